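"""Synthetic data: class-labelled textured images and planted feature tables.

The image generator emulates the *shape* of a staged-dementia MRI
collection — four balanced classes of 128 x 128 8-bit grayscale images —
with class identity carried purely by texture statistics, which is the
only thing the co-occurrence pipeline consumes.  Each class is a
Gaussian random field: white noise smoothed with a class-specific
correlation length (strictly increasing across classes) and scaled by a
class-specific contrast.  Rougher fields (shorter correlation length)
produce strictly larger expected short-range GLCM contrast, so the class
ordering of mean contrast is planted by construction and end-to-end
classification above chance is achievable in principle.  No anatomy, MRI
physics (bias fields, Rician noise) or 3-D structure is simulated.

The feature-table generator plants ``k_informative`` columns whose
class-conditional means are separated by a configurable effect size (in
within-class standard deviations) among pure-noise columns, with the
ground-truth column mask recorded — the fixture for weight-recovery
experiments.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import save_image


@dataclass
class SyntheticConfig:
    """Image-set shape and texture parameters.

    ``class_smoothness`` are the Gaussian-field kernel sigmas in pixels
    (strictly increasing: later classes are smoother); ``class_contrast``
    scales the field amplitude.  The defaults give monotone, comfortably
    detectable but non-trivial separation at 32 gray levels.
    """

    n_classes: int = 4
    n_per_class: int = 100
    size: int = 128
    class_smoothness: tuple = (0.5, 1.0, 2.0, 4.0)
    class_contrast: tuple = (1.0, 0.9, 0.8, 0.7)
    missing_fraction: float = 0.0
    mask: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_smoothness) != self.n_classes or \
           len(self.class_contrast) != self.n_classes:
            raise ValueError("per-class parameter lengths must equal n_classes")
        if any(b <= a for a, b in zip(self.class_smoothness, self.class_smoothness[1:])):
            raise ValueError("class_smoothness must be strictly increasing")
        if not (0.0 <= self.missing_fraction <= 0.2):
            raise ValueError("missing_fraction must lie in [0, 0.2]")
        if self.size < 8:
            raise ValueError("size must be >= 8")


@dataclass
class PlantedFeatureConfig:
    """Planted-signal feature-table shape."""

    n_samples: int = 400
    k_informative: int = 4
    m_noise: int = 12
    effect: float = 2.0
    n_classes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect <= 0:
            raise ValueError("effect must be > 0")
        if self.k_informative < 1:
            raise ValueError("k_informative must be >= 1")


def _elliptical_mask(size: int) -> np.ndarray:
    r = np.linspace(-1.0, 1.0, size)
    yy, xx = np.meshgrid(r, r, indexing="ij")
    return (yy / 0.95) ** 2 + (xx / 0.8) ** 2 <= 1.0


def generate_image(class_index: int, config: SyntheticConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """One textured image for the given class; 8-bit-valued float array,
    NaN where pixels were injected as missing."""
    if not (0 <= class_index < config.n_classes):
        raise ValueError("class_index out of range")
    sigma = config.class_smoothness[class_index]
    contrast = config.class_contrast[class_index]
    field = ndimage.gaussian_filter(
        rng.standard_normal((config.size, config.size)), sigma=sigma, mode="reflect")
    field = (field - field.mean()) / field.std()
    img = 127.5 + 60.0 * contrast * field
    img = np.clip(np.round(img), 0.0, 255.0)
    if config.mask:
        img = np.where(_elliptical_mask(config.size), img, 0.0)
    if config.missing_fraction > 0:
        holes = rng.random(img.shape) < config.missing_fraction
        img = np.where(holes, np.nan, img)
    return img


def generate_dataset(config: SyntheticConfig | None = None):
    """Balanced, seeded image set.

    Returns ``(images, labels)`` where ``images`` is a list of 2-D
    arrays and ``labels`` an integer array, in a seeded shuffled order.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    images, labels = [], []
    for c in range(cfg.n_classes):
        for _ in range(cfg.n_per_class):
            images.append(generate_image(c, cfg, rng))
            labels.append(c)
    order = rng.permutation(len(images))
    return [images[i] for i in order], np.asarray(labels)[order]


def write_dataset(config: SyntheticConfig, outdir) -> pd.DataFrame:
    """Write one folder per class of PNGs plus a ``manifest.csv``
    (path, label), mirroring a per-class directory layout."""
    cfg = config
    images, labels = generate_dataset(cfg)
    rows = []
    counters = {c: 0 for c in range(cfg.n_classes)}
    for img, lab in zip(images, labels):
        lab = int(lab)
        cls_dir = os.path.join(outdir, f"class_{lab}")
        os.makedirs(cls_dir, exist_ok=True)
        path = os.path.join(cls_dir, f"img_{counters[lab]:05d}.png")
        counters[lab] += 1
        save_image(np.nan_to_num(img, nan=0.0), path)
        rows.append({"path": path, "label": lab})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return manifest


def generate_feature_table(config: PlantedFeatureConfig | None = None):
    """Planted-signal table.

    Returns ``(X, y, informative_mask, feature_names)``: informative
    columns have class-conditional means ``class * effect`` (unit
    within-class std), noise columns are i.i.d. standard normal, and the
    column order is a seeded shuffle with the ground truth recorded in
    ``informative_mask``.
    """
    cfg = config or PlantedFeatureConfig()
    rng = np.random.default_rng(cfg.seed)
    n, k, m = cfg.n_samples, cfg.k_informative, cfg.m_noise
    # balanced labels: round-robin assignment, then a seeded shuffle
    y = np.tile(np.arange(cfg.n_classes), n // cfg.n_classes + 1)[:n]
    rng.shuffle(y)
    info = y[:, None] * cfg.effect + rng.standard_normal((n, k))
    noise = rng.standard_normal((n, m))
    X = np.concatenate([info, noise], axis=1)
    mask = np.concatenate([np.ones(k, dtype=bool), np.zeros(m, dtype=bool)])
    order = rng.permutation(k + m)
    X = X[:, order]
    mask = mask[order]
    names = [f"{'informative' if mask[j] else 'noise'}_{j}" for j in range(k + m)]
    return X, y, mask, names
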