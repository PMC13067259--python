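"""Gray-level co-occurrence matrices and Haralick texture descriptors.

A GLCM for an offset ``(d, theta)`` tabulates how often gray level *i*
sits at a fixed displacement from gray level *j*; normalized, it is a
joint probability over level pairs.  Neurodegeneration roughens tissue
texture, which shows up as off-diagonal GLCM mass: contrast and
dissimilarity rise, energy and homogeneity fall, entropy rises.  Those
six scalars, swept over a grid of distances and directions, form the
feature vector consumed downstream.

Angle-to-offset convention (row, col), matching the standard
image-processing reading of direction on a raster:

* theta = 0      -> (0,  d)   (east)
* theta = pi/4   -> (-d, d)   (north-east)
* theta = pi/2   -> (-d, 0)   (north)
* theta = 3pi/4  -> (-d, -d)  (north-west)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import PreprocessConfig, normalize_intensity, preprocess_image, quantize

FEATURE_NAMES = ("contrast", "energy", "correlation", "homogeneity", "entropy", "dissimilarity")

DEFAULT_DISTANCES = (1, 3, 5, 7)
DEFAULT_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass
class GLCM:
    """Normalized co-occurrence matrix for one (distance, angle) offset."""

    P: np.ndarray
    d: int
    theta: float
    levels: int
    symmetric: bool = True


@dataclass
class TextureConfig:
    """Feature-extraction grid and GLCM options.

    ``window`` selects the opt-in sliding-window mode: per-window
    feature values are averaged over all windows of that (odd) size.
    ``window=None`` (default) computes one whole-image GLCM per offset.
    """

    distances: tuple = DEFAULT_DISTANCES
    angles: tuple = DEFAULT_ANGLES
    levels: int = 32
    window: int | None = None
    window_step: int = 1
    symmetric: bool = True

    def __post_init__(self) -> None:
        if any(int(d) < 1 for d in self.distances):
            raise ValueError("distances must be positive integers")
        if not (2 <= int(self.levels) <= 256):
            raise ValueError("levels must lie in [2, 256]")
        if self.window is not None:
            if self.window % 2 == 0 or self.window < 3:
                raise ValueError("window must be an odd integer >= 3")


@dataclass
class HaralickVector:
    """Ordered texture features over the (distance, angle, feature) grid."""

    values: np.ndarray
    index: list = field(default_factory=list)  # (d, angle_index, feature_name)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def names(self) -> list:
        return [f"d{d}_a{ai}_{name}" for d, ai, name in self.index]


def offset_for_angle(d: int, theta: float) -> tuple:
    """Map (distance, angle) to a (row, col) displacement."""
    dr = -int(round(d * np.sin(theta)))
    dc = int(round(d * np.cos(theta)))
    return dr, dc


def compute_glcm(qimage: np.ndarray, d: int, theta: float, levels: int,
                 symmetric: bool = True) -> GLCM:
    """Count all in-bounds ordered pixel pairs at offset (d, theta) and
    normalize to a probability matrix.

    In symmetric mode the transposed counts are added before
    normalization, so each unordered pair contributes in both
    orientations and ``P`` is exactly symmetric.
    """
    img = np.asarray(qimage)
    if img.ndim != 2:
        raise ValueError("qimage must be 2-D")
    if img.min() < 0 or img.max() >= levels:
        raise ValueError("qimage values must lie in [0, levels-1]")
    img = img.astype(np.int64)
    dr, dc = offset_for_angle(int(d), theta)
    h, w = img.shape

    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"offset ({dr},{dc}) admits no pixel pair in a {h}x{w} image")

    a = img[r0:r1, c0:c1].ravel()
    b = img[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels).reshape(levels, levels)
    counts = counts.astype(float)
    if symmetric:
        counts = counts + counts.T
    P = counts / counts.sum()
    return GLCM(P=P, d=int(d), theta=float(theta), levels=int(levels), symmetric=symmetric)


def _matrix(glcm) -> np.ndarray:
    P = glcm.P if isinstance(glcm, GLCM) else np.asarray(glcm, dtype=float)
    return P


def glcm_contrast(glcm) -> float:
    """Sum of (i-j)^2 P(i,j): local intensity variation."""
    P = _matrix(glcm)
    i, j = np.indices(P.shape)
    return float(((i - j) ** 2 * P).sum())


def glcm_energy(glcm) -> float:
    """Angular second moment, sum of P(i,j)^2: texture uniformity."""
    P = _matrix(glcm)
    return float((P ** 2).sum())


def glcm_correlation(glcm) -> float:
    """Normalized linear dependence of paired gray levels.

    Uses the marginal means/standard deviations of ``P``; degenerate
    marginals (sigma_x * sigma_y < 1e-12) return 0 by convention.
    """
    P = _matrix(glcm)
    L = P.shape[0]
    lev = np.arange(L, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mx = float(lev @ px)
    my = float(lev @ py)
    sx = float(np.sqrt(((lev - mx) ** 2) @ px))
    sy = float(np.sqrt(((lev - my) ** 2) @ py))
    if sx * sy < 1e-12:
        return 0.0
    i, j = np.indices(P.shape)
    val = (float((i * j * P).sum()) - mx * my) / (sx * sy)
    return float(np.clip(val, -1.0, 1.0))


def glcm_homogeneity(glcm) -> float:
    """Inverse difference moment, sum of P(i,j) / (1 + |i-j|)."""
    P = _matrix(glcm)
    i, j = np.indices(P.shape)
    return float((P / (1.0 + np.abs(i - j))).sum())


def glcm_entropy(glcm, eps: float = 1e-12) -> float:
    """Shannon entropy (bits) of the co-occurrence distribution,
    -sum P log2(P + eps); the small eps keeps the log finite."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    P = _matrix(glcm)
    return float(-(P * np.log2(P + eps)).sum())


def glcm_dissimilarity(glcm) -> float:
    """Sum of |i-j| P(i,j): linear-penalty analog of contrast."""
    P = _matrix(glcm)
    i, j = np.indices(P.shape)
    return float((np.abs(i - j) * P).sum())


_FEATURE_FNS = {
    "contrast": glcm_contrast,
    "energy": glcm_energy,
    "correlation": glcm_correlation,
    "homogeneity": glcm_homogeneity,
    "entropy": glcm_entropy,
    "dissimilarity": glcm_dissimilarity,
}


def glcm_features(glcm) -> np.ndarray:
    """The six Haralick descriptors of one GLCM, in canonical order."""
    return np.array([_FEATURE_FNS[name](glcm) for name in FEATURE_NAMES])


def _window_features(qimage: np.ndarray, d: int, theta: float, cfg: TextureConfig) -> np.ndarray:
    w = cfg.window
    h, wid = qimage.shape
    if h < w or wid < w:
        raise ValueError("image smaller than the sliding window")
    feats = []
    for r in range(0, h - w + 1, cfg.window_step):
        for c in range(0, wid - w + 1, cfg.window_step):
            patch = qimage[r:r + w, c:c + w]
            try:
                g = compute_glcm(patch, d, theta, cfg.levels, cfg.symmetric)
            except ValueError:
                continue  # offset does not fit in this window
            feats.append(glcm_features(g))
    if not feats:
        raise ValueError("no window admits the requested offset")
    return np.mean(feats, axis=0)


def extract_features(image: np.ndarray, config: TextureConfig | None = None,
                     quantized: bool = False) -> HaralickVector:
    """Haralick feature vector over the full (distance x angle) grid.

    Parameters
    ----------
    image : ndarray
        Preprocessed image (no missing pixels).  Unless ``quantized``,
        it is min-max normalized and uniformly binned to
        ``config.levels`` first.
    config : TextureConfig
        Grid and GLCM options; the default grid (distances 1, 3, 5, 7 x
        four directions x six features) yields 96 values.
    """
    cfg = config or TextureConfig()
    if quantized:
        qimg = np.asarray(image, dtype=np.int64)
    else:
        # normalize + quantize only; smoothing belongs to the preprocess stage
        qimg = quantize(normalize_intensity(image), cfg.levels, assume_range="unit")
    h, w = qimg.shape
    if max(cfg.distances) >= max(h, w):
        raise ValueError("image smaller than the largest configured distance")

    values, index = [], []
    for d in cfg.distances:
        for ai, theta in enumerate(cfg.angles):
            if cfg.window is None:
                g = compute_glcm(qimg, d, theta, cfg.levels, cfg.symmetric)
                feats = glcm_features(g)
            else:
                feats = _window_features(qimg, d, theta, cfg)
            values.extend(feats)
            index.extend((int(d), ai, name) for name in FEATURE_NAMES)
    return HaralickVector(values=np.asarray(values, dtype=float), index=index)


class HaralickExtractor:
    """scikit-learn style transformer: images in, Haralick features out.

    ``transform`` accepts a sequence of 2-D arrays (raw ``[0, 255]`` or
    already-normalized ``[0, 1]`` images) and applies the preprocessing
    chain (impute, Gaussian smooth, min-max normalize, quantize) before
    computing the feature grid for each image.

    Parameters mirror :class:`TextureConfig` plus the smoothing sigma.
    """

    def __init__(self, distances=DEFAULT_DISTANCES, angles=DEFAULT_ANGLES,
                 levels: int = 32, window: int | None = None, window_step: int = 1,
                 symmetric: bool = True, smooth_sigma: float = 1.0):
        self.distances = distances
        self.angles = angles
        self.levels = levels
        self.window = window
        self.window_step = window_step
        self.symmetric = symmetric
        self.smooth_sigma = smooth_sigma

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("distances", "angles", "levels", "window", "window_step",
                 "symmetric", "smooth_sigma")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _texture_config(self) -> TextureConfig:
        return TextureConfig(distances=tuple(self.distances), angles=tuple(self.angles),
                             levels=self.levels, window=self.window,
                             window_step=self.window_step, symmetric=self.symmetric)

    def fit(self, X, y=None):
        cfg = self._texture_config()
        self.feature_names_ = [
            f"d{int(d)}_a{ai}_{name}"
            for d in cfg.distances for ai in range(len(cfg.angles))
            for name in FEATURE_NAMES
        ]
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        cfg = self._texture_config()
        pre = PreprocessConfig(smooth_sigma=self.smooth_sigma, levels=self.levels)
        rows = []
        for img in X:
            qimg = preprocess_image(img, pre)
            rows.append(extract_features(qimg, cfg, quantized=True).values)
        return np.asarray(rows)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
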