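"""Image cleaning and standardization ahead of texture extraction.

Images are plain 2-D ``float64`` arrays with intensities in ``[0, 255]``
(or ``[0, 1]`` once normalized).  Missing pixels are encoded as ``NaN``;
ordinary 8-bit PNG/JPEG inputs contain none, so imputation only fires on
data with explicitly injected gaps.

The canonical order of stages is::

    mean_impute -> gaussian_smooth -> normalize_intensity -> quantize

Motion correction and slice-time compensation are exposed as named
identity hooks so the pipeline structure mirrors a full MRI workflow;
they perform no computation here (that is registration-tool territory,
out of scope for 2-D texture analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage


@dataclass
class PreprocessConfig:
    """Preprocessing knobs.

    Parameters
    ----------
    smooth_sigma : float
        Standard deviation, in pixels, of the Gaussian smoothing kernel.
    levels : int
        Number of gray levels ``L`` for quantization, ``2 <= L <= 256``.
        The default of 32 keeps co-occurrence matrices well populated
        even for small windows while preserving texture contrast.
    icv : float or None
        Intracranial-volume denominator for volumetric measurements,
        unused by the image pipeline itself.
    """

    smooth_sigma: float = 1.0
    levels: int = 32
    icv: float | None = None

    def __post_init__(self) -> None:
        if self.smooth_sigma <= 0:
            raise ValueError("smooth_sigma must be > 0")
        if not (2 <= int(self.levels) <= 256):
            raise ValueError("levels must lie in [2, 256]")
        if self.icv is not None and self.icv <= 0:
            raise ValueError("icv must be > 0 when given")


def _as_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("image must be a 2-D array with height, width >= 2")
    return arr


def load_image(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/JPEG; color inputs are converted by
    averaging the channels (luminance average)."""
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return arr


def save_image(image: np.ndarray, path) -> None:
    """Write an image as 8-bit grayscale PNG (values clipped to [0, 255])."""
    arr = np.clip(np.asarray(image, dtype=float), 0, 255).round().astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def motion_correction(image: np.ndarray) -> np.ndarray:
    """Identity hook standing where rigid-body head-motion correction
    would sit in a volumetric pipeline."""
    return _as_image(image).copy()


def slice_time_compensation(image: np.ndarray) -> np.ndarray:
    """Identity hook standing where slice-timing compensation would sit."""
    return _as_image(image).copy()


def mean_impute(image: np.ndarray) -> np.ndarray:
    """Replace every missing (NaN) pixel with the mean of the non-missing
    pixels.

    Raises
    ------
    ValueError
        If every pixel is missing (no data to impute from).
    """
    arr = _as_image(image)
    mask = np.isnan(arr)
    if not mask.any():
        return arr.copy()
    if mask.all():
        raise ValueError("cannot impute an all-missing image")
    out = arr.copy()
    out[mask] = arr[~mask].mean()
    return out


def gaussian_smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """2-D Gaussian convolution with reflective boundary handling.

    Reflection avoids the edge darkening a zero-padded convolution would
    introduce, which matters because co-occurrence statistics are
    sensitive to spurious intensity gradients at the frame.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    arr = _as_image(image)
    if np.isnan(arr).any():
        raise ValueError("image has missing pixels; run mean_impute first")
    if arr.min() == arr.max():
        # convolution preserves constants exactly; short-circuit to avoid
        # accumulating float rounding in the separable filter
        return arr.copy()
    return ndimage.gaussian_filter(arr, sigma=sigma, mode="reflect")


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Min-max rescale to ``[0, 1]``.  A constant image maps to all
    zeros (documented convention so the operation is total)."""
    arr = _as_image(image)
    if np.isnan(arr).any():
        raise ValueError("image has missing pixels; run mean_impute first")
    lo, hi = arr.min(), arr.max()
    if hi - lo == 0:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def normalize_by_icv(raw_measurement: float, icv: float) -> float:
    """Scale a volumetric measurement by the intracranial volume,
    removing head-size variation across subjects."""
    if icv <= 0:
        raise ValueError("icv must be > 0")
    return raw_measurement / icv


def quantize(image: np.ndarray, levels: int, assume_range: str = "auto") -> np.ndarray:
    """Uniformly bin intensities into ``levels`` integer gray levels.

    Parameters
    ----------
    image : ndarray
        Values in ``[0, 1]`` (normalized) or ``[0, 255]`` (raw 8-bit).
    levels : int
        Bin count ``L``; output values are integers in ``[0, L-1]``.
    assume_range : {"auto", "unit", "byte"}
        Value-range interpretation.  ``auto`` treats any image whose
        maximum exceeds 1 as 8-bit.

    The binning is monotone: ``v1 <= v2`` implies ``q(v1) <= q(v2)``.
    """
    levels = int(levels)
    if not (2 <= levels <= 256):
        raise ValueError("levels must lie in [2, 256]")
    arr = _as_image(image)
    if np.isnan(arr).any():
        raise ValueError("image has missing pixels; run mean_impute first")
    if assume_range == "auto":
        assume_range = "byte" if arr.max() > 1.0 else "unit"
    if assume_range == "byte":
        arr = arr / 255.0
    elif assume_range != "unit":
        raise ValueError("assume_range must be 'auto', 'unit' or 'byte'")
    if arr.min() < -1e-9 or arr.max() > 1.0 + 1e-9:
        raise ValueError("image values out of range for quantization")
    q = np.floor(np.clip(arr, 0.0, 1.0) * levels).astype(np.int64)
    return np.minimum(q, levels - 1)


def preprocess_image(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Full stage chain: impute -> smooth -> min-max normalize -> quantize.

    Returns the quantized integer image in ``[0, levels - 1]``.
    """
    cfg = config or PreprocessConfig()
    img = mean_impute(image)
    img = motion_correction(img)
    img = slice_time_compensation(img)
    img = gaussian_smooth(img, cfg.smooth_sigma)
    img = normalize_intensity(img)
    return quantize(img, cfg.levels, assume_range="unit")
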