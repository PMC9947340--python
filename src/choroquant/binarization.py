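"""Lumen/stroma partition of the choroid by Niblack local thresholding.

Niblack's rule sets a per-pixel threshold ``T(x) = m(x) + k·s(x)`` from the
mean ``m`` and population standard deviation ``s`` of the intensities in a
square window centered on ``x``.  Windows are clipped at the image borders:
statistics run over in-image pixels only, never over padded values.  Pixels at
or below the threshold are luminal (vessel interiors are hyporeflective on
OCT); the rest of the choroid ROI is stroma, so the two masks partition the
ROI exactly.

The default parameters (31×31 window, ``k = −0.2``) follow the ImageJ Auto
Local Threshold settings conventionally used for choroid binarization; a
median despeckle precedes thresholding by default, the standard first step of
that workflow on speckled OCT images.  Window statistics are restricted to
the choroid ROI by default so the threshold is not distorted by the bright
RPE band above or the dark sclera below the choroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .errors import ValidationError
from .segmentation import ChoroidSegmentation

__all__ = [
    "NiblackParams",
    "BinarizedChoroid",
    "niblack_threshold",
    "binarize_choroid",
    "export_masks",
]


@dataclass(frozen=True)
class NiblackParams:
    """Niblack window half-width (radius 15 ⇒ 31×31 window) and sd weight."""

    window_radius_px: int = 15
    k: float = -0.2

    def __post_init__(self) -> None:
        if self.window_radius_px < 1:
            raise ValidationError("window_radius_px must be ≥ 1")
        if not np.isfinite(self.k):
            raise ValidationError("k must be finite")


@dataclass
class BinarizedChoroid:
    """Exact lumen/stroma partition of the choroid ROI of one B-scan."""

    lumen_mask: np.ndarray
    stroma_mask: np.ndarray
    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.lumen_mask.shape == self.stroma_mask.shape == self.roi_mask.shape):
            raise ValidationError("mask shapes differ")
        if np.any(self.lumen_mask & self.stroma_mask):
            raise ValidationError("lumen and stroma masks overlap")
        if not np.array_equal(self.lumen_mask | self.stroma_mask, self.roi_mask):
            raise ValidationError("lumen ∪ stroma must equal the ROI")


def _clipped_window_sums(arr: np.ndarray, radius: int) -> np.ndarray:
    """Sum of ``arr`` over the square window of half-width ``radius`` centered
    at each pixel, window clipped to the image (summed-area table)."""
    h, w = arr.shape
    # integral image with a zero top row / left column
    ii = np.zeros((h + 1, w + 1), dtype=np.float64)
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=ii[1:, 1:])
    r0 = np.clip(np.arange(h) - radius, 0, h)
    r1 = np.clip(np.arange(h) + radius + 1, 0, h)
    c0 = np.clip(np.arange(w) - radius, 0, w)
    c1 = np.clip(np.arange(w) + radius + 1, 0, w)
    return (
        ii[np.ix_(r1, c1)] - ii[np.ix_(r0, c1)] - ii[np.ix_(r1, c0)] + ii[np.ix_(r0, c0)]
    )


def niblack_threshold(image: np.ndarray, params: NiblackParams = NiblackParams()) -> np.ndarray:
    """Per-pixel Niblack threshold map ``m + k·s`` with clipped windows.

    ``s`` is the population (divide-by-N) standard deviation computed as
    ``sqrt(E[x²] − E[x]²)``.  For integer-valued images the windowed sums are
    exact in float64, so the map is bit-identical to a naive per-pixel loop
    using the same formula.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("image must be a non-empty 2D array")
    r = params.window_radius_px
    h, w = img.shape
    n = _clipped_window_sums(np.ones_like(img), r)
    s1 = _clipped_window_sums(img, r)
    s2 = _clipped_window_sums(img * img, r)
    mean = s1 / n
    var = np.maximum(s2 / n - mean * mean, 0.0)
    return mean + params.k * np.sqrt(var)


def binarize_choroid(
    flat_image: np.ndarray,
    seg: ChoroidSegmentation,
    params: NiblackParams = NiblackParams(),
    *,
    despeckle: bool = True,
    roi_only: bool = True,
    work_image: np.ndarray | None = None,
) -> BinarizedChoroid:
    """Partition the choroid ROI of a flattened B-scan into lumen and stroma.

    The ROI covers rows in ``[upper, lower)`` per column.  By default the
    window statistics are restricted to ROI pixels, so the threshold inside
    the choroid is not dragged around by the bright RPE above or the dark
    sclera below; ``roi_only=False`` computes the map from the whole image
    instead.  ``despeckle`` applies a 3×3 median before thresholding.  Ties
    (intensity == threshold) go to lumen.  An empty ROI yields empty masks,
    not an error.
    """
    img = np.asarray(flat_image, dtype=np.float64)
    h, w = img.shape
    upper = np.round(seg.upper.rows).astype(np.intp)
    lower = np.round(seg.lower.rows).astype(np.intp)
    if upper.shape[0] != w:
        raise ValidationError("segmentation does not match image width")
    rows = np.arange(h)[:, None]
    roi = (rows >= upper[None, :]) & (rows < lower[None, :])
    if not roi.any():
        empty = np.zeros_like(roi)
        return BinarizedChoroid(lumen_mask=empty, stroma_mask=empty.copy(), roi_mask=roi)

    if work_image is not None:
        # caller-provided pre-despeckled image (e.g. shared with segmentation)
        work = np.asarray(work_image, dtype=np.float64)
        if work.shape != img.shape:
            raise ValidationError("work_image shape mismatch")
    elif despeckle:
        work = median_filter(img, size=3)
    else:
        work = img
    if roi_only:
        # window statistics over ROI pixels only: masked sums / masked counts
        r = params.window_radius_px
        m = roi.astype(np.float64)
        n = _clipped_window_sums(m, r)
        s1 = _clipped_window_sums(work * m, r)
        s2 = _clipped_window_sums(work * work * m, r)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = s1 / n
            var = np.maximum(s2 / n - mean * mean, 0.0)
            thresh = mean + params.k * np.sqrt(var)
        thresh = np.where(n > 0, thresh, np.inf)
    else:
        thresh = niblack_threshold(work, params)

    lumen = roi & (work <= thresh)
    stroma = roi & ~lumen
    return BinarizedChoroid(lumen_mask=lumen, stroma_mask=stroma, roi_mask=roi)


def export_masks(binarized: BinarizedChoroid, directory, stem: str) -> tuple:
    """Write the lumen/stroma masks as 8-bit 0/255 PNGs
    (``<stem>_lumen.png``, ``<stem>_stroma.png``); returns the two paths."""
    from pathlib import Path

    import imageio.v3 as iio

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, mask in (("lumen", binarized.lumen_mask), ("stroma", binarized.stroma_mask)):
        p = out / f"{stem}_{name}.png"
        iio.imwrite(p, (mask.astype(np.uint8) * 255))
        paths.append(p)
    return tuple(paths)
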