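"""RPE detection, flattening, and choroid boundary delineation.

The retinal pigment epithelium (RPE) is the dominant hyperreflective band of a
structural B-scan; its reflection serves as the flattening reference that
removes acquisition tilt.  Boundaries are found as minimum-cost left-to-right
paths through brightness- or gradient-derived cost images, with a per-column
slope constraint that enforces anatomical continuity (dynamic programming,
deterministic tie-break toward the smallest row).  The choroid's upper
boundary is taken as the bottom edge of the RPE band; the lower boundary
follows the bright-to-dark transition at the choroid–sclera interface.

Externally produced boundaries (e.g. from a learned segmenter) can be wrapped
unchanged via :func:`use_external_boundaries`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter, uniform_filter1d

from .errors import DetectionError, FlatteningError, SegmentationError, ValidationError
from .scan_model import BScan

__all__ = [
    "BoundaryKind",
    "BoundaryCurve",
    "ChoroidSegmentation",
    "detect_rpe",
    "flatten",
    "segment_choroid",
    "segmentation_to_csv",
    "segmentation_from_csv",
    "use_external_boundaries",
]

MAX_SLOPE_PX = 2
MIN_THICKNESS_PX = 5
RPE_SEARCH_DEPTH_PX = 12
LATERAL_COST_SMOOTH_PX = 31
SCLERA_LOOKAHEAD_PX = 10
SCLERA_REGION_WEIGHT = 0.5


class BoundaryKind(str, Enum):
    RPE = "rpe"
    CHOROID_UPPER = "choroid_upper"
    CHOROID_LOWER = "choroid_lower"


@dataclass
class BoundaryCurve:
    """Real-valued row index per column; continuous to within MAX_SLOPE_PX."""

    rows: np.ndarray
    kind: BoundaryKind

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.float64)
        if self.rows.ndim != 1:
            raise ValidationError("boundary rows must be 1D")
        if np.any(self.rows < 0):
            raise ValidationError("boundary rows must be nonnegative")
        if self.rows.size > 1:
            step = np.abs(np.diff(self.rows))
            if np.any(step > MAX_SLOPE_PX + 1e-9):
                raise ValidationError(
                    f"boundary slope exceeds {MAX_SLOPE_PX} px/column "
                    f"(max {step.max():.2f})"
                )


@dataclass
class ChoroidSegmentation:
    """Per-B-scan RPE and upper/lower choroid boundaries plus flatten shifts."""

    rpe: BoundaryCurve
    upper: BoundaryCurve
    lower: BoundaryCurve
    flatten_shift: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.upper.rows > self.lower.rows):
            raise ValidationError("upper boundary must not lie below lower boundary")
        if np.any(self.rpe.rows > self.upper.rows):
            raise ValidationError("RPE must lie at or above the choroid upper boundary")


def _min_cost_path(
    cost: np.ndarray,
    lo: np.ndarray | None = None,
    hi: np.ndarray | None = None,
    max_slope: int = MAX_SLOPE_PX,
) -> np.ndarray:
    """Minimum-cost column-monotone path through ``cost`` (rows × cols).

    ``lo``/``hi`` give inclusive per-column row bounds.  Transitions are
    limited to ``|Δrow| ≤ max_slope`` per column; ties break toward the
    smallest row.  Returns the row index per column.
    """
    h, w = cost.shape
    big = np.float64(1e30)
    c = cost.astype(np.float64, copy=True)
    if lo is not None or hi is not None:
        rows = np.arange(h)[:, None]
        mask = np.zeros((h, w), dtype=bool)
        if lo is not None:
            mask |= rows < np.asarray(lo)[None, :]
        if hi is not None:
            mask |= rows > np.asarray(hi)[None, :]
        if mask.all(axis=0).any():
            raise SegmentationError("no admissible row in some column")
        c[mask] = big

    offsets = np.arange(-max_slope, max_slope + 1)
    back = np.zeros((h, w), dtype=np.int8)
    dp = c[:, 0].copy()
    cand = np.empty((offsets.size, h), dtype=np.float64)
    for col in range(1, w):
        # cand[j, r] = dp[r + offsets[j]] (previous column), inf off-range
        for j, off in enumerate(offsets):
            if off < 0:
                cand[j, -off:] = dp[:off]
                cand[j, :-off] = big
            elif off > 0:
                cand[j, :-off] = dp[off:]
                cand[j, -off:] = big
            else:
                cand[j] = dp
        best = np.argmin(cand, axis=0)
        back[:, col] = best.astype(np.int8)
        dp = cand[best, np.arange(h)] + c[:, col]

    path = np.empty(w, dtype=np.intp)
    path[-1] = int(np.argmin(dp))  # argmin → first occurrence → smallest row
    for col in range(w - 1, 0, -1):
        off = offsets[back[path[col], col]]
        path[col - 1] = path[col] + off
    return path


def detect_rpe(bscan: BScan, *, min_brightness_quantile: float = 0.95) -> BoundaryCurve:
    """Locate the RPE as the brightest axially smoothed, continuous band.

    The cost image is the negated axially Gaussian-smoothed intensity; the
    minimum-cost path then rides the dominant bright band.  Fails if no pixel
    reaches a minimal brightness (degenerate, e.g. all-zero images).
    """
    img = np.asarray(bscan.image, dtype=np.float64)
    peak = float(img.max())
    if peak <= 0 or float(np.quantile(img, min_brightness_quantile)) <= 0:
        raise DetectionError("no bright band present (image too dark)")
    smooth = gaussian_filter1d(img, sigma=2.0, axis=0)
    path = _min_cost_path(-smooth)
    return BoundaryCurve(rows=path.astype(np.float64), kind=BoundaryKind.RPE)


def flatten(bscan: BScan, rpe: BoundaryCurve) -> tuple[BScan, np.ndarray]:
    """Shift each column by an integer so the RPE lies on one target row.

    The target is the median detected RPE row; vacated pixels are filled with
    0.  Shift-only (no interpolation), so per-column intensity statistics are
    preserved for downstream thresholding.  Returns the flattened scan and the
    applied per-column shifts (positive = moved down).
    """
    img = bscan.image
    h, w = img.shape
    if rpe.rows.shape[0] != w:
        raise ValidationError("RPE curve does not match image width")
    target = int(np.round(np.median(rpe.rows)))
    shift = target - np.round(rpe.rows).astype(np.intp)
    if np.any(np.abs(shift) > h // 2):
        raise FlatteningError("flattening would shift >50% of a column out of frame")
    rows = np.arange(h)[:, None]
    src = rows - shift[None, :]
    valid = (src >= 0) & (src < h)
    out = np.zeros_like(img)
    cols = np.broadcast_to(np.arange(w)[None, :], (h, w))
    out[valid] = img[src[valid], cols[valid]]
    return BScan(image=out, angle_deg=bscan.angle_deg), shift


def segment_choroid(
    flat_bscan: BScan,
    rpe: BoundaryCurve,
    *,
    min_thickness_px: int = MIN_THICKNESS_PX,
    despeckled_image: np.ndarray | None = None,
) -> ChoroidSegmentation:
    """Delineate the choroid band of a flattened B-scan.

    Upper boundary: the strongest bright→dark transition within a shallow
    window below the RPE ridge (bottom edge of the RPE band).  Lower boundary:
    minimum-cost path through the axially smoothed downward gradient, i.e. the
    choroid–sclera interface, constrained at least ``min_thickness_px`` below
    the upper boundary.
    """
    img = np.asarray(flat_bscan.image, dtype=np.float64)
    h, w = img.shape
    if rpe.rows.shape[0] != w:
        raise ValidationError("RPE curve does not match image width")

    # downward step cost: d[r] = I[r+1] − I[r] of the despeckled image,
    # axially box-smoothed (3 px) and laterally box-smoothed: the interfaces
    # of interest (RPE bottom edge, choroid–sclera) are laterally coherent
    # across the scan, while vessel-lumen edges inside the choroid are not,
    # so lateral averaging suppresses blob capture.  The axial smoothing
    # spreads a sharp edge between rows b−1 and b over a two-row cost plateau
    # at b−2 and b−1; with ties broken toward the smaller row the path
    # settles on b−2, so the boundary (first dark row) is path + 2.
    if despeckled_image is not None:
        work = np.asarray(despeckled_image, dtype=np.float64)
        if work.shape != img.shape:
            raise ValidationError("despeckled image shape mismatch")
    else:
        work = median_filter(img, size=3)
    # zero pixels are vacated by the flattening shift, not tissue: replace
    # them with a background estimate so they create neither spurious edges
    # nor artificially dark regions
    pos = work > 0
    if pos.any() and not pos.all():
        work = np.where(pos, work, np.percentile(work[pos], 5))
    grad = np.zeros_like(work)
    grad[:-1, :] = work[1:, :] - work[:-1, :]
    cost = uniform_filter1d(grad, size=3, axis=0)
    cost = uniform_filter1d(cost, size=LATERAL_COST_SMOOTH_PX, axis=1)
    _EDGE_OFFSET = 2

    look = SCLERA_LOOKAHEAD_PX
    csum = np.zeros((h + 1, w), dtype=np.float64)
    np.cumsum(work, axis=0, out=csum[1:])

    rpe_rows = np.round(rpe.rows).astype(np.intp)
    lo_u = np.clip(rpe_rows - 1, 0, h - 2)
    hi_u = np.clip(rpe_rows + RPE_SEARCH_DEPTH_PX, 0, h - 2)
    upper = _min_cost_path(cost, lo=lo_u, hi=hi_u) + _EDGE_OFFSET

    # lower boundary: the choroid–sclera interface is the *deepest* strong
    # bright→dark edge — vessels clipped at the band bottom imitate edges a
    # few rows above it.  Add a region term (mean brightness of the next
    # SCLERA_LOOKAHEAD_PX rows) so the path prefers edges with genuinely
    # dark tissue below.  The region term strictly decreases across the
    # edge-cost plateau, so the path lands one row higher than the gradient
    # tie-break alone and the boundary is path + 1.
    below = np.empty((h, w), dtype=np.float64)
    for r in range(h):
        r0, r1 = r + 1, min(r + 1 + look, h)
        below[r] = (csum[r1] - csum[r0]) / max(r1 - r0, 1) if r1 > r0 else work[r]
    below = uniform_filter1d(below, size=LATERAL_COST_SMOOTH_PX, axis=1)
    cost_lower = cost + SCLERA_REGION_WEIGHT * below

    lo_l = np.clip(upper + min_thickness_px - 1, 0, h - 2)
    hi_l = np.full(w, h - 2, dtype=np.intp)
    if np.any(lo_l > hi_l):
        raise SegmentationError("no admissible lower-boundary path")
    lower = _min_cost_path(cost_lower, lo=lo_l, hi=hi_l) + 1

    return ChoroidSegmentation(
        rpe=BoundaryCurve(rows=rpe.rows, kind=BoundaryKind.RPE),
        upper=BoundaryCurve(rows=upper.astype(np.float64), kind=BoundaryKind.CHOROID_UPPER),
        lower=BoundaryCurve(rows=np.maximum(lower, upper).astype(np.float64), kind=BoundaryKind.CHOROID_LOWER),
        flatten_shift=np.zeros(w, dtype=np.intp),
    )


def segmentation_to_csv(seg: ChoroidSegmentation, path) -> None:
    """Export boundaries as CSV: column_index, rpe_row, upper_row, lower_row."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["column_index", "rpe_row", "upper_row", "lower_row"])
        for c in range(seg.rpe.rows.size):
            writer.writerow([c, seg.rpe.rows[c], seg.upper.rows[c], seg.lower.rows[c]])


def segmentation_from_csv(path) -> ChoroidSegmentation:
    """Read boundaries written by :func:`segmentation_to_csv` (or produced by
    an external segmenter in the same layout), validating all invariants."""
    import csv
    from pathlib import Path

    rows = []
    with Path(path).open() as fh:
        reader = csv.DictReader(fh)
        for rec in reader:
            rows.append((int(rec["column_index"]), float(rec["rpe_row"]),
                         float(rec["upper_row"]), float(rec["lower_row"])))
    if not rows:
        raise ValidationError(f"no boundary rows in {path}")
    rows.sort()
    rpe = np.array([r[1] for r in rows])
    upper = np.array([r[2] for r in rows])
    lower = np.array([r[3] for r in rows])
    return ChoroidSegmentation(
        rpe=BoundaryCurve(rpe, BoundaryKind.RPE),
        upper=BoundaryCurve(upper, BoundaryKind.CHOROID_UPPER),
        lower=BoundaryCurve(lower, BoundaryKind.CHOROID_LOWER),
        flatten_shift=np.zeros(rpe.size, dtype=np.intp),
    )


def use_external_boundaries(
    bscan: BScan, upper: BoundaryCurve, lower: BoundaryCurve
) -> ChoroidSegmentation:
    """Wrap externally supplied choroid boundaries unchanged (RPE := upper)."""
    h, w = bscan.image.shape
    for curve in (upper, lower):
        if curve.rows.shape[0] != w or np.any(curve.rows >= h):
            raise ValidationError("boundary does not fit the B-scan")
    if np.any(upper.rows > lower.rows):
        raise ValidationError("upper boundary crosses below lower boundary")
    return ChoroidSegmentation(
        rpe=BoundaryCurve(rows=upper.rows.copy(), kind=BoundaryKind.RPE),
        upper=BoundaryCurve(rows=upper.rows.copy(), kind=BoundaryKind.CHOROID_UPPER),
        lower=BoundaryCurve(rows=lower.rows.copy(), kind=BoundaryKind.CHOROID_LOWER),
        flatten_shift=np.zeros(w, dtype=np.intp),
    )
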