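"""Magnification-corrected choroidal volumetrics over macular rings.

Each radial B-scan samples two opposite semi-meridians of the macula; a
semi-meridian of ``n_radials`` radial lines represents an angular sector of
width ``Δθ = π / n_radials``.  A column at fundus radius ``r`` from the fovea
therefore contributes an annular sector element ``h · r · Δr · Δθ`` to the
volume, where ``h`` is the column's compartment thickness (pixel count ×
axial mm/px) and ``Δr`` the magnification-corrected lateral pixel pitch.
Summing over columns and semi-meridians integrates the compartment volume in
polar coordinates; for a constant-thickness choroid this converges to
``π (R_out² − R_in²) · t``.

Lateral magnification is corrected with Bennett's formula, ``q(AL) = 0.01306
(AL − 1.82)`` mm/degree, applied as the ratio against a reference (emmetropic)
axial length so the device constant cancels.

Reported regions follow the macular-grid convention: ring extents are
diameters in mm, default 0–3, 3–6 and 0–6.  CVI is luminal over total
choroidal volume per ring; a session's CVI is a ratio of summed volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .binarization import BinarizedChoroid
from .errors import ParameterError, UndefinedValueError, ValidationError
from .scan_model import ScanGeometry

__all__ = [
    "DEFAULT_RINGS",
    "REFERENCE_AXIAL_LENGTH_MM",
    "RingSpec",
    "RingVolumes",
    "RegionalVolumes",
    "bennett_lateral_scale",
    "aline_radii",
    "sector_volumes",
    "cvi",
]

DEFAULT_RINGS: tuple[tuple[float, float], ...] = ((0.0, 3.0), (3.0, 6.0), (0.0, 6.0))
REFERENCE_AXIAL_LENGTH_MM = 24.46
_BENNETT_OFFSET_MM = 1.82


@dataclass(frozen=True)
class RingSpec:
    """Macular rings as (inner_diameter_mm, outer_diameter_mm) pairs."""

    rings: tuple[tuple[float, float], ...] = DEFAULT_RINGS

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rings", tuple((float(a), float(b)) for a, b in self.rings)
        )
        for inner, outer in self.rings:
            if not (0 <= inner < outer):
                raise ValidationError(f"ring ({inner}, {outer}) must satisfy 0 ≤ inner < outer")


@dataclass(frozen=True)
class RingVolumes:
    lv_mm3: float
    sv_mm3: float
    tcv_mm3: float
    cvi: float  # NaN when TCV = 0 (undefined, reported as missing)


@dataclass
class RegionalVolumes:
    """LV, SV, TCV (mm³) and CVI per macular ring."""

    by_ring: dict[tuple[float, float], RingVolumes]

    def __getitem__(self, ring: tuple[float, float]) -> RingVolumes:
        return self.by_ring[(float(ring[0]), float(ring[1]))]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ring_inner_mm": inner,
                "ring_outer_mm": outer,
                "LV_mm3": v.lv_mm3,
                "SV_mm3": v.sv_mm3,
                "TCV_mm3": v.tcv_mm3,
                "CVI_pct": v.cvi * 100.0 if not math.isnan(v.cvi) else float("nan"),
            }
            for (inner, outer), v in self.by_ring.items()
        ]
        return pd.DataFrame(rows)


def bennett_lateral_scale(
    axial_length_mm: float, reference_al_mm: float = REFERENCE_AXIAL_LENGTH_MM
) -> float:
    """Relative lateral magnification ``q(AL) / q(AL_ref)``.

    Multiplies the nominal lateral mm-per-pixel; the axial scale is unaffected
    (depth calibration does not depend on ocular magnification).
    """
    for al in (axial_length_mm, reference_al_mm):
        if al <= _BENNETT_OFFSET_MM:
            raise ParameterError(
                f"axial length {al} mm outside the domain of Bennett's formula"
            )
    return (axial_length_mm - _BENNETT_OFFSET_MM) / (reference_al_mm - _BENNETT_OFFSET_MM)


def aline_radii(geometry: ScanGeometry, fovea_col: int, scale: float = 1.0) -> np.ndarray:
    """Signed fundus radius (mm) of every column; negative on the semi-meridian
    left of the fovea, positive right of it."""
    cols = np.arange(geometry.n_alines)
    return (cols - fovea_col) * geometry.lateral_mm_per_px * scale


def cvi(lv_mm3: float, tcv_mm3: float) -> float:
    """Choroidal vascularity index LV/TCV (dimensionless fraction)."""
    if tcv_mm3 == 0:
        raise UndefinedValueError("CVI undefined for TCV = 0")
    if not (0 <= lv_mm3 <= tcv_mm3):
        raise ValidationError("LV must lie in [0, TCV]")
    return lv_mm3 / tcv_mm3


def sector_volumes(
    binarized: Sequence[BinarizedChoroid],
    geometry: ScanGeometry,
    fovea_col: int,
    scale: float = 1.0,
    rings: RingSpec = RingSpec(),
) -> RegionalVolumes:
    """Integrate lumen/stroma/total volumes over macular rings in polar form.

    Expects one binarized B-scan per radial angle, in angle order.  Each
    column's full thickness is assigned to the ring containing its center
    radius (half-open ``[inner, outer)`` in radius); the fovea-center column
    carries zero weight (r = 0).
    """
    if len(binarized) != geometry.n_radials:
        raise ValidationError(
            f"expected one binarized scan per radial ({geometry.n_radials}), "
            f"got {len(binarized)}"
        )
    axial = geometry.axial_mm_per_px
    dr = geometry.lateral_mm_per_px * scale
    dtheta = math.pi / geometry.n_radials
    r = np.abs(aline_radii(geometry, fovea_col, scale))  # (n_alines,)

    # per-column pixel counts summed over scans
    lumen_counts = np.zeros(geometry.n_alines, dtype=np.float64)
    total_counts = np.zeros(geometry.n_alines, dtype=np.float64)
    per_scan_lumen = []
    per_scan_total = []
    for b in binarized:
        if b.roi_mask.shape != (geometry.axial_px, geometry.n_alines):
            raise ValidationError("binarized mask shape does not match geometry")
        per_scan_lumen.append(b.lumen_mask.sum(axis=0).astype(np.float64))
        per_scan_total.append(b.roi_mask.sum(axis=0).astype(np.float64))

    weight = r * dr * dtheta * axial  # volume element per pixel of thickness
    by_ring: dict[tuple[float, float], RingVolumes] = {}
    for inner_d, outer_d in rings.rings:
        in_ring = (r >= inner_d / 2.0) & (r < outer_d / 2.0)
        w = np.where(in_ring, weight, 0.0)
        lv = 0.0
        tcv = 0.0
        sv = 0.0
        for lcount, tcount in zip(per_scan_lumen, per_scan_total):
            lv += float(np.dot(lcount, w))
            tcv += float(np.dot(tcount, w))
            sv += float(np.dot(tcount - lcount, w))
        try:
            ring_cvi = cvi(lv, tcv)
        except UndefinedValueError:
            ring_cvi = float("nan")
        except ValidationError:
            # numerical dust can push LV a hair past TCV; clamp
            ring_cvi = min(max(lv / tcv, 0.0), 1.0)
        by_ring[(inner_d, outer_d)] = RingVolumes(lv_mm3=lv, sv_mm3=sv, tcv_mm3=tcv, cvi=ring_cvi)
    return RegionalVolumes(by_ring=by_ring)
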