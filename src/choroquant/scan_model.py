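"""Data model for radial SS-OCT scan sets.

A session is a set of B-scans acquired as spokes through the fovea at fixed
angular increments (the clinical default: 18 lines at 10° over the
half-circle, 12 mm wide, 2048 A-lines, 3 mm imaged depth).  Images are stored
row-major with row 0 on the vitreous (top) side and columns indexing A-lines;
pixel intervals are half-open ``[i, i+1)``.

Sessions round-trip losslessly through a directory of 8/16-bit grayscale
TIFF/PNG images plus a ``session.json`` sidecar.
"""

from __future__ import annotations

import json
import math
import shutil
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
import numpy as np
import tifffile
import imageio.v3 as iio

from .errors import FormatError, ValidationError

__all__ = [
    "Condition",
    "Timepoint",
    "ScanGeometry",
    "SubjectMeta",
    "SessionLabel",
    "BScan",
    "RadialScanSet",
    "mm_per_px",
    "load_radial_set",
    "save_radial_set",
]


class Condition(str, Enum):
    CONTROL = "control"
    HYPERGLYCEMIA = "hyperglycemia"


class Timepoint(str, Enum):
    BASELINE = "baseline"
    DARK = "dark"
    LIGHT_30S = "light_30s"
    LIGHT_2MIN = "light_2min"
    LIGHT_5MIN = "light_5min"


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition parameters fixing the pixel↔mm conversion and radial layout.

    The radial lines tile the half-circle: ``n_radials × angle_step_deg`` must
    equal 180 (each line contributes two opposite semi-meridians).
    """

    n_radials: int = 18
    angle_step_deg: float = 10.0
    scan_width_mm: float = 12.0
    n_alines: int = 2048
    axial_depth_mm: float = 3.0
    axial_px: int = 512

    def __post_init__(self) -> None:
        if self.n_radials < 1 or self.n_alines < 1 or self.axial_px < 1:
            raise ValidationError("pixel/scan counts must be positive")
        if self.scan_width_mm <= 0 or self.axial_depth_mm <= 0:
            raise ValidationError("physical scan dimensions must be positive")
        if not math.isclose(self.n_radials * self.angle_step_deg, 180.0):
            raise ValidationError(
                f"radial lines must tile the half-circle: "
                f"{self.n_radials} × {self.angle_step_deg}° != 180°"
            )

    @property
    def lateral_mm_per_px(self) -> float:
        return self.scan_width_mm / self.n_alines

    @property
    def axial_mm_per_px(self) -> float:
        return self.axial_depth_mm / self.axial_px


def mm_per_px(geometry: ScanGeometry) -> tuple[float, float]:
    """Return ``(lateral_mm_per_px, axial_mm_per_px)`` for a geometry."""
    return geometry.lateral_mm_per_px, geometry.axial_mm_per_px


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    axial_length_mm: float = 24.46
    age_years: float = 25.0

    def __post_init__(self) -> None:
        if not (15.0 < self.axial_length_mm < 40.0):
            raise ValidationError(
                f"axial length {self.axial_length_mm} mm outside sanity bounds (15, 40)"
            )
        if self.age_years <= 0:
            raise ValidationError("age must be positive")


@dataclass(frozen=True)
class SessionLabel:
    condition: Condition = Condition.CONTROL
    timepoint: Timepoint = Timepoint.BASELINE

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        object.__setattr__(self, "timepoint", Timepoint(self.timepoint))


@dataclass
class BScan:
    """One radial cross-section: rows = depth (top row vitreous side),
    columns = A-lines; ``angle_deg`` orients the radial line in [0, 180)."""

    image: np.ndarray
    angle_deg: float

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 2:
            raise ValidationError("B-scan image must be 2D")
        if np.issubdtype(img.dtype, np.floating) and np.any(img < 0):
            raise ValidationError("B-scan intensities must be nonnegative")
        if not (0.0 <= self.angle_deg < 180.0):
            raise ValidationError(f"angle {self.angle_deg}° outside [0, 180)")
        self.image = img

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BScan):
            return NotImplemented
        return (
            self.angle_deg == other.angle_deg
            and self.image.dtype == other.image.dtype
            and np.array_equal(self.image, other.image)
        )


@dataclass
class RadialScanSet:
    """One session's radial B-scans plus subject metadata and fovea column.

    All radials intersect at the fovea, so the fovea center is a single shared
    column index (manual annotation consumed as input).
    """

    geometry: ScanGeometry
    subject: SubjectMeta
    label: SessionLabel
    bscans: list[BScan]
    fovea_col: int

    def __post_init__(self) -> None:
        g = self.geometry
        if len(self.bscans) != g.n_radials:
            raise ValidationError(
                f"expected {g.n_radials} B-scans, got {len(self.bscans)}"
            )
        seen: set[int] = set()
        for b in self.bscans:
            if b.image.shape != (g.axial_px, g.n_alines):
                raise ValidationError(
                    f"B-scan shape {b.image.shape} != geometry "
                    f"({g.axial_px}, {g.n_alines})"
                )
            k = b.angle_deg / g.angle_step_deg
            if not math.isclose(k, round(k), abs_tol=1e-9):
                raise ValidationError(
                    f"angle {b.angle_deg}° is not a multiple of {g.angle_step_deg}°"
                )
            ki = int(round(k))
            if ki in seen or not (0 <= ki < g.n_radials):
                raise ValidationError(f"duplicate or out-of-range angle {b.angle_deg}°")
            seen.add(ki)
        if not (0 <= self.fovea_col < g.n_alines):
            raise ValidationError(f"fovea_col {self.fovea_col} outside [0, {g.n_alines})")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RadialScanSet):
            return NotImplemented
        return (
            self.geometry == other.geometry
            and self.subject == other.subject
            and self.label == other.label
            and self.fovea_col == other.fovea_col
            and self.bscans == other.bscans
        )


_BIT_DEPTH_DTYPES = {8: np.uint8, 16: np.uint16}


def save_radial_set(
    scan_set: RadialScanSet, directory_path: str | Path, *, overwrite: bool = False
) -> Path:
    """Write a session directory (one TIFF per radial + ``session.json``).

    Refuses to clobber an existing non-empty directory unless ``overwrite``.
    Only 8/16-bit unsigned integer images are stored (lossless contract).
    """
    out = Path(directory_path)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FormatError(f"refusing to overwrite non-empty {out} (pass overwrite=True)")
    dtype = scan_set.bscans[0].image.dtype
    if dtype == np.uint8:
        bit_depth = 8
    elif dtype == np.uint16:
        bit_depth = 16
    else:
        raise FormatError(f"only uint8/uint16 images are stored losslessly, got {dtype}")
    if any(b.image.dtype != dtype for b in scan_set.bscans):
        raise FormatError("all B-scans in a session must share one bit depth")

    if out.exists() and overwrite:
        shutil.rmtree(out)
    out.mkdir(parents=True)
    g = scan_set.geometry
    for b in sorted(scan_set.bscans, key=lambda s: s.angle_deg):
        k = int(round(b.angle_deg / g.angle_step_deg))
        tifffile.imwrite(out / f"bscan_{k:03d}.tif", b.image)
    sidecar = {
        "geometry": {
            "n_radials": g.n_radials,
            "angle_step_deg": g.angle_step_deg,
            "scan_width_mm": g.scan_width_mm,
            "n_alines": g.n_alines,
            "axial_depth_mm": g.axial_depth_mm,
            "axial_px": g.axial_px,
        },
        "subject": {
            "subject_id": scan_set.subject.subject_id,
            "axial_length_mm": scan_set.subject.axial_length_mm,
            "age_years": scan_set.subject.age_years,
        },
        "label": {
            "condition": scan_set.label.condition.value,
            "timepoint": scan_set.label.timepoint.value,
        },
        "fovea_col": scan_set.fovea_col,
        "bit_depth": bit_depth,
    }
    (out / "session.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return out


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(iio.imread(path))


def load_radial_set(directory_path: str | Path) -> RadialScanSet:
    """Load and validate a session directory written by :func:`save_radial_set`.

    Accepts TIFF or PNG images named ``bscan_<k>.<ext>`` where ``k`` is the
    angle index.
    """
    directory = Path(directory_path)
    sidecar_path = directory / "session.json"
    if not sidecar_path.is_file():
        raise FormatError(f"missing sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
        geometry = ScanGeometry(**meta["geometry"])
        subject = SubjectMeta(**meta["subject"])
        label = SessionLabel(**meta["label"])
        fovea_col = int(meta["fovea_col"])
        bit_depth = int(meta.get("bit_depth", 8))
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    if bit_depth not in _BIT_DEPTH_DTYPES:
        raise FormatError(f"unsupported bit depth {bit_depth}")

    bscans: list[BScan] = []
    for k in range(geometry.n_radials):
        candidates = [
            directory / f"bscan_{k:03d}{ext}"
            for ext in (".tif", ".tiff", ".png")
        ]
        path = next((p for p in candidates if p.is_file()), None)
        if path is None:
            raise ValidationError(f"missing B-scan for angle index {k} in {directory}")
        img = _read_image(path)
        if img.dtype != _BIT_DEPTH_DTYPES[bit_depth]:
            raise ValidationError(
                f"{path.name}: dtype {img.dtype} does not match sidecar "
                f"bit_depth {bit_depth}"
            )
        bscans.append(BScan(image=img, angle_deg=k * geometry.angle_step_deg))
    return RadialScanSet(
        geometry=geometry,
        subject=subject,
        label=label,
        bscans=bscans,
        fovea_col=fovea_col,
    )
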