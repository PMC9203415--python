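"""Domain types, coordinate frames and I/O for SD-OCT segmentation volumes.

Coordinate convention (fixed throughout the package)
----------------------------------------------------
* The origin sits at the physical corner of the scanned en face area.
* ``x`` is the fast axis (along a b-scan; reported as "horizontal").
* ``y`` is the slow axis (across b-scans; reported as "vertical").
* A regular en face grid at resolution ``r`` stores sample ``i`` at
  physical position ``(i + 0.5) * r`` (pixel-centre sampling).
* Native volume grids are fence-post sampled: b-scan ``j`` lies at
  ``j * bscan_spacing`` and a-scan ``i`` at ``i * ascan_spacing``, so the
  first and last samples coincide with the scan borders.

Which physical direction a device labels "horizontal" is a convention;
here it is always the fast (a-scan) axis.  Volumes are stored as
multi-page uint8 TIFF label stacks (one page per b-scan, axes
``[axial, a-scan]``) with a JSON sidecar holding the geometry and the
label scheme; annotations are plain CSV.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ScanGeometry",
    "SegmentationVolume",
    "FoveaAnnotation",
    "RORA_LOCATIONS",
    "SCAN_DENSITIES",
    "mm_to_grid",
    "grid_to_mm",
    "read_segmentation_volume",
    "write_segmentation_volume",
    "read_annotations",
    "write_annotations",
]

RORA_LOCATIONS = ("foveal", "extrafoveal", "none")
SCAN_DENSITIES = ("standard", "dense")

#: numerical slack used when comparing physical extents
_EPS = 1e-9


@dataclass(frozen=True)
class ScanGeometry:
    """Physical sampling grid of one SD-OCT macular cube.

    Spacings are in millimetres.  The slow-axis pitch of a standard
    6 x 6 mm cube with 49 b-scans is 0.125 mm; a dense cube doubles the
    b-scan count.
    """

    n_bscans: int
    n_ascans: int
    n_axial: int
    bscan_spacing: float
    ascan_spacing: float
    axial_spacing: float
    extent_x: float = 6.0
    extent_y: float = 6.0

    def __post_init__(self) -> None:
        if self.n_bscans < 2 or self.n_ascans < 2:
            raise ValueError("need at least 2 b-scans and 2 a-scans")
        if self.n_axial < 1:
            raise ValueError("n_axial must be positive")
        for name in ("bscan_spacing", "ascan_spacing", "axial_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if (self.n_bscans - 1) * self.bscan_spacing > self.extent_y + _EPS:
            raise ValueError(
                "b-scan positions exceed declared slow-axis extent: "
                f"({self.n_bscans} - 1) x {self.bscan_spacing} > {self.extent_y}"
            )
        if (self.n_ascans - 1) * self.ascan_spacing > self.extent_x + _EPS:
            raise ValueError(
                "a-scan positions exceed declared fast-axis extent: "
                f"({self.n_ascans} - 1) x {self.ascan_spacing} > {self.extent_x}"
            )

    @classmethod
    def default(
        cls,
        n_bscans: int = 49,
        n_ascans: int = 512,
        n_axial: int = 160,
        axial_spacing: float = 0.0039,
        extent_x: float = 6.0,
        extent_y: float = 6.0,
    ) -> "ScanGeometry":
        """A 6 x 6 mm macular cube; spacings derived fence-post style."""
        return cls(
            n_bscans=n_bscans,
            n_ascans=n_ascans,
            n_axial=n_axial,
            bscan_spacing=extent_y / (n_bscans - 1),
            ascan_spacing=extent_x / (n_ascans - 1),
            axial_spacing=axial_spacing,
            extent_x=extent_x,
            extent_y=extent_y,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScanGeometry":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass
class SegmentationVolume:
    """Per-b-scan retinal layer label maps plus physical geometry.

    ``labels`` is an integer array indexed ``[b-scan, axial, a-scan]``;
    ``label_scheme`` maps layer names (e.g. ``"GCL"``) to label values.
    Background is 0 and never part of the scheme.
    """

    geometry: ScanGeometry
    labels: np.ndarray
    label_scheme: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.geometry
        expected = (g.n_bscans, g.n_axial, g.n_ascans)
        if self.labels.shape != expected:
            raise ValueError(
                f"label array shape {self.labels.shape} does not match "
                f"geometry {expected}"
            )
        if "GCL" not in self.label_scheme or "IPL" not in self.label_scheme:
            raise ValueError("label scheme must include GCL and IPL")
        allowed = set(self.label_scheme.values()) | {0}
        present = set(np.unique(self.labels).tolist())
        unknown = sorted(present - allowed)
        if unknown:
            raise ValueError(f"unknown label values in volume: {unknown}")

    @property
    def layer_names(self) -> list:
        return list(self.label_scheme)


@dataclass(frozen=True)
class FoveaAnnotation:
    """Manual fovea position for one eye, in en face millimetres."""

    eye_id: str
    x_mm: float
    y_mm: float
    grader: str = ""
    rora_location: str = "none"
    scan_density: str = "standard"

    def __post_init__(self) -> None:
        if self.rora_location not in RORA_LOCATIONS:
            raise ValueError(
                f"rora_location {self.rora_location!r} not in {RORA_LOCATIONS}"
            )
        if self.scan_density not in SCAN_DENSITIES:
            raise ValueError(
                f"scan_density {self.scan_density!r} not in {SCAN_DENSITIES}"
            )
        if self.x_mm < 0 or self.y_mm < 0:
            raise ValueError("annotation coordinates must be non-negative")


# ---------------------------------------------------------------------------
# coordinate transforms


def mm_to_grid(p: tuple, resolution: float) -> tuple:
    """Physical (x, y) in mm -> (column, row) index on a pixel-centre grid.

    Pixel ``i`` covers ``[i * res, (i + 1) * res)``.  A small epsilon
    absorbs binary-representation error so that e.g. 3.0 mm at 0.025 mm/px
    maps to pixel 120 exactly.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    x, y = p
    return (
        int(math.floor(x / resolution + _EPS)),
        int(math.floor(y / resolution + _EPS)),
    )


def grid_to_mm(idx: tuple, resolution: float) -> tuple:
    """(column, row) index -> pixel-centre position in mm."""
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    i, j = idx
    return ((i + 0.5) * resolution, (j + 0.5) * resolution)


# ---------------------------------------------------------------------------
# segmentation volume I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_segmentation_volume(vol: SegmentationVolume, path) -> Path:
    """Write a volume as multi-page uint8 TIFF + JSON sidecar.

    Returns the TIFF path; the sidecar shares its stem.
    """
    path = Path(path)
    if max(vol.label_scheme.values(), default=0) > 255:
        raise ValueError("label values must fit in uint8")
    tifffile.imwrite(path, vol.labels.astype(np.uint8))
    sidecar = {
        "geometry": vol.geometry.to_dict(),
        "label_scheme": dict(vol.label_scheme),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _check_contiguity(labels: np.ndarray, scheme: Mapping) -> None:
    """Warn when a layer's voxels are not a contiguous axial run somewhere."""
    n_b, n_z, n_a = labels.shape
    z = np.arange(n_z)[None, :, None]
    for name, value in scheme.items():
        mask = labels == value
        count = mask.sum(axis=1)
        any_col = count > 0
        if not any_col.any():
            continue
        zmin = np.where(mask, z, n_z).min(axis=1)
        zmax = np.where(mask, z, -1).max(axis=1)
        run = zmax - zmin + 1
        if np.any(run[any_col] != count[any_col]):
            warnings.warn(
                f"layer {name!r} is not axially contiguous in some a-scan "
                "columns; thickness is computed by voxel counting",
                stacklevel=3,
            )


def read_segmentation_volume(
    path, label_scheme: Mapping | None = None, check_contiguity: bool = True
) -> SegmentationVolume:
    """Read a multi-page TIFF label stack with its JSON geometry sidecar.

    The sidecar is mandatory: spacings are never guessed.  ``label_scheme``
    overrides the sidecar's scheme when given.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"geometry sidecar {sidecar} is missing; spacings are required "
            "and are never inferred from pixel data"
        )
    meta = json.loads(sidecar.read_text())
    if "geometry" not in meta:
        raise ValueError(f"sidecar {sidecar} has no 'geometry' entry")
    geometry = ScanGeometry.from_dict(meta["geometry"])
    scheme = dict(label_scheme) if label_scheme is not None else meta.get("label_scheme")
    if not scheme:
        raise ValueError("no label scheme in sidecar and none supplied")
    labels = tifffile.imread(path)
    if labels.ndim == 2:  # single page
        labels = labels[None]
    if labels.shape[0] != geometry.n_bscans:
        raise ValueError(
            f"TIFF page count {labels.shape[0]} does not match sidecar "
            f"n_bscans {geometry.n_bscans}"
        )
    vol = SegmentationVolume(geometry=geometry, labels=labels, label_scheme=scheme)
    if check_contiguity:
        _check_contiguity(labels, scheme)
    return vol


# ---------------------------------------------------------------------------
# annotation I/O

_ANNOTATION_COLUMNS = [
    "eye_id",
    "x_mm",
    "y_mm",
    "grader",
    "rora_location",
    "scan_density",
]


def read_annotations(path, extent: tuple | None = None) -> list:
    """Read fovea annotations from CSV.

    When ``extent`` (mm, fast/slow axes) is given, coordinates are
    range-checked and a violating row is reported by number.
    """
    df = pd.read_csv(path, dtype={"eye_id": str})
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation CSV lacks columns: {missing}")
    out = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ann = FoveaAnnotation(
                eye_id=str(row.eye_id),
                x_mm=float(row.x_mm),
                y_mm=float(row.y_mm),
                grader=str(row.grader),
                rora_location=str(row.rora_location),
                scan_density=str(row.scan_density),
            )
        except ValueError as exc:
            raise ValueError(f"annotation row {row_number}: {exc}") from exc
        if extent is not None and not (
            ann.x_mm <= extent[0] + _EPS and ann.y_mm <= extent[1] + _EPS
        ):
            raise ValueError(
                f"annotation row {row_number}: ({ann.x_mm}, {ann.y_mm}) mm "
                f"outside scan extent {extent}"
            )
        out.append(ann)
    return out


def write_annotations(annotations: Sequence[FoveaAnnotation], path) -> Path:
    path = Path(path)
    df = pd.DataFrame([asdict(a) for a in annotations], columns=_ANNOTATION_COLUMNS)
    df.to_csv(path, index=False)
    return path
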