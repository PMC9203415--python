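"""En face layer-thickness projection and isotropic resampling.

A segmentation volume is reduced to a 2D thickness map by counting, in
every a-scan column, the voxels labelled with the requested layers and
multiplying by the axial voxel pitch.  The native map inherits the scan's
anisotropic sampling (e.g. 0.125 mm between b-scans vs ~0.012 mm between
a-scans for a standard 49-b-scan cube) and is bilinearly resampled to a
common isotropic 0.025 mm grid before template matching, which for a
6 x 6 mm cube yields a 240 x 240 map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

from .data import SegmentationVolume

__all__ = [
    "EnFaceMap",
    "DETECTION_RESOLUTION_MM",
    "layer_thickness_map",
    "total_thickness_map",
    "resample",
    "export_enface",
    "import_enface",
]

#: common isotropic grid used for template matching, mm per pixel
DETECTION_RESOLUTION_MM = 0.025


@dataclass
class EnFaceMap:
    """2D scalar thickness grid (mm) on a physical coordinate frame.

    ``values`` is indexed ``[y, x]`` (slow, fast axis).  Sample ``[j, i]``
    sits at physical position ``(offset + index * resolution)`` per axis:
    pixel-centre grids use ``offset = resolution / 2``, native fence-post
    grids use ``offset = 0``.
    """

    values: np.ndarray
    resolution_x: float
    resolution_y: float
    extent_x: float
    extent_y: float
    layer_set: tuple = ()
    offset_x: float = 0.0
    offset_y: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("en face map must be 2D")
        if self.resolution_x <= 0 or self.resolution_y <= 0:
            raise ValueError("resolutions must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("en face map contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("thickness values must be >= 0")
        self.layer_set = tuple(self.layer_set)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def sample_positions(self) -> tuple:
        """Physical positions (x, y) of the grid samples, in mm."""
        ny, nx = self.values.shape
        x = self.offset_x + np.arange(nx) * self.resolution_x
        y = self.offset_y + np.arange(ny) * self.resolution_y
        return x, y


def layer_thickness_map(vol: SegmentationVolume, layers: Sequence[str]) -> EnFaceMap:
    """Project per-column thickness of ``layers`` to a native en face map.

    Thickness at (b-scan j, a-scan i) is the number of voxels in column
    ``(j, :, i)`` carrying any of the requested labels, times the axial
    voxel pitch.  Columns with no such voxels (e.g. an atrophic foveal
    centre) map to 0.
    """
    unknown = [name for name in layers if name not in vol.label_scheme]
    if unknown:
        raise ValueError(
            f"unknown layer name(s) {unknown}; scheme has {sorted(vol.label_scheme)}"
        )
    values = np.isin(vol.labels, [vol.label_scheme[name] for name in layers])
    thickness = values.sum(axis=1) * vol.geometry.axial_spacing
    g = vol.geometry
    return EnFaceMap(
        values=thickness.astype(float),
        resolution_x=g.ascan_spacing,
        resolution_y=g.bscan_spacing,
        extent_x=g.extent_x,
        extent_y=g.extent_y,
        layer_set=tuple(layers),
        offset_x=0.0,
        offset_y=0.0,
    )


def total_thickness_map(vol: SegmentationVolume) -> EnFaceMap:
    """Full-retina (all labelled layers) thickness at native resolution."""
    return layer_thickness_map(vol, list(vol.label_scheme))


def resample(m: EnFaceMap, target_resolution: float = DETECTION_RESOLUTION_MM) -> EnFaceMap:
    """Bilinearly resample a map onto an isotropic pixel-centre grid.

    Output shape is ``round(extent / target_resolution)`` per axis with
    samples at ``(i + 0.5) * target_resolution``.  Sample coordinates are
    clamped to the source grid, so output values stay within the input
    range (bilinear convexity).
    """
    if target_resolution <= 0:
        raise ValueError("target_resolution must be > 0")
    if target_resolution > min(m.extent_x, m.extent_y):
        raise ValueError(
            f"target resolution {target_resolution} mm exceeds the scan "
            f"extent ({m.extent_x} x {m.extent_y} mm)"
        )
    nx = int(round(m.extent_x / target_resolution))
    ny = int(round(m.extent_y / target_resolution))
    x_mm = (np.arange(nx) + 0.5) * target_resolution
    y_mm = (np.arange(ny) + 0.5) * target_resolution
    # fractional source indices, clamped to the valid range (edge clamp)
    col = (x_mm - m.offset_x) / m.resolution_x
    row = (y_mm - m.offset_y) / m.resolution_y
    col = np.clip(col, 0, m.values.shape[1] - 1)
    row = np.clip(row, 0, m.values.shape[0] - 1)
    rr, cc = np.meshgrid(row, col, indexing="ij")
    out = ndimage.map_coordinates(m.values, [rr, cc], order=1, mode="nearest")
    return EnFaceMap(
        values=out,
        resolution_x=target_resolution,
        resolution_y=target_resolution,
        extent_x=m.extent_x,
        extent_y=m.extent_y,
        layer_set=m.layer_set,
        offset_x=0.5 * target_resolution,
        offset_y=0.5 * target_resolution,
    )


# ---------------------------------------------------------------------------
# I/O: 32-bit float TIFF + JSON geometry sidecar


def export_enface(m: EnFaceMap, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, m.values.astype(np.float32))
    meta = {
        "resolution_x": m.resolution_x,
        "resolution_y": m.resolution_y,
        "extent_x": m.extent_x,
        "extent_y": m.extent_y,
        "offset_x": m.offset_x,
        "offset_y": m.offset_y,
        "layer_set": list(m.layer_set),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def import_enface(path) -> EnFaceMap:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"geometry sidecar {sidecar} is missing")
    meta = json.loads(sidecar.read_text())
    values = tifffile.imread(path).astype(float)
    return EnFaceMap(
        values=values,
        resolution_x=meta["resolution_x"],
        resolution_y=meta["resolution_y"],
        extent_x=meta["extent_x"],
        extent_y=meta["extent_y"],
        layer_set=tuple(meta.get("layer_set", ())),
        offset_x=meta.get("offset_x", 0.0),
        offset_y=meta.get("offset_y", 0.0),
    )
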