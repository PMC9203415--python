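"""Comparison detectors: scan centre and thinnest central retinal point.

The scan-centre baseline stands in for the fixation-based centering an
OCT device performs at acquisition time; the thinnest-point baseline is
the classical fovea definition (minimum ILM-to-BM retinal thickness),
which degrades under atrophy and acquisition artifacts.
"""

from __future__ import annotations

import math

import numpy as np

from .data import ScanGeometry, mm_to_grid
from .detector import DetectionResult
from .enface import EnFaceMap, DETECTION_RESOLUTION_MM

__all__ = ["center_baseline", "thinnest_point_baseline", "DEFAULT_BORDER_EXCLUSION_PX"]

#: native a-scan pixels dropped at the left/right b-scan borders, where
#: acquisition artifacts are common
DEFAULT_BORDER_EXCLUSION_PX = 50


def center_baseline(geom: ScanGeometry, eye_id: str = "") -> DetectionResult:
    """Assume the fovea at the geometric centre of the scanned area."""
    x_mm = geom.extent_x / 2.0
    y_mm = geom.extent_y / 2.0
    x_px, y_px = mm_to_grid((x_mm, y_mm), DETECTION_RESOLUTION_MM)
    return DetectionResult(
        x_mm=x_mm,
        y_mm=y_mm,
        x_px=x_px,
        y_px=y_px,
        reliability=math.nan,
        method="center",
        eye_id=eye_id,
        bscan_index=min(int(round(y_mm / geom.bscan_spacing)), geom.n_bscans - 1),
        ascan_index=min(int(round(x_mm / geom.ascan_spacing)), geom.n_ascans - 1),
    )


def thinnest_point_baseline(
    total_thickness: EnFaceMap,
    geom: ScanGeometry,
    border_exclusion: int = DEFAULT_BORDER_EXCLUSION_PX,
    eye_id: str = "",
) -> DetectionResult:
    """Assume the fovea at the minimum total retinal thickness.

    Operates on the native-resolution full-retina thickness map;
    ``border_exclusion`` native a-scan columns are dropped on each side
    of every b-scan.  Ties are broken by the smallest row-major index.
    """
    values = total_thickness.values
    n_ascans = values.shape[1]
    if 2 * border_exclusion >= n_ascans:
        raise ValueError(
            f"border exclusion of {border_exclusion} px per side covers the "
            f"entire b-scan width ({n_ascans} a-scans)"
        )
    allowed = values[:, border_exclusion : n_ascans - border_exclusion]
    flat = int(np.argmin(allowed))
    y_px, x_off = np.unravel_index(flat, allowed.shape)
    x_px = int(x_off) + border_exclusion
    x_mm = total_thickness.offset_x + x_px * total_thickness.resolution_x
    y_mm = total_thickness.offset_y + y_px * total_thickness.resolution_y
    return DetectionResult(
        x_mm=float(x_mm),
        y_mm=float(y_mm),
        x_px=x_px,
        y_px=int(y_px),
        reliability=math.nan,
        method="thinnest",
        eye_id=eye_id,
        bscan_index=int(y_px) if total_thickness.offset_y == 0.0 else None,
        ascan_index=x_px if total_thickness.offset_x == 0.0 else None,
    )
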