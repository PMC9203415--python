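"""Template construction, matched filtering and detection behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octfovea import (
    DetectionResult,
    EnFaceMap,
    ScanGeometry,
    build_template,
    detect,
    match_template,
    to_volume_coords,
)


def _iso_map(values):
    ny, nx = values.shape
    return EnFaceMap(
        values=values,
        resolution_x=0.025, resolution_y=0.025,
        extent_x=nx * 0.025, extent_y=ny * 0.025,
        offset_x=0.0125, offset_y=0.0125,
    )


class TestBuildTemplate:
    def test_physical_width_matches_foveola(self, template):
        assert template.foveola_width_mm == pytest.approx(0.35, abs=1e-12)

    def test_center_value_closed_form(self, template):
        c = (template.size - 1) // 2
        assert template.kernel[c, c] == pytest.approx(-1.0 / (2 * math.pi * 49), rel=1e-12)

    def test_inverted_with_unique_minimum_at_center(self, template):
        c = (template.size - 1) // 2
        assert np.all(template.kernel <= 0)
        assert np.argmin(template.kernel) == c * template.size + c
        assert (template.kernel == template.kernel[c, c]).sum() == 1

    def test_radial_and_point_symmetry(self, template):
        k, c = template.kernel, (template.size - 1) // 2
        for off in (1, 5, 17, 40):
            assert k[c + off, c] == k[c, c + off] == k[c - off, c] == k[c, c - off]
        np.testing.assert_array_equal(k, k[::-1, ::-1])

    def test_weight_sum_near_minus_one(self, template):
        assert -1.0 <= template.kernel.sum() <= -0.999

    def test_even_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            build_template(size=80)


class TestMatchTemplate:
    def test_delta_map_reproduces_translated_kernel(self, template):
        values = np.zeros((120, 120))
        y0, x0, v = 60, 55, 0.08
        values[y0, x0] = v
        heat = match_template(_iso_map(values), template)
        half = (template.size - 1) // 2
        window = heat.values[y0 - half : y0 + half + 1, x0 - half : x0 + half + 1]
        np.testing.assert_allclose(window, v * template.kernel, atol=1e-12)

    def test_constant_map_scales_kernel_sum(self, template):
        c = 0.09
        heat = match_template(_iso_map(np.full((100, 100), c)), template)
        np.testing.assert_allclose(heat.values, c * template.kernel.sum(), atol=1e-12)

    def test_resolution_mismatch_instructs_resample(self, template):
        m = EnFaceMap(
            values=np.zeros((49, 512)),
            resolution_x=6 / 511, resolution_y=0.125,
            extent_x=6.0, extent_y=6.0,
        )
        with pytest.raises(ValueError, match="resample"):
            match_template(m, template)

    def test_map_smaller_than_template_rejected(self, template):
        with pytest.raises(ValueError, match="smaller"):
            match_template(_iso_map(np.zeros((40, 40))), template)


class TestDetect:
    def test_tie_broken_by_smallest_row_major_index(self, template):
        values = np.full((120, 120), 0.09)
        # two identical pits, symmetric content
        values[50, 50] = 0.0
        values[80, 90] = 0.0
        det = detect(_iso_map(values), template)
        assert (det.y_px, det.x_px) == (50, 50)

    def test_reliability_equals_heatmap_at_detection(self, template):
        values = np.full((120, 120), 0.09)
        values[60, 60] = 0.0
        m = _iso_map(values)
        det = detect(m, template)
        heat = match_template(m, template)
        assert det.reliability == heat.values[det.y_px, det.x_px]

    def test_recovers_clean_phantom_pit(self, clean_iso_map, template):
        det = detect(clean_iso_map, template)
        assert abs(det.x_mm - 3.0) <= 0.025
        assert abs(det.y_mm - 3.0) <= 0.025

    def test_nan_map_rejected(self, template):
        with pytest.raises(ValueError, match="finite|non-finite"):
            _iso_map(np.full((100, 100), np.nan))


class TestVolumeCoords:
    def test_known_positions(self, default_geometry):
        det = DetectionResult(x_mm=3.0, y_mm=3.0, x_px=120, y_px=120, reliability=0.0)
        # 3.0 mm / 0.125 mm = b-scan 24; 3.0 mm sits midway between
        # a-scans 255 and 256 (pitch 6/511 mm) and rounds to 256
        assert to_volume_coords(det, default_geometry) == (24, 256)
        det0 = DetectionResult(x_mm=0.0, y_mm=0.0, x_px=0, y_px=0, reliability=0.0)
        assert to_volume_coords(det0, default_geometry) == (0, 0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        x=st.floats(0.0, 6.0, allow_nan=False),
        y=st.floats(0.0, 6.0, allow_nan=False),
    )
    def test_round_trip_within_half_spacing(self, x, y, default_geometry):
        g = default_geometry
        det = DetectionResult(x_mm=x, y_mm=y, x_px=0, y_px=0, reliability=0.0)
        b, a = to_volume_coords(det, g)
        assert abs(b * g.bscan_spacing - y) <= g.bscan_spacing / 2 + 1e-9
        assert abs(a * g.ascan_spacing - x) <= g.ascan_spacing / 2 + 1e-9


class TestDetectorProperties:
    def test_translation_equivariance(self, clean_iso_map, template, rng):
        det0 = detect(clean_iso_map, template)
        for _ in range(10):
            dy = int(rng.integers(-30, 31))
            dx = int(rng.integers(-30, 31))
            shifted = _iso_map(np.roll(clean_iso_map.values, (dy, dx), axis=(0, 1)))
            det = detect(shifted, template)
            assert (det.y_px - det0.y_px, det.x_px - det0.x_px) == (dy, dx)
            assert abs(det.reliability - det0.reliability) <= 1e-9

    def test_reliability_decreases_as_pit_flattens(self, clean_iso_map, template):
        """Blending the map toward a flat parafoveal sheet lowers the score."""
        base = clean_iso_map.values
        para = base.max()
        fovea_px = detect(clean_iso_map, template)
        scores = []
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            blended = _iso_map((1 - lam) * base + lam * para)
            heat = match_template(blended, template)
            scores.append(heat.values[fovea_px.y_px, fovea_px.x_px])
        assert all(s1 > s2 for s1, s2 in zip(scores, scores[1:]))
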