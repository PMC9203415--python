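"""Synthetic phantom generator: determinism, ground truth, failure modes."""

import numpy as np
import pytest

from octfovea import ScanGeometry, layer_thickness_map, total_thickness_map
from octfovea.phantom import (
    ArtifactSpec,
    CohortJitter,
    DrusenSpec,
    PhantomSpec,
    PitSpec,
    RoraSpec,
    cohort_rora_summary,
    generate,
    generate_cohort,
    paper_like_base,
    paper_like_jitter,
    sample_cohort_specs,
)


def _gclipl_labels(vol):
    scheme = vol.label_scheme
    return np.isin(vol.labels, [scheme["GCL"], scheme["IPL"]])


class TestGenerate:
    def test_same_seed_bit_identical(self, default_geometry):
        spec = PhantomSpec(geometry=default_geometry, noise_sd=0.01, seed=42)
        v1, _ = generate(spec)
        v2, _ = generate(spec)
        np.testing.assert_array_equal(v1.labels, v2.labels)

    def test_different_seeds_differ_under_noise(self, default_geometry):
        base = dict(geometry=default_geometry, noise_sd=0.01)
        v1, _ = generate(PhantomSpec(**base, seed=42))
        v2, _ = generate(PhantomSpec(**base, seed=43))
        assert not np.array_equal(v1.labels, v2.labels)

    @pytest.mark.parametrize("profile", ["gaussian", "cosine"])
    def test_noiseless_map_minimum_at_fovea_cell(self, default_geometry, profile):
        """The fovea's native cell attains the global minimum; the
        discretised pit floor is a plateau, so the check is tie-inclusive."""
        spec = PhantomSpec(
            geometry=default_geometry, fovea_mm=(2.5, 3.5), pit=PitSpec(profile=profile)
        )
        vol, truth = generate(spec)
        m = layer_thickness_map(vol, ("GCL", "IPL"))
        g = vol.geometry
        j = round(truth.fovea_mm[1] / g.bscan_spacing)
        i = round(truth.fovea_mm[0] / g.ascan_spacing)
        assert m.values[j, i] == m.values.min()

    def test_fovea_too_close_to_border_rejected(self, default_geometry):
        with pytest.raises(ValueError, match="border"):
            generate(PhantomSpec(geometry=default_geometry, fovea_mm=(0.2, 3.0)))

    def test_lesion_outside_extent_rejected(self, default_geometry):
        spec = PhantomSpec(
            geometry=default_geometry, rora=RoraSpec(center_mm=(9.0, 3.0), radius_mm=1.0)
        )
        with pytest.raises(ValueError, match="extent"):
            generate(spec)


class TestRora:
    def test_location_enum_matches_mask_at_fovea(self, default_geometry):
        foveal = PhantomSpec(
            geometry=default_geometry,
            rora=RoraSpec(center_mm=(3.2, 3.0), radius_mm=1.0),
        )
        _, truth = generate(foveal)
        assert truth.rora_location == "foveal"

        extrafoveal = PhantomSpec(
            geometry=default_geometry,
            rora=RoraSpec(center_mm=(1.2, 1.5), radius_mm=1.0),
        )
        _, truth = generate(extrafoveal)
        assert truth.rora_location == "extrafoveal"
        g = default_geometry
        assert not truth.rora_mask[round(3.0 / g.bscan_spacing), round(3.0 / g.ascan_spacing)]

        _, truth = generate(PhantomSpec(geometry=default_geometry))
        assert truth.rora_location == "none"

    def test_outer_only_lesion_leaves_inner_labels_bit_identical(self, default_geometry):
        base = PhantomSpec(geometry=default_geometry, noise_sd=0.008, seed=9)
        lesioned = PhantomSpec(
            geometry=default_geometry,
            noise_sd=0.008,
            seed=9,
            rora=RoraSpec(center_mm=(1.5, 1.5), radius_mm=1.2),
            drusen=(DrusenSpec(center_mm=(4.5, 4.5)),),
        )
        v1, _ = generate(base)
        v2, _ = generate(lesioned)
        np.testing.assert_array_equal(_gclipl_labels(v1), _gclipl_labels(v2))

    def test_inner_damage_distorts_gclipl(self, default_geometry):
        damaged = PhantomSpec(
            geometry=default_geometry,
            rora=RoraSpec(center_mm=(3.0, 3.0), radius_mm=1.5, inner_layer_damage_fraction=0.8),
        )
        intact = PhantomSpec(geometry=default_geometry)
        v_dam, _ = generate(damaged)
        v_int, _ = generate(intact)
        assert not np.array_equal(_gclipl_labels(v_dam), _gclipl_labels(v_int))


def test_artifact_strictly_reduces_total_thickness_in_its_row(default_geometry):
    plain = PhantomSpec(geometry=default_geometry)
    cut = PhantomSpec(geometry=default_geometry, artifact=ArtifactSpec(bscan_index=10, cut_fraction=0.5))
    t_plain = total_thickness_map(generate(plain)[0]).values
    t_cut = total_thickness_map(generate(cut)[0]).values
    row_p, row_c = t_plain[10], t_cut[10]
    removed = row_c < row_p
    assert removed.all()  # 50% cut removes voxels in every column
    np.testing.assert_array_equal(np.delete(t_plain, 10, axis=0), np.delete(t_cut, 10, axis=0))


class TestCohort:
    def test_same_arguments_same_cohort(self):
        base, jitter = paper_like_base(), paper_like_jitter()
        s1 = sample_cohort_specs(8, base, jitter, seed=3)
        s2 = sample_cohort_specs(8, base, jitter, seed=3)
        assert s1 == s2

    def test_single_member(self):
        members = generate_cohort(1, paper_like_base(), paper_like_jitter(), seed=0)
        assert len(members) == 1

    def test_empty_jitter_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            CohortJitter(rora_area_range_mm2=(2.0, 1.0))

    def test_paper_like_composition(self):
        """n=55 draws approximate the target cohort: RORA areas around
        7.42 +/- 5.06 mm^2 and a roughly 32:23 foveal/extrafoveal split."""
        specs = sample_cohort_specs(55, paper_like_base(), paper_like_jitter(), seed=1)
        summary = cohort_rora_summary(specs)
        assert summary["n_with_rora"] == 55
        assert 5.0 < summary["rora_area_mean_mm2"] < 10.0
        n_foveal = sum(
            1 for s in specs
            if (s.rora.center_mm[0] - s.fovea_mm[0]) ** 2
            + (s.rora.center_mm[1] - s.fovea_mm[1]) ** 2
            <= s.rora.radius_mm**2
        )
        assert 20 <= n_foveal <= 45
        n_dense = sum(1 for s in specs if s.geometry.n_bscans == 98)
        assert 4 <= n_dense <= 25
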