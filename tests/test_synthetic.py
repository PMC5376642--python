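"""Ground-truthed scene generation and the non-image sample generators."""

import numpy as np
import pytest

from ferrofossil.morphometry import mode_estimate
from ferrofossil.stereology import QuotaConstants, cell_volume
from ferrofossil.synthetic import (
    SceneParams,
    generate_compositions,
    generate_dspacings,
    generate_morphotype_population,
    generate_section_scene,
    generate_segment_lengths,
)

GREENALITE_TERNARY = {"Fe": 3 / 14, "Si": 2 / 14, "O": 9 / 14}
QUARTZ_TERNARY = {"Fe": 0.0, "Si": 1 / 3, "O": 2 / 3}


class TestSectionScene:
    def test_empty_cell_has_no_interior_signal(self):
        params = SceneParams(
            seed=5, crystal_volume_fraction=0.0, background_volume_fraction=0.0,
            pixel_size_nm=20.0, frame_margin_um=1.0, section_offset_um=0.0,
        )
        stack, gt = generate_section_scene(params)
        assert len(gt.particles) == 0
        interior_fe = stack.channel("Fe").intensities[gt.region_labels == 1]
        # pure noise: well below any crystal signal
        assert interior_fe.max() < 100

    def test_ground_truth_concentration_matches_quota_constants(self):
        params = SceneParams(seed=1, section_offset_um=0.0)
        _, gt = generate_section_scene(params)
        factor = QuotaConstants.paper_compat().atoms_per_um3_of_crystal
        # achieved volume fraction ~ requested 0.058 → ~9.6e8 atoms/μm³
        assert gt.true_concentration() == pytest.approx(
            gt.volume_fraction_interior * factor
        )
        assert gt.true_concentration() == pytest.approx(9.6e8, rel=0.10)

    def test_quota_equals_concentration_times_volume_exactly(self, default_scene):
        _, gt = default_scene
        for convention in ("standard_sphere", "paper_sphere"):
            v = cell_volume(gt.geometry(convention))
            assert gt.true_quota(volume_convention=convention) == pytest.approx(
                gt.true_concentration() * v, rel=1e-12
            )

    def test_determinism_byte_identical(self):
        params = SceneParams(seed=11, pixel_size_nm=20.0, frame_margin_um=1.0)
        s1, g1 = generate_section_scene(params)
        s2, g2 = generate_section_scene(params)
        for el in s1.channels:
            assert np.array_equal(
                s1.channels[el].intensities, s2.channels[el].intensities
            )
        assert np.array_equal(g1.region_labels, g2.region_labels)
        assert g1.particles.equals(g2.particles)

    def test_region_labels_partition_frame(self, default_scene):
        _, gt = default_scene
        assert set(np.unique(gt.region_labels)) <= {0, 1, 2, 3}

    def test_summed_particle_areas_match_rasterized_section_fraction(
        self, noisefree_scene
    ):
        _, gt = noisefree_scene
        interior = gt.particles[gt.particles.region == "interior"]
        raster = (
            interior.pixel_count.sum() * gt.params.pixel_size_nm**2
        )
        assert interior.area_nm2.sum() == pytest.approx(raster, rel=0.05)

    def test_cylinder_scene(self):
        params = SceneParams(
            shape="cylinder", diameter_um=4.5, length_um=10.0,
            crystal_volume_fraction=0.04, wall_thickness_nm=150.0,
            pixel_size_nm=20.0, seed=3,
        )
        stack, gt = generate_section_scene(params)
        assert gt.volume_fraction_interior == pytest.approx(0.04, rel=0.15)
        assert (gt.region_labels == 1).any()

    def test_infeasible_packing_raises(self):
        from ferrofossil.synthetic import SceneFeasibilityError

        params = SceneParams(
            diameter_um=1.0, wall_thickness_nm=100.0,
            crystal_median_diameter_nm=900.0, crystal_volume_fraction=0.5,
            pixel_size_nm=20.0, seed=0,
        )
        with pytest.raises((SceneFeasibilityError, ValueError)):
            generate_section_scene(params)

    def test_delesse_pooled_recovery(self):
        """Pooled drawn area fraction over many random sections approaches the
        3-D volume fraction (Delesse principle)."""
        tot_crystal_px = 0
        tot_interior_px = 0
        vf = []
        for i in range(30):
            params = SceneParams(
                seed=3000 + i, crystal_volume_fraction=0.05,
                background_volume_fraction=0.0, pixel_size_nm=20.0,
                frame_margin_um=0.8,
            )
            _, gt = generate_section_scene(params)
            interior = gt.region_labels == 1
            tot_crystal_px += int((interior & (gt.crystal_labels > 0)).sum())
            tot_interior_px += int(interior.sum())
            vf.append(gt.volume_fraction_interior)
        pooled = tot_crystal_px / tot_interior_px
        assert pooled == pytest.approx(np.mean(vf), rel=0.15)


class TestCompositions:
    def test_lambda_one_is_endmember(self):
        (m,) = generate_compositions(GREENALITE_TERNARY, QUARTZ_TERNARY, [1.0])
        for el, v in GREENALITE_TERNARY.items():
            assert m[el] == pytest.approx(v)

    def test_midpoint_arithmetic(self):
        (m,) = generate_compositions(GREENALITE_TERNARY, QUARTZ_TERNARY, [0.5])
        assert m["Fe"] == pytest.approx(0.1071, abs=1e-4)
        assert m["Si"] == pytest.approx(0.2381, abs=1e-4)
        assert m["O"] == pytest.approx(0.6548, abs=1e-4)

    def test_endpoints(self):
        host_m, end_m = generate_compositions(
            GREENALITE_TERNARY, QUARTZ_TERNARY, [0.0, 1.0]
        )
        assert host_m["Si"] == pytest.approx(1 / 3)
        assert end_m["Fe"] == pytest.approx(3 / 14)

    def test_noisy_measurements_renormalized(self):
        ms = generate_compositions(
            GREENALITE_TERNARY, QUARTZ_TERNARY, [0.3] * 20, noise_sd=0.02, seed=4
        )
        for m in ms:
            assert sum(m.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(v >= 0 for v in m.values())


class TestSegmentLengths:
    def test_lower_bound_respected(self):
        lengths = generate_segment_lengths(5, seed=42)
        assert lengths.size == 5
        assert (lengths >= 1.5).all()

    def test_large_sample_mode(self):
        lengths = generate_segment_lengths(200, seed=7)
        assert mode_estimate(lengths) == pytest.approx(3.5, abs=0.5)

    def test_degenerate_sd(self):
        assert (generate_segment_lengths(10, sd_um=0.0, seed=0) == 3.5).all()

    def test_seeded_determinism(self):
        a = generate_segment_lengths(50, seed=9)
        b = generate_segment_lengths(50, seed=9)
        assert np.array_equal(a, b)


class TestDspacings:
    def test_zero_jitter_returns_references(self, minerals):
        assert generate_dspacings(minerals["greenalite"]) == [7.2, 23.0]

    def test_jitter_bounded(self, minerals):
        obs = generate_dspacings(minerals["greenalite"], jitter_angstrom=0.1, seed=3)
        for o, d in zip(obs, [7.2, 23.0]):
            assert abs(o - d) <= 0.1

    def test_empty_reference_list_errors(self, minerals):
        import dataclasses

        bare = dataclasses.replace(minerals["quartz"], d_spacings_angstrom=[])
        with pytest.raises(ValueError):
            generate_dspacings(bare)


class TestMorphotypePopulation:
    def test_population_covers_all_classes(self):
        records, truths = generate_morphotype_population(n=60, seed=0)
        assert len(records) == 60
        assert set(truths) == {
            "Huroniospora_thin", "Huroniospora_thick", "Gminuta_T1",
            "Gminuta_T2", "Ggrandis_T2", "Animikiea_T1",
        }
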