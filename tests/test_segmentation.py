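"""Fe-mineral segmentation: thresholding, particle labelling, region logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ferrofossil.refdb import ElementChannel, ElementMapStack
from ferrofossil.segmentation import (
    RegionMasks,
    area_fraction,
    assign_regions,
    label_particles,
    threshold_fe,
)


def _fe_stack(arr, px=10.0):
    return ElementMapStack({"Fe": ElementChannel("Fe", np.asarray(arr, float), px)})


class TestThreshold:
    def test_all_zero_channel_gives_empty_mask(self):
        assert not threshold_fe(_fe_stack(np.zeros((8, 8)))).any()

    def test_otsu_separates_bimodal_exactly(self):
        img = np.full((20, 20), 10.0)
        img[5:10, 5:10] = 200.0
        mask = threshold_fe(_fe_stack(img))
        assert np.array_equal(mask, img == 200.0)

    def test_fixed_above_max_is_empty(self):
        img = np.random.default_rng(0).uniform(0, 50, (16, 16))
        assert not threshold_fe(_fe_stack(img), "fixed", 1000.0).any()

    def test_fixed_requires_value(self):
        with pytest.raises(ValueError):
            threshold_fe(_fe_stack(np.zeros((4, 4))), "fixed")

    def test_missing_fe_channel(self):
        stack = ElementMapStack({"Si": ElementChannel("Si", np.zeros((4, 4)), 10.0)})
        with pytest.raises(KeyError):
            threshold_fe(stack)

    @given(st.integers(min_value=0, max_value=250), st.integers(min_value=0, max_value=250))
    @settings(max_examples=25, deadline=None)
    def test_monotonicity_in_threshold(self, t1, t2):
        """Raising a fixed threshold never increases mask area."""
        img = np.random.default_rng(7).uniform(0, 255, (32, 32))
        stack = _fe_stack(img)
        lo, hi = sorted((t1, t2))
        assert (
            threshold_fe(stack, "fixed", float(hi)).sum()
            <= threshold_fe(stack, "fixed", float(lo)).sum()
        )


class TestLabelParticles:
    def test_square_particle_geometry(self):
        mask = np.zeros((20, 20), bool)
        mask[3:8, 3:8] = True
        (p,) = label_particles(mask, pixel_size_nm=10.0)
        assert p.pixel_count == 25
        assert p.area_nm2 == pytest.approx(2500.0)
        assert p.equivalent_diameter_nm == pytest.approx(56.4, abs=0.1)
        assert p.centroid == (5.0, 5.0)

    def test_diagonal_pixels_conn4_discarded(self):
        mask = np.zeros((10, 10), bool)
        mask[2, 2] = mask[3, 3] = True
        assert label_particles(mask, 10.0, min_pixels=4, connectivity=4) == []

    def test_diagonal_pixels_conn8_merge(self):
        mask = np.zeros((10, 10), bool)
        mask[2, 2] = mask[3, 3] = True
        parts = label_particles(mask, 10.0, min_pixels=2, connectivity=8)
        assert len(parts) == 1 and parts[0].pixel_count == 2

    def test_empty_mask(self):
        assert label_particles(np.zeros((5, 5), bool), 10.0) == []


class TestRegions:
    def _annulus_masks(self, n=60, r_in=15, r_out=25):
        c = (n - 1) / 2
        yy, xx = np.mgrid[:n, :n]
        d = np.hypot(yy - c, xx - c)
        interior = d <= r_in
        wall = (d <= r_out) & ~interior
        background = d > r_out + 2
        return RegionMasks(interior, wall, background)

    def test_masks_must_be_disjoint(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        with pytest.raises(ValueError):
            RegionMasks(m, m, np.zeros((5, 5), bool))

    def test_centroid_assignment(self):
        masks = self._annulus_masks()
        mask = np.zeros((60, 60), bool)
        mask[28:32, 28:32] = True   # centre → interior
        mask[8:11, 28:31] = True    # on the wall band
        mask[1:4, 1:4] = True       # far corner → background
        parts = assign_regions(label_particles(mask, 10.0, min_pixels=4), masks)
        regions = sorted(p.region for p in parts)
        assert regions == ["background", "interior", "wall"]

    def test_scene_region_accuracy(self, default_scene):
        """≥95% of segmented particles land in their ground-truth region."""
        stack, gt = default_scene
        masks = gt.region_masks()
        mask = threshold_fe(stack)
        parts = assign_regions(label_particles(mask, stack.pixel_size_nm), masks)
        truth = gt.particles.set_index("crystal_id")["region"]
        checked = correct = 0
        for p in parts:
            r, c = int(round(p.centroid[0])), int(round(p.centroid[1]))
            cid = gt.crystal_labels[r, c]
            if cid > 0:
                checked += 1
                correct += truth.loc[cid] == p.region
        assert checked > 50
        assert correct / checked >= 0.95


class TestAreaFraction:
    def test_no_particles_is_zero(self):
        mask = np.ones((10, 10), bool)
        assert area_fraction([], mask, 10.0) == 0.0

    def test_full_coverage_is_one(self):
        region = np.ones((10, 10), bool)
        parts = label_particles(region, 10.0)
        assert area_fraction(parts, region, 10.0) == pytest.approx(1.0)

    def test_empty_region_errors(self):
        with pytest.raises(ValueError):
            area_fraction([], np.zeros((4, 4), bool), 10.0)

    def test_noisefree_scene_recovers_drawn_fraction(self, noisefree_scene):
        """Noise-free segmentation reproduces the drawn section fraction to
        within rasterization error (≤2% relative)."""
        stack, gt = noisefree_scene
        masks = gt.region_masks()
        mask = threshold_fe(stack)
        parts = assign_regions(
            label_particles(mask, stack.pixel_size_nm, min_pixels=1), masks
        )
        measured = area_fraction(
            parts, masks.interior, stack.pixel_size_nm, region="interior"
        )
        drawn = gt.section_area_fraction("interior")
        assert measured == pytest.approx(drawn, rel=0.02)

    def test_region_disjointness_conserves_total_area(self, default_scene):
        stack, gt = default_scene
        masks = gt.region_masks()
        mask = threshold_fe(stack)
        parts = assign_regions(label_particles(mask, stack.pixel_size_nm), masks)
        total = sum(p.area_nm2 for p in parts)
        by_region = sum(
            sum(p.area_nm2 for p in parts if p.region == r)
            for r in ("interior", "wall", "background")
        )
        assert by_region == pytest.approx(total)
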