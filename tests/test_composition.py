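"""Ternary projection, mixing-line deconvolution and mineral identification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ferrofossil.composition import (
    CompositionMeasurement,
    RedoxMeasurement,
    fit_mixing_line,
    match_dspacing,
    match_stoichiometry,
    redox_label,
    reference_ternaries,
    si_o_ratio,
    ternary_project,
)
from ferrofossil.synthetic import generate_compositions

GREENALITE = np.array([3 / 14, 2 / 14, 9 / 14])
QUARTZ = np.array([0.0, 1 / 3, 2 / 3])


class TestTernaryProject:
    def test_quartz_already_in_subspace(self):
        v = ternary_project({"Si": 1 / 3, "O": 2 / 3})
        assert v == pytest.approx([0.0, 1 / 3, 2 / 3])

    def test_greenalite_visible_atoms(self):
        v = ternary_project({"Fe": 3, "Si": 2, "O": 9})
        assert v == pytest.approx([0.2143, 0.1429, 0.6429], abs=1e-4)

    def test_carbon_excluded_and_renormalized(self):
        m = CompositionMeasurement({"Fe": 0.2, "Si": 0.1, "O": 0.5, "C": 0.2})
        v = ternary_project(m)
        assert v.sum() == pytest.approx(1.0)
        assert v == pytest.approx(np.array([0.2, 0.1, 0.5]) / 0.8)

    def test_idempotence(self):
        v = ternary_project({"Fe": 0.3, "Si": 0.3, "O": 0.4})
        again = ternary_project(dict(zip(("Fe", "Si", "O"), v)))
        assert again == pytest.approx(v)

    def test_all_absent_errors(self):
        with pytest.raises(ValueError):
            ternary_project({"C": 1.0})


class TestMixingLine:
    def _mixture_points(self, lambdas, noise=0.0, seed=0):
        ms = generate_compositions(
            dict(zip(("Fe", "Si", "O"), GREENALITE)),
            dict(zip(("Fe", "Si", "O"), QUARTZ)),
            lambdas, noise_sd=noise, seed=seed,
        )
        return [ternary_project(m) for m in ms]

    def test_noisefree_recovery_exact(self):
        pts = self._mixture_points([0.2, 0.4, 0.6, 0.8, 1.0])
        fit = fit_mixing_line(pts, QUARTZ)
        assert fit.collinearity_rms == pytest.approx(0.0, abs=1e-12)
        assert fit.endmember_estimate == pytest.approx(GREENALITE, abs=1e-12)

    def test_noisy_recovery_within_002(self):
        pts = self._mixture_points(list(np.linspace(0.2, 1.0, 25)), noise=0.01, seed=5)
        fit = fit_mixing_line(pts, QUARTZ)
        assert np.linalg.norm(fit.endmember_estimate - GREENALITE) < 0.02

    def test_two_points_exact(self):
        pts = self._mixture_points([0.5, 1.0])
        fit = fit_mixing_line(pts, QUARTZ)
        assert fit.collinearity_rms == pytest.approx(0.0, abs=1e-12)

    def test_all_points_at_host_errors(self):
        with pytest.raises(ValueError):
            fit_mixing_line([QUARTZ, QUARTZ], QUARTZ)

    def test_traversing_crystals_define_endmember(self):
        pts = self._mixture_points([0.3, 0.6, 1.0, 1.0])
        fit = fit_mixing_line(pts, QUARTZ, traverses_section=[False, False, True, True])
        assert fit.endmember_estimate == pytest.approx(GREENALITE, abs=1e-12)

    def test_endmember_lies_on_fitted_line(self):
        pts = self._mixture_points(list(np.linspace(0.3, 1.0, 15)), noise=0.005, seed=2)
        fit = fit_mixing_line(pts, QUARTZ)
        rel = fit.endmember_estimate - fit.host
        off_line = rel - (rel @ fit.direction) * fit.direction
        assert np.linalg.norm(off_line) < 1e-12


class TestSiORatio:
    def test_quartz(self):
        assert si_o_ratio({"Si": 1 / 3, "O": 2 / 3}) == pytest.approx(0.5)

    def test_greenalite_all_oxygen(self):
        assert si_o_ratio({"Si": 2 / 14, "Fe": 3 / 14, "O": 9 / 14}) == pytest.approx(
            2 / 9, abs=1e-4
        )

    def test_greenalite_hydroxyl_blind(self):
        assert si_o_ratio({"Si": 2 / 10, "Fe": 3 / 10, "O": 5 / 10}) == pytest.approx(0.4)

    def test_zero_oxygen_errors(self):
        with pytest.raises(ValueError):
            si_o_ratio({"Si": 1.0})


class TestStoichiometryMatch:
    def test_exact_greenalite(self, minerals):
        m = match_stoichiometry(dict(zip(("Fe", "Si", "O"), GREENALITE)), list(minerals.values()))
        assert m is not None and m.mineral == "greenalite"
        assert m.distance == pytest.approx(0.0, abs=1e-12)

    def test_midpoint_mixture_matches_nothing(self, minerals):
        mid = 0.5 * (GREENALITE + QUARTZ)
        assert match_stoichiometry(mid, list(minerals.values())) is None

    def test_empty_refs_errors(self):
        with pytest.raises(ValueError):
            match_stoichiometry(dict(zip(("Fe", "Si", "O"), GREENALITE)), [])

    def test_hydrous_minerals_carry_two_conventions(self, minerals):
        ternaries = reference_ternaries(minerals["greenalite"])
        assert set(ternaries) == {"all_O", "hydroxyl_blind"}
        assert ternaries["hydroxyl_blind"] == pytest.approx([0.3, 0.2, 0.5])


class TestDspacingMatch:
    def test_greenalite_both_planes(self, minerals):
        (best, *_) = match_dspacing([7.2, 23.0], list(minerals.values()))
        assert best.mineral == "greenalite"
        assert best.n_matched == 2
        assert best.mean_residual_angstrom == pytest.approx(0.0)

    def test_single_plane_within_tolerance(self, minerals):
        results = match_dspacing([7.35], list(minerals.values()))
        assert [r.mineral for r in results] == ["greenalite"]
        assert results[0].n_matched == 1

    def test_no_candidates_outside_tolerance(self, minerals):
        assert match_dspacing([5.0], list(minerals.values())) == []

    def test_empty_observation_errors(self, minerals):
        with pytest.raises(ValueError):
            match_dspacing([], list(minerals.values()))

    @given(st.permutations([7.2, 23.0]))
    @settings(max_examples=5, deadline=None)
    def test_order_invariance(self, minerals, observed):
        results = match_dspacing(list(observed), list(minerals.values()))
        assert [r.mineral for r in results] == ["greenalite"]
        assert results[0].mean_residual_angstrom == pytest.approx(0.0)


class TestRedox:
    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.0045, "ferrous"), (0.0, "ferrous"), (0.5, "mixed/ferric")],
    )
    def test_labels(self, fraction, expected):
        assert redox_label(RedoxMeasurement(fraction)) == expected

    def test_bounded_input(self):
        with pytest.raises(ValueError):
            RedoxMeasurement(1.5)
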