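"""MCT algebra, isocline recovery against the analytic LV oracle, dynamics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from mctipm.coexistence import (
    CompetitionCoefficients,
    classify_outcome,
    competition_coefficients,
    competitive_ability_ratio,
    equilibrium_point,
    find_isocline,
    niche_overlap,
    propagate_uncertainty,
    simulate_competition,
)
from mctipm.truth import identical_latitudes_truth
from mctipm.vital_rates import ModelSet, VitalRateModel


def lv_lambda(r, a_own, a_other):
    """Analytic single-class growth: lambda = exp(r (1 - a11 N1 - a12 N2))."""
    return lambda own, other: float(np.exp(r * (1 - a_own * own
                                                - a_other * other)))


def lv_equilibrium(a11, a12, a21, a22):
    det = a11 * a22 - a12 * a21
    return (a22 - a12) / det, (a11 - a21) / det


class TestMetrics:
    def test_niche_overlap_worked_values(self):
        assert niche_overlap(CompetitionCoefficients(0.01, 0.01, 0.01, 0.01)) \
            == pytest.approx(1.0)
        assert niche_overlap(CompetitionCoefficients(0.01, 0.0, 0.0, 0.01)) \
            == pytest.approx(0.0)
        assert niche_overlap(CompetitionCoefficients(0.04, 0.01, 0.01, 0.01)) \
            == pytest.approx(0.5)

    def test_competitive_ability_worked_values(self):
        assert competitive_ability_ratio(
            CompetitionCoefficients(0.01, 0.02, 0.02, 0.01)) == pytest.approx(1.0)
        assert competitive_ability_ratio(
            CompetitionCoefficients(0.04, 0.01, 0.01, 0.01)) == pytest.approx(2.0)

    def test_domain_errors(self):
        bad = CompetitionCoefficients(-0.01, 0.01, 0.01, 0.01)
        with pytest.raises(ValueError):
            niche_overlap(bad)
        with pytest.raises(ValueError):
            competitive_ability_ratio(bad)

    @given(st.lists(st.floats(1e-4, 1e-1), min_size=4, max_size=4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_window_condition_equals_invasion_conditions(self, alphas):
        """rho < k1/k2 < 1/rho holds exactly when both invasions succeed.

        Exact boundary ties (a11 == a21 or a22 == a12) are excluded: both
        sides of the equivalence sit on a knife edge there and float
        rounding decides them arbitrarily; the classifier counts ties as
        non-coexistence.
        """
        a11, a12, a21, a22 = alphas
        assume(a11 != a21 and a22 != a12)
        c = CompetitionCoefficients(a11, a12, a21, a22)
        rho = niche_overlap(c)
        k = competitive_ability_ratio(c)
        window = rho < k < 1.0 / rho
        invasion = (a11 > a21) and (a22 > a12)
        assert window == invasion


class TestClassification:
    def test_mutual_invasibility(self):
        assert classify_outcome(CompetitionCoefficients(
            0.02, 0.01, 0.01, 0.02)) == "stable_coexistence"

    def test_priority_effect(self):
        assert classify_outcome(CompetitionCoefficients(
            0.01, 0.02, 0.02, 0.01)) == "priority_effect"

    def test_one_sided_exclusions(self):
        assert classify_outcome(CompetitionCoefficients(
            0.02, 0.02, 0.01, 0.01)) == "exclusion_of_south"
        assert classify_outcome(CompetitionCoefficients(
            0.01, 0.01, 0.02, 0.02)) == "exclusion_of_north"

    def test_boundary_tie_is_not_coexistence(self):
        assert classify_outcome(CompetitionCoefficients(
            0.01, 0.01, 0.01, 0.01)) == "priority_effect"

    def test_viability_shortcut(self):
        assert classify_outcome(None, south_viable=False) == "exclusion_of_south"
        assert classify_outcome(None, north_viable=False) == "exclusion_of_north"
        assert classify_outcome(None, south_viable=False, north_viable=False,
                                lam_south=0.8, lam_north=0.9) == \
            "exclusion_of_south"

    @given(st.lists(st.floats(1e-4, 1e-1), min_size=4, max_size=4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_relabeling_invariance(self, alphas):
        """Swapping latitude labels swaps exclusion labels, inverts k, keeps rho."""
        a11, a12, a21, a22 = alphas
        c = CompetitionCoefficients(a11, a12, a21, a22)
        swapped = CompetitionCoefficients(a22, a21, a12, a11)
        mapping = {"exclusion_of_south": "exclusion_of_north",
                   "exclusion_of_north": "exclusion_of_south",
                   "stable_coexistence": "stable_coexistence",
                   "priority_effect": "priority_effect"}
        assert classify_outcome(swapped) == mapping[classify_outcome(c)]
        assert niche_overlap(swapped) == pytest.approx(niche_overlap(c))
        k, ks = competitive_ability_ratio(c), competitive_ability_ratio(swapped)
        assert ks == pytest.approx(1.0 / k, rel=1e-9)


class TestIsoclineOnLVOracle:
    def test_axis_intercepts_recovered(self):
        iso = find_isocline(lv_lambda(0.2, 0.002, 0.001), latitude="S")
        assert iso.present
        assert iso.intercept_own == pytest.approx(500.0, rel=0.01)
        assert iso.intercept_other == pytest.approx(1000.0, rel=0.01)
        assert iso.r_squared > 0.999

    def test_no_competitor_effect_flat_isocline(self):
        iso = find_isocline(lv_lambda(0.3, 0.004, 0.0), latitude="S")
        assert iso.slope == pytest.approx(0.0, abs=1e-6)
        assert iso.intercept_own == pytest.approx(250.0, rel=0.01)
        assert np.isinf(iso.intercept_other)

    def test_nonviable_population_flagged_absent(self):
        iso = find_isocline(lambda own, other: 0.9, latitude="N")
        assert not iso.present
        assert np.isnan(iso.intercept_own)

    def test_full_chain_recovers_lv_parameters(self, rng):
        """Isocline -> coefficients -> metrics chain vs the analytic model."""
        for _ in range(20):
            r1, r2 = rng.uniform(0.05, 0.4, 2)
            a11, a22 = 1.0 / rng.uniform(150, 800, 2)
            a12 = a11 * rng.uniform(0.3, 1.5)
            a21 = a22 * rng.uniform(0.3, 1.5)
            iso_s = find_isocline(lv_lambda(r1, a11, a12), latitude="S")
            iso_n = find_isocline(lv_lambda(r2, a22, a21), latitude="N")
            c = competition_coefficients(iso_s, iso_n)
            for est, true in zip((c.a11, c.a12, c.a21, c.a22),
                                 (a11, a12, a21, a22)):
                assert est == pytest.approx(true, rel=0.01)
            assert classify_outcome(c) == classify_outcome(
                CompetitionCoefficients(a11, a12, a21, a22))
            n_s, n_n, _ = equilibrium_point(iso_s, iso_n)
            e_s, e_n = lv_equilibrium(a11, a12, a21, a22)
            if e_s > 0 and e_n > 0:
                assert n_s == pytest.approx(e_s, rel=0.01)
                assert n_n == pytest.approx(e_n, rel=0.01)


class TestEquilibrium:
    def _iso(self, own, other, lat):
        from mctipm.coexistence import Isocline
        pts = pd.DataFrame({"other": [0.0, other / 2], "own": [own, own / 2]})
        return Isocline(
            latitude=lat, points=pts, slope=-own / other, intercept_own=own,
            intercept_other=other, r_squared=1.0, present=True,
            lam_low_density=1.2)

    def test_symmetric_latitudes_give_half(self):
        iso_s = self._iso(500.0, 1000.0, "S")
        iso_n = self._iso(500.0, 1000.0, "N")
        n_s, n_n, p = equilibrium_point(iso_s, iso_n)
        assert p == pytest.approx(0.5)
        assert n_s == pytest.approx(n_n)

    def test_worked_linear_solve(self):
        # a11 = a22 = 0.02, a12 = a21 = 0.01 -> N* = (100/3, 100/3)
        iso_s = self._iso(50.0, 100.0, "S")
        iso_n = self._iso(50.0, 100.0, "N")
        n_s, n_n, p = equilibrium_point(iso_s, iso_n)
        assert n_s == pytest.approx(100.0 / 3, rel=1e-9)
        assert n_n == pytest.approx(100.0 / 3, rel=1e-9)
        assert p == pytest.approx(0.5)

    def test_exclusion_geometry_snaps_proportion(self):
        # Southern isocline everywhere inside the Northern one -> South wins
        iso_s = self._iso(200.0, 250.0, "S")
        iso_n = self._iso(900.0, 600.0, "N")
        *_, p = equilibrium_point(iso_n, iso_s)  # north "south" dominates
        assert p in (0.0, 1.0)


class TestDynamics:
    def test_identical_latitudes_stay_balanced(self, temp_std):
        models = ModelSet.from_truth(identical_latitudes_truth())
        traj = simulate_competition(models, temp_std(22), n_days=60)
        np.testing.assert_allclose(traj["p_south"], 0.5, atol=1e-9)

    def test_single_latitude_equilibrates_at_carrying_capacity(
            self, truth_models, temp_std):
        """Alone, a latitude settles where lambda = 1 (own-axis intercept)."""
        T = temp_std(22)
        iso = find_isocline(truth_models, T, "S")
        from mctipm.coexistence import neonate_state
        from mctipm.ipm import KernelBuilder, MeshConfig
        mesh = MeshConfig()
        state = neonate_state(truth_models, T, "S", 6.0, mesh)
        b = KernelBuilder(truth_models, T, "S", mesh=mesh)
        for _ in range(250):
            P, F, _ = b.matrices(S=float(state.sum()), A=0.0)
            state = (P + F) @ state
        assert float(state.sum()) == pytest.approx(iso.intercept_own, rel=0.02)

    def test_divergence_guard(self, truth_models, temp_std):
        with pytest.raises(RuntimeError, match="diverged"):
            simulate_competition(truth_models, temp_std(22), n_days=30,
                                 init_per_latitude=6.0, max_density=10.0)


class TestUncertaintyPropagation:
    def test_zero_variance_draws_degenerate_fractions(self, truth_models,
                                                      temp_std):
        """Constant draws: every draw classifies identically."""
        n = 5
        models = {}
        for r, m in truth_models.models.items():
            models[r] = VitalRateModel(
                rate=r, family=m.family, terms=m.terms, coef=m.coef,
                residual_sd=m.residual_sd, draws=np.tile(m.coef, (n, 1)),
                residual_sd_draws=(np.full(n, m.residual_sd)
                                   if m.residual_sd else None))
        per_draw, summary = propagate_uncertainty(
            ModelSet(models), temp_std(22), n_draws=n, n_grid=8)
        fr = summary["classification_fractions"]
        assert set(fr.values()) <= {0.0, 1.0}
        assert sum(fr.values()) == pytest.approx(1.0)
        assert per_draw["p_south"].nunique() == 1

    def test_requires_enough_draws(self, truth_models, temp_std):
        with pytest.raises(ValueError, match="draws"):
            propagate_uncertainty(truth_models, temp_std(22), n_draws=10)
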