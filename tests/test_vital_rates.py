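"""Vital-rate models: prediction identities, fitting, selection, frequencies."""

import numpy as np
import pandas as pd
import pytest

from mctipm.simulate import sample_frequency_data, sample_rate_records
from mctipm.structures import design_matrix, structure_terms
from mctipm.truth import FrequencyTruth, RateTruth, TrueParameters, default_truth
from mctipm.vital_rates import (
    InferenceConfig,
    ModelSet,
    VitalRateModel,
    fit_genotype_frequencies,
    fit_vital_rate,
    partition_densities,
    prepare_records,
    rate_frame,
    select_model,
)


def _cov_frame(**kw):
    base = {"z": 0.0, "T": 0.0, "S": 0.0, "A": 0.0, "L": 0.0, "sex": 0.0}
    base.update(kw)
    return pd.DataFrame({k: [v] for k, v in base.items()})


class TestPredictionIdentities:
    def test_logistic_all_zero_gives_half(self):
        m = VitalRateModel(rate="egg_prob", family="binomial",
                           terms=("1", "z", "S"), coef=[0.0, 0.0, 0.0])
        assert m.predict(_cov_frame(z=1.3, S=250.0))[0] == pytest.approx(0.5)

    def test_poisson_intercept_ln2_gives_two(self):
        m = VitalRateModel(rate="clutch_size", family="poisson",
                           terms=("1",), coef=[np.log(2.0)])
        assert m.predict(_cov_frame())[0] == pytest.approx(2.0)

    def test_link_scale_is_exact_dot_product(self):
        terms = structure_terms("M5", "survival")
        rng = np.random.default_rng(3)
        coef = rng.normal(size=len(terms))
        m = VitalRateModel(rate="survival", family="binomial", terms=terms,
                           coef=coef)
        cov = _cov_frame(z=0.7, T=-1.2, S=120.0, A=30.0, L=1.0, sex=1.0)
        X = design_matrix(terms, cov)
        assert m.linpred(cov)[0] == pytest.approx(float(X[0] @ coef), abs=1e-12)

    def test_affine_density_decomposition_matches_linpred(self, truth_models):
        z = np.linspace(-2.5, 2.5, 7)
        for rate, model in truth_models.models.items():
            base, kS, kA = model.affine_in_density(z, T=0.9, L=1.0, sex=0.0)
            for S, A in [(0.0, 0.0), (150.0, 40.0), (900.0, 900.0)]:
                cov = pd.DataFrame({"z": z, "T": 0.9, "S": S, "A": A,
                                    "L": 1.0, "sex": 0.0})
                np.testing.assert_allclose(base + kS * S + kA * A,
                                           model.linpred(cov), atol=1e-10)

    def test_response_ranges(self, truth_models):
        cov = pd.DataFrame({"z": np.linspace(-2.5, 2.5, 20), "T": 2.0,
                            "S": 500.0, "A": 500.0, "L": 0.0, "sex": 0.0})
        for rate in ("survival", "egg_prob", "release_prob", "female_prob"):
            p = truth_models[rate].predict(cov)
            assert np.all((p >= 0) & (p <= 1))
        assert np.all(truth_models["clutch_size"].predict(cov) >= 0)


class TestFitting:
    def test_recovers_known_density_coefficient(self, truth):
        frame = sample_rate_records(truth, "egg_prob", 2000, seed=8)
        m = fit_vital_rate(frame, "egg_prob", "M2",
                           InferenceConfig(n_draws=500, seed=9))
        i = m.terms.index("S")
        true_bS = truth.rates["egg_prob"].coef["S"]
        se = m.draws[:, i].std()
        assert m.coef[i] == pytest.approx(true_bS, abs=4 * se)
        assert m.coef[i] < 0
        assert m.n_draws == 500

    def test_draw_store_finite_and_large(self, truth):
        frame = sample_rate_records(truth, "growth", 1000, seed=2)
        m = fit_vital_rate(frame, "growth", "M1",
                           InferenceConfig(n_draws=1000, seed=3))
        assert m.draws.shape == (1000, len(m.terms))
        assert np.all(np.isfinite(m.draws))
        assert m.residual_sd == pytest.approx(0.035, rel=0.15)

    def test_constant_response_error_names_rate(self, truth):
        frame = sample_rate_records(truth, "survival", 200, seed=4)
        frame["y"] = 1.0
        with pytest.raises(Exception, match="survival"):
            fit_vital_rate(frame, "survival", "M1")

    def test_missing_column_raises_schema_error(self, truth):
        frame = sample_rate_records(truth, "survival", 100, seed=4)
        with pytest.raises(KeyError):
            fit_vital_rate(frame.drop(columns=["T"]), "survival", "M1")


class TestModelSelection:
    def test_tie_breaks_toward_fewer_parameters(self, truth):
        frame = sample_rate_records(truth, "clutch_size", 400, seed=5)
        tab = select_model(frame, "clutch_size", ["M2", "M2"],
                           InferenceConfig(n_draws=300, seed=6))
        assert tab.selected == "M2"
        assert tab.table["selected"].sum() == 1
        assert tab.table.loc[tab.table["selected"], :].index[0] == 0

    def test_interaction_truth_selects_full_structure(self):
        """Data generated under strong three-way interactions favor M5."""
        base = default_truth()
        rates = dict(base.rates)
        rates["female_prob"] = RateTruth(
            coef={"1": 1.0, "z": 0.0, "T": 0.2, "S": -0.004, "A": -0.006,
                  "L": 0.3, "T:S": 0.0, "T:A": -0.006, "L:S": 0.0,
                  "L:A": -0.004, "L:T": 0.0, "T:L:S": 0.0, "T:L:A": 0.012},
            clone_sd=0.05)
        truth = TrueParameters(rates=rates, frequency=base.frequency)
        frame = sample_rate_records(truth, "female_prob", 5000, seed=12)
        tab = select_model(frame, "female_prob", ["M1", "M3", "M5"],
                           InferenceConfig(n_draws=400, seed=13))
        assert tab.selected == "M5"

    def test_additive_truth_keeps_simple_structure_competitive(self):
        """Under additive truth, M1's ELPD is within 2 SE of the best."""
        base = default_truth()
        rates = dict(base.rates)
        rates["clutch_size"] = RateTruth(
            coef={"1": 1.6, "z": 0.4, "T": 0.1, "S": -0.002, "A": -0.001,
                  "L": 0.1},
            clone_sd=0.05)
        truth = TrueParameters(rates=rates, frequency=base.frequency)
        frame = sample_rate_records(truth, "clutch_size", 5000, seed=14)
        tab = select_model(frame, "clutch_size", ["M1", "M2", "M5"],
                          InferenceConfig(n_draws=400, seed=15))
        t = tab.table
        best = t["elpd"].max()
        m1 = t.loc[t["label"] == "M1"].iloc[0]
        assert m1["elpd"] >= best - 2 * m1["se"]

    def test_failed_candidate_marked_unavailable(self, truth):
        frame = sample_rate_records(truth, "egg_prob", 300, seed=16)
        frame["y"] = 0.0  # degenerate: every candidate fails
        with pytest.raises(RuntimeError):
            select_model(frame, "egg_prob", ["M1", "M2"])


@pytest.fixture(scope="module")
def fitted():
    samples = sample_frequency_data(FrequencyTruth(), seed=21)
    return fit_genotype_frequencies(samples, InferenceConfig(
        n_draws=500, seed=22))


class TestFrequencyModel:
    def test_day_zero_anchor_every_draw(self, fitted):
        for d in range(0, 500, 25):
            assert fitted.p_south(0.0, 1.5, draw=d) == pytest.approx(0.5)
        assert fitted.p_south(0.0, -2.0) == pytest.approx(0.5)

    def test_positive_slope_monotone_in_day(self, fitted):
        days = np.arange(1, 29)
        p = fitted.p_south(days, 1.0)
        assert fitted.linpred(28, 1.0) > 0
        assert np.all(np.diff(p) > 0)

    def test_recovers_generating_slopes(self, fitted):
        assert fitted.beta_day_temp == pytest.approx(0.03, abs=0.03)
        assert (fitted.draws[:, 1] > 0).mean() > 0.8

    def test_single_latitude_separation_warns(self):
        samples = sample_frequency_data(FrequencyTruth(), seed=23)
        samples["latitude_sampled"] = "S"
        with pytest.warns(UserWarning, match="separation"):
            fit_genotype_frequencies(samples, InferenceConfig(n_draws=10))

    def test_requires_multiple_aquaria(self):
        samples = sample_frequency_data(FrequencyTruth(), seed=24)
        samples["aquarium"] = "P0"
        with pytest.raises(ValueError):
            fit_genotype_frequencies(samples)


class TestPartitionDensities:
    def test_single_latitude(self):
        assert partition_densities(100, None, 14, 0.0, None, "S") == (100.0, 0.0)
        assert partition_densities(100, None, 14, 0.0, None, "N") == (0.0, 100.0)

    def test_even_frequency_splits_in_half(self):
        samples = sample_frequency_data(FrequencyTruth(), seed=25)
        fm = fit_genotype_frequencies(samples, InferenceConfig(n_draws=10))
        south, north = partition_densities(100, fm, 0, 0.0, None, "SN")
        assert south == pytest.approx(50.0)
        assert north == pytest.approx(50.0)

    @pytest.mark.parametrize("count", [0, 13, 457])
    def test_components_sum_to_count(self, count):
        samples = sample_frequency_data(FrequencyTruth(), seed=26)
        fm = fit_genotype_frequencies(samples, InferenceConfig(n_draws=10))
        south, north = partition_densities(count, fm, 21, 1.2, "P3", "SN")
        assert south + north == pytest.approx(count, abs=1e-9)
        assert south >= 0 and north >= 0


def test_rate_frame_subsets(truth, reference_design):
    from mctipm.simulate import simulate_experiment
    from mctipm.vital_rates import FrequencyModel
    rec, cen, _ = simulate_experiment(reference_design, truth, seed=31)
    even = FrequencyModel(beta_day=0.0, beta_day_temp=0.0, aquarium_sd=0.0,
                          aquarium_effects={})
    prepared = prepare_records(rec, cen, reference_design, even)
    surv = rate_frame(prepared, "survival")
    assert len(surv) == len(rec)
    growth = rate_frame(prepared, "growth")
    assert (growth["survived"] == 1).all()
    eggs = rate_frame(prepared, "egg_prob")
    assert (eggs["sex"] == 0).all()
    clutch = rate_frame(prepared, "clutch_size")
    assert (clutch["released"] == 1).all()
    females = rate_frame(prepared, "female_prob")
    assert (females["trials"] >= females["y"]).all()
    # densities: single-latitude aquaria have A = 0, mixed have A > 0
    mono_ids = {a.id for a in reference_design.aquaria if not a.is_interlatitudinal}
    assert (prepared.loc[prepared["aquarium"].isin(mono_ids), "A"] == 0).all()
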