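import numpy as np
import pytest

from survflow import (
    cox_fit,
    cox_score_test,
    hazard_ratio_table,
    logrank_test,
    model_from_dict,
    model_to_dict,
    predict_linear,
    predict_survival,
)
from survflow.errors import CollinearityError, DegenerateFeatureError
from survflow.simulate import SimulationConfig, simulate_ph_dataset

from conftest import make_dataset, random_censored


def exact_partial_loglik(beta, times, events, x):
    """Brute-force exact partial likelihood (no ties), independent of the
    Newton implementation."""
    ll = 0.0
    for i in np.flatnonzero(events == 1):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


class TestCoxFit:
    def test_duplicated_groups_beta_zero(self, rng):
        t, e = random_censored(rng, 30)
        ds = make_dataset(
            np.tile(t, 2), np.tile(e, 2),
            np.concatenate([np.zeros(30), np.ones(30)]),
        )
        m = cox_fit(ds)
        assert m.coefficients[0] == pytest.approx(0.0, abs=1e-8)
        assert m.hazard_ratios[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_search_maximizer(self, rng):
        # 8-subject fixture whose exact partial likelihood has an interior max
        times = np.arange(1.0, 9.0)
        events = np.ones(8, dtype=int)
        x = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=float)
        m = cox_fit(make_dataset(times, events, x))
        grid = np.arange(-5, 5, 1e-4)
        vals = np.array([exact_partial_loglik(b, times, events, x) for b in grid])
        assert abs(m.coefficients[0] - grid[vals.argmax()]) <= 1e-4

    def test_separation_flagged_not_raised(self):
        # every x=1 subject fails before any x=0 subject: monotone likelihood
        times = np.arange(1.0, 9.0)
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        with pytest.warns(UserWarning, match="separation"):
            m = cox_fit(make_dataset(times, np.ones(8, int), x))
        assert not m.converged
        assert abs(m.coefficients[0]) > 20

    def test_monte_carlo_recovery(self):
        ests = []
        for seed in range(40):
            ds, _ = simulate_ph_dataset(
                SimulationConfig(n=500, beta=(0.5, -0.5), seed=seed)
            )
            ests.append(cox_fit(ds).coefficients)
        mean = np.mean(ests, axis=0)
        assert abs(mean[0] - 0.5) < 0.05 and abs(mean[1] + 0.5) < 0.05

    def test_constant_feature_rejected(self, rng):
        t, e = random_censored(rng, 20)
        with pytest.raises(DegenerateFeatureError):
            cox_fit(make_dataset(t, e, np.ones(20)))

    def test_collinear_features_rejected(self, rng):
        t, e = random_censored(rng, 50)
        x = rng.standard_normal(50)
        with pytest.raises(CollinearityError):
            cox_fit(make_dataset(t, e, np.column_stack([x, 2 * x])))

    def test_incomplete_cases_dropped_with_count(self, rng):
        t, e = random_censored(rng, 50, cens_frac=0.1)
        x = rng.standard_normal(50)
        x[:5] = np.nan
        with pytest.warns(UserWarning, match="5 incomplete"):
            m = cox_fit(make_dataset(t, e, x))
        assert m.n == 45

    def test_efron_equals_breslow_without_ties(self, rng):
        t, e = random_censored(rng, 80)
        x = rng.standard_normal((80, 2))
        ds = make_dataset(t, e, x)
        me = cox_fit(ds, ties_method="efron")
        mb = cox_fit(ds, ties_method="breslow")
        np.testing.assert_allclose(me.coefficients, mb.coefficients, atol=1e-8)

    def test_efron_differs_from_breslow_with_ties(self, rng):
        t = np.repeat([1.0, 2.0, 3.0, 4.0, 5.0], 8)
        e = rng.integers(0, 2, 40)
        e[:4] = 1
        x = rng.standard_normal(40)
        ds = make_dataset(t, e, x)
        me = cox_fit(ds, ties_method="efron")
        mb = cox_fit(ds, ties_method="breslow")
        assert abs(me.coefficients[0] - mb.coefficients[0]) > 1e-6

    def test_lrt_nonnegative_and_fit_dominates_null(self, small_sim):
        ds, _ = small_sim
        m = cox_fit(ds)
        assert m.lrt_statistic >= 0
        assert m.log_partial_likelihood_fit >= m.log_partial_likelihood_null

    def test_baseline_hazard_monotone(self, small_sim):
        ds, _ = small_sim
        m = cox_fit(ds)
        assert (m.baseline_cumulative_hazard >= 0).all()
        assert (np.diff(m.baseline_cumulative_hazard) >= 0).all()

    def test_coefficients_invariant_to_covariate_offset(self, rng):
        t, e = random_censored(rng, 60)
        x = rng.standard_normal(60)
        m1 = cox_fit(make_dataset(t, e, x))
        m2 = cox_fit(make_dataset(t, e, x + 1e4))
        assert m1.coefficients[0] == pytest.approx(m2.coefficients[0], abs=1e-6)


class TestScoreTest:
    def test_equals_logrank_for_binary_indicator(self, rng):
        for _ in range(5):
            t, e = random_censored(rng, 60)
            g = rng.integers(0, 2, 60).astype(float)
            if e[g == 0].sum() == 0 or e[g == 1].sum() == 0:
                continue
            chi2, df, _ = cox_score_test(make_dataset(t, e, g), ties_method="breslow")
            lr = logrank_test(
                make_dataset(t, e, groups=np.where(g == 1, "A", "B"))
            )
            assert chi2 == pytest.approx(lr.chi_square, abs=1e-8)
            assert df == 1


class TestHazardRatioTable:
    def test_formula_instantiation(self, rng):
        t, e = random_censored(rng, 60)
        x = rng.standard_normal((60, 2))
        m = cox_fit(make_dataset(t, e, x))
        tab = hazard_ratio_table(m)
        assert list(tab["feature"]) == list(m.feature_names)
        from scipy import stats

        z = stats.norm.ppf(0.975)
        np.testing.assert_allclose(
            tab["hr_ci_lower"], np.exp(m.coefficients - z * m.standard_errors)
        )
        np.testing.assert_allclose(tab["hr"], np.exp(tab["beta"]))


class TestPrediction:
    def test_linear_predictor_centering_and_linearity(self, small_sim):
        ds, _ = small_sim
        m = cox_fit(ds)
        eta_mean = predict_linear(m, m.covariate_means.reshape(1, -1))
        assert eta_mean[0] == pytest.approx(0.0, abs=1e-12)
        a = np.zeros((1, ds.p))
        b = np.zeros((1, ds.p))
        b[0, 0] = 2.5
        diff = predict_linear(m, b)[0] - predict_linear(m, a)[0]
        assert diff == pytest.approx(2.5 * m.coefficients[0], abs=1e-12)

    def test_survival_at_zero_is_one(self, small_sim):
        ds, _ = small_sim
        m = cox_fit(ds)
        s = predict_survival(m, ds.covariates[:5], [0.0])
        np.testing.assert_allclose(s, 1.0)

    def test_mean_subject_gets_baseline_survival(self, small_sim):
        ds, _ = small_sim
        m = cox_fit(ds)
        h = float(m.baseline_times[len(m.baseline_times) // 2])
        s = predict_survival(m, m.covariate_means.reshape(1, -1), [h])[0, 0]
        idx = np.searchsorted(m.baseline_times, h, side="right") - 1
        assert s == pytest.approx(np.exp(-m.baseline_cumulative_hazard[idx]), abs=1e-12)


class TestSerialization:
    def test_round_trip_preserves_predictions(self, small_sim):
        ds, _ = small_sim
        m = cox_fit(ds)
        m2 = model_from_dict(model_to_dict(m))
        horizons = [1.0, 5.0, 20.0]
        np.testing.assert_allclose(
            predict_survival(m, ds.covariates, horizons),
            predict_survival(m2, ds.covariates, horizons),
            atol=1e-15,
        )
        import json

        json.dumps(model_to_dict(m))  # must be JSON-serializable
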