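import numpy as np
import pytest

from survflow import (
    build_nomogram,
    cox_fit,
    observed_ranges_from,
    predict_survival,
    score_patient,
    survival_from_total_points,
)
from survflow.errors import DegenerateRangeError, FlatModelError
from survflow.nomogram import feature_points
from survflow.simulate import SimulationConfig, simulate_ph_dataset

from conftest import make_dataset, random_censored


@pytest.fixture
def fitted(rng):
    ds, _ = simulate_ph_dataset(
        SimulationConfig(
            n=300,
            beta=(0.8, -0.5, 0.3),
            covariate_kinds=("standard_normal", "standard_normal", ("bernoulli", 0.4)),
            seed=9,
        )
    )
    model = cox_fit(ds)
    ranges = observed_ranges_from(ds, model.feature_names)
    return ds, model, ranges


class TestBuildNomogram:
    def test_single_covariate_spans_0_to_100(self, rng):
        t, e = random_censored(rng, 60)
        x = rng.uniform(2, 7, 60)
        model = cox_fit(make_dataset(t, e, x))
        nomo = build_nomogram(model, {"x1": (2.0, 7.0)}, horizons=[5.0])
        pts = feature_points(nomo, np.array([[2.0], [7.0]]))
        lo, hi = sorted(pts.ravel())
        assert lo == pytest.approx(0.0, abs=1e-10)
        assert hi == pytest.approx(100.0, abs=1e-10)

    def test_reference_patient_scores_zero(self, fitted):
        _, model, ranges = fitted
        nomo = build_nomogram(model, ranges, horizons=[5.0])
        res = score_patient(nomo, model, nomo.reference_values)
        assert res["total_points"] == pytest.approx(0.0, abs=1e-9)

    def test_max_points_proportional_to_beta_range_product(self, rng):
        t, e = random_censored(rng, 80)
        X = rng.standard_normal((80, 2))
        model = cox_fit(make_dataset(t, e, X))
        b1, b2 = np.abs(model.coefficients)
        # ranges chosen so |b1| * r1 = 2 * |b2| * r2
        r1 = 1.0 / b1
        r2 = 0.5 / b2
        nomo = build_nomogram(model, {"x1": (0, r1), "x2": (0, r2)}, horizons=[1.0])
        np.testing.assert_allclose(nomo.max_points, [100.0, 50.0], atol=1e-9)

    def test_flat_model_rejected(self, fitted):
        import dataclasses

        _, model, ranges = fitted
        flat = dataclasses.replace(model, coefficients=np.zeros_like(model.coefficients))
        with pytest.raises(FlatModelError):
            build_nomogram(flat, ranges, horizons=[1.0])

    def test_zero_width_range_rejected(self, fitted):
        _, model, ranges = fitted
        bad = dict(ranges)
        bad["x1"] = (3.0, 3.0)
        with pytest.raises(DegenerateRangeError):
            build_nomogram(model, bad, horizons=[1.0])

    def test_points_nonnegative_over_range(self, fitted):
        _, model, ranges = fitted
        nomo = build_nomogram(model, ranges, horizons=[1.0])
        grid = np.linspace(nomo.observed_min, nomo.observed_max, 25)
        pts = feature_points(nomo, grid)
        assert (pts >= -1e-10).all()


class TestScorePatient:
    def test_round_trip_equals_direct_prediction(self, fitted):
        ds, model, ranges = fitted
        horizons = np.quantile(ds.time, [0.25, 0.5, 0.75])
        nomo = build_nomogram(model, ranges, horizons=horizons)
        rng = np.random.default_rng(4)
        X = np.column_stack(
            [
                rng.uniform(lo, hi, 100)
                for lo, hi in zip(nomo.observed_min, nomo.observed_max)
            ]
        )
        direct = predict_survival(model, X, horizons)
        via_nomogram = survival_from_total_points(
            nomo, model, feature_points(nomo, X).sum(axis=1)
        )
        assert np.abs(direct - via_nomogram).max() < 1e-9

    def test_total_points_at_extremes(self, fitted):
        _, model, ranges = fitted
        nomo = build_nomogram(model, ranges, horizons=[5.0])
        # each covariate at the end opposite its reference: full per-feature span
        anti_ref = np.where(
            nomo.reference_values == nomo.observed_min,
            nomo.observed_max,
            nomo.observed_min,
        )
        res = score_patient(nomo, model, anti_ref)
        assert res["total_points"] == pytest.approx(nomo.max_points.sum(), abs=1e-9)

    def test_out_of_range_flagged_and_extrapolates(self, fitted):
        _, model, ranges = fitted
        nomo = build_nomogram(model, ranges, horizons=[5.0])
        x = nomo.observed_max * 1.5
        res = score_patient(nomo, model, x)
        assert res["out_of_range"] is True
        np.testing.assert_allclose(
            res["per_feature_points"],
            (x - nomo.reference_values) * nomo.points_per_unit,
        )

    def test_monotone_in_positive_beta_covariate(self, fitted):
        _, model, ranges = fitted
        nomo = build_nomogram(model, ranges, horizons=[5.0])
        j = int(np.argmax(model.coefficients))
        x = nomo.reference_values.copy()
        totals = []
        for v in np.linspace(nomo.observed_min[j], nomo.observed_max[j], 7):
            x[j] = v
            totals.append(score_patient(nomo, model, x)["total_points"])
        assert (np.diff(totals) >= -1e-12).all()

    def test_invariant_to_affine_covariate_rescaling(self, rng):
        t, e = random_censored(rng, 120)
        X = rng.standard_normal((120, 2))
        ds1 = make_dataset(t, e, X)
        X2 = X.copy()
        X2[:, 0] = 50 + 3 * X2[:, 0]
        ds2 = make_dataset(t, e, X2)
        m1, m2 = cox_fit(ds1), cox_fit(ds2)
        n1 = build_nomogram(m1, observed_ranges_from(ds1, m1.feature_names), [5.0])
        n2 = build_nomogram(m2, observed_ranges_from(ds2, m2.feature_names), [5.0])
        np.testing.assert_allclose(n1.max_points, n2.max_points, atol=1e-6)
        p1 = feature_points(n1, X).sum(axis=1)
        p2 = feature_points(n2, X2).sum(axis=1)
        np.testing.assert_allclose(p1, p2, atol=1e-6)
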