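"""Linear/sigmoid/LOESS fitting, AIC selection, CV classification."""

import numpy as np
import pandas as pd
import pytest

from tfdosage import doseresponse as dr
from tests.conftest import make_sigmoid_points


def pts(x, y):
    return pd.DataFrame({"x": np.asarray(x, float),
                         "y": np.asarray(y, float)})


class TestLinear:
    def test_exact_line_recovered(self):
        x = np.linspace(-2, 2, 20)
        fit = dr.fit_linear(pts(x, 0.5 * x + 0.1))
        assert fit.slope == pytest.approx(0.5, abs=1e-10)
        assert fit.intercept == pytest.approx(0.1, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_constant_y_has_zero_slope(self):
        x = np.linspace(-1, 1, 10)
        fit = dr.fit_linear(pts(x, np.full(10, 0.3)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_closed_form(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20); y = rng.normal(size=20)
        fit = dr.fit_linear(pts(x, y))
        # oracle: closed-form normal equations
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.rmse == pytest.approx(np.sqrt(fit.rss / 20), abs=1e-12)

    def test_degenerate_x_flagged(self):
        fit = dr.fit_linear(pts(np.ones(5), np.arange(5)))
        assert not fit.defined


class TestAIC:
    def test_closed_form_gaussian_value(self):
        aic, floored = dr.compute_aic(10.0, 10, 2)
        expected = 10 * (np.log(2 * np.pi * 1.0) + 1) + 2 * 3
        assert aic == pytest.approx(expected, abs=1e-9)
        assert not floored

    def test_equal_rss_penalty_difference_is_four(self):
        lin, _ = dr.compute_aic(5.0, 30, 2)
        sig, _ = dr.compute_aic(5.0, 30, 4)
        assert lin - sig == pytest.approx(-4.0, abs=1e-12)

    def test_monotone_in_rss(self):
        a1, _ = dr.compute_aic(1.0, 20, 2)
        a2, _ = dr.compute_aic(2.0, 20, 2)
        assert a2 > a1

    def test_zero_rss_floored_and_flagged(self):
        aic, floored = dr.compute_aic(0.0, 10, 2)
        assert floored and np.isfinite(aic)


class TestSigmoid:
    def test_noiseless_parameter_recovery(self):
        x = np.arange(-2, 2.01, 0.5)
        y = dr.sigmoid(x, 0.0, -4.0, 0.0, 1.0)
        fit = dr.fit_sigmoid(pts(x, y))
        assert fit.converged
        assert fit.a == pytest.approx(0.0, abs=1e-3)
        assert fit.b == pytest.approx(-4.0, abs=1e-2)
        assert fit.c == pytest.approx(0.0, abs=1e-3)
        assert fit.d == pytest.approx(1.0, abs=1e-3)

    def test_constant_y_collapses_to_flat(self):
        x = np.linspace(-2, 2, 30)
        fit = dr.fit_sigmoid(pts(x, np.full(30, 0.3)))
        assert abs(fit.d - fit.c) < 1e-6

    def test_midpoint_identity_for_converged_fits(self):
        for seed in range(5):
            p = make_sigmoid_points(0.1, -5, -0.3, 0.7, seed=seed)
            fit = dr.fit_sigmoid(p)
            if fit.converged:
                mid = dr.sigmoid(fit.a, fit.a, fit.b, fit.c, fit.d)
                assert mid == pytest.approx((fit.c + fit.d) / 2, abs=1e-9)

    def test_canonical_orientation_d_above_c(self):
        for seed in range(5):
            p = make_sigmoid_points(0.0, 5, 0.5, -0.5, seed=seed)
            fit = dr.fit_sigmoid(p)
            assert fit.d >= fit.c

    def test_orientation_equivalence_under_y_negation(self):
        p = make_sigmoid_points(0.0, -4, 0.0, 1.0, noise_sd=0.05, seed=8)
        fit = dr.fit_sigmoid(p)
        neg = p.copy(); neg["y"] = -neg["y"]
        fit2 = dr.fit_sigmoid(neg)
        assert fit2.c == pytest.approx(-fit.d, abs=1e-4)
        assert fit2.d == pytest.approx(-fit.c, abs=1e-4)
        assert fit2.b == pytest.approx(-fit.b, rel=1e-3)
        x = np.linspace(-1.5, 0.5, 7)
        np.testing.assert_allclose(fit2.predict(x), -fit.predict(x), atol=1e-4)

    def test_sigmoid_never_fits_worse_than_linear(self):
        # the 4PL approaches a line in its flat b -> 0 valley, so the
        # dominance holds up to optimizer precision there
        rng = np.random.default_rng(9)
        for seed in range(5):
            x = rng.uniform(-1.5, 0.5, 60)
            y = 0.4 * x + rng.normal(0, 0.1, 60)
            p = pts(x, y)
            lin = dr.fit_linear(p)
            sig = dr.fit_sigmoid(p)
            if sig.converged:
                assert sig.rss <= lin.rss * (1 + 1e-3) + 1e-8


class TestDeltaAIC:
    def test_steep_sigmoid_data_prefers_sigmoid(self):
        p = make_sigmoid_points(-0.3, -8, 0.0, 1.0, n=90, noise_sd=0.05,
                                seed=1)
        lin, sig = dr.fit_linear(p), dr.fit_sigmoid(p)
        assert dr.delta_aic(lin, sig) > 2

    def test_linear_truth_keeps_delta_aic_small(self):
        rng = np.random.default_rng(2)
        deltas = []
        for _ in range(50):
            x = rng.uniform(-1.8, 0.8, 90)
            y = 0.5 * x + rng.normal(0, 0.1, 90)
            p = pts(x, y)
            d = dr.delta_aic(dr.fit_linear(p), dr.fit_sigmoid(p))
            if np.isfinite(d):
                deltas.append(d)
        assert np.median(deltas) < 2

    def test_non_converged_sigmoid_gives_nan(self):
        lin = dr.fit_linear(pts(np.arange(5.0), np.arange(5.0)))
        bad = dr.SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                            np.nan, np.nan, 5, converged=False)
        assert np.isnan(dr.delta_aic(lin, bad))


class TestLoess:
    def test_full_span_degree_one_equals_ols(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(-1, 1, 40))
        y = 0.7 * x + 0.2 + rng.normal(0, 0.01, 40)
        lo = dr.fit_loess(pts(x, y), span=1.0, degree=1)
        lin = dr.fit_linear(pts(x, y))
        # tricube weights vary per target point, so the agreement is
        # approximate but close on near-linear data
        np.testing.assert_allclose(lo.fitted, lin.predict(x), atol=0.02)

    def test_bell_shape_recovers_interior_maximum(self):
        x = np.linspace(-1.5, 1.5, 60)
        y = np.exp(-x ** 2)
        lo = dr.fit_loess(pts(x, y), span=0.4, degree=2)
        assert abs(x[np.argmax(lo.fitted)]) < 0.15

    def test_span_too_small_raises_naming_minimum(self):
        x = np.linspace(0, 1, 8)
        with pytest.raises(Exception, match="span"):
            dr.fit_loess(pts(x, x), span=0.01, degree=2)

    def test_rmse_non_negative(self):
        p = make_sigmoid_points(0, -4, 0, 1, n=40, seed=4)
        assert dr.fit_loess(p).rmse >= 0


class TestCV:
    def test_noiseless_cv_is_tight(self):
        p = make_sigmoid_points(0.0, -4, 0.0, 1.0, n=60, noise_sd=0.0, seed=5)
        fit = dr.crossvalidate_sigmoid(p, folds=10, rng_seed=1)
        assert all(sd < 1e-3 for sd in fit.cv_param_sd.values())
        assert fit.heldout_pearson_r > 0.999

    def test_same_seed_reproduces_summaries(self):
        p = make_sigmoid_points(0.0, -4, 0.0, 1.0, seed=6)
        f1 = dr.crossvalidate_sigmoid(p, folds=10, rng_seed=3)
        f2 = dr.crossvalidate_sigmoid(p, folds=10, rng_seed=3)
        assert f1.cv_param_mean == f2.cv_param_mean
        assert f1.heldout_pearson_r == f2.heldout_pearson_r

    def test_needs_at_least_fold_points(self):
        p = make_sigmoid_points(0, -4, 0, 1, n=8, seed=7)
        with pytest.raises(ValueError):
            dr.crossvalidate_sigmoid(p, folds=10, rng_seed=0)


class TestClassification:
    def _fit_with_cv(self, mean, sd):
        fit = dr.SigmoidFit(0, 0, 0, 0, 1, 0, 0.1, 90, converged=True,
                            cv_folds_used=10)
        fit.cv_param_mean = {"a": 0, "b": mean["b"], "c": 0, "d": 0,
                             "range": mean["range"]}
        fit.cv_param_sd = {"a": 0.1, "b": sd["b"], "c": 0.1, "d": 0.1,
                           "range": sd["range"]}
        return fit

    def test_zero_slope_mean_is_unresponsive(self):
        fits = {"g1": self._fit_with_cv({"b": 0.0, "range": 1.0},
                                        {"b": 1.0, "range": 0.01})}
        out = dr.classify_responsive(fits)
        assert not out.iloc[0]["responsive"]

    def test_strong_clean_signal_is_responsive(self):
        fits = {"g1": self._fit_with_cv({"b": -5.0, "range": 0.8},
                                        {"b": 0.2, "range": 0.02})}
        out = dr.classify_responsive(fits)
        assert out.iloc[0]["responsive"]

    def test_range_below_threshold_is_unresponsive(self):
        fits = {"g1": self._fit_with_cv({"b": -5.0, "range": 0.04},
                                        {"b": 0.2, "range": 0.001})}
        out = dr.classify_responsive(fits)
        assert not out.iloc[0]["responsive"]


class TestNonMonotonic:
    def test_identical_fits_give_zero_delta_rmse(self):
        p = make_sigmoid_points(0, -4, 0, 1, n=60, seed=8)
        lo = dr.fit_loess(p)
        out = dr.classify_nonmonotonic({"g": lo.rmse}, {"g": lo})
        assert out.iloc[0]["delta_rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_bells_confirmed_monotonic_not(self):
        # 2 bells in 40 genes: the top-5% rule admits exactly two
        # candidates, so both planted bells must occupy those slots
        rng = np.random.default_rng(9)
        sig_rmse, loess_fits = {}, {}
        for i in range(40):
            x = rng.uniform(-1.8, 0.8, 90)
            if i < 2:    # bell-shaped
                y = 0.8 * np.exp(-((x + 0.5) / 0.4) ** 2)
            else:        # monotone sigmoid
                y = dr.sigmoid(x, -0.5, -5, 0, 0.8)
            y = y + rng.normal(0, 0.05, 90)
            p = pts(x, y)
            sig_rmse[f"g{i}"] = dr.fit_sigmoid(p).rmse
            loess_fits[f"g{i}"] = dr.fit_loess(p)
        out = dr.classify_nonmonotonic(sig_rmse, loess_fits).set_index(
            "trans_gene")
        assert out.loc[["g0", "g1"], "nonmonotonic"].all()
        assert not out.loc[[f"g{i}" for i in range(2, 40)],
                           "nonmonotonic"].any()


class TestPredictionGrid:
    def test_sigmoid_midpoint_value(self):
        fit = dr.SigmoidFit(0, -4, 0, 1, 0, 0, 0, 10, converged=True)
        y, _ = dr.predict_response_grid(fit, np.array([0.0]))
        assert y[0] == pytest.approx(0.5, abs=1e-12)

    def test_grid_endpoint_direct_evaluation(self):
        fit = dr.SigmoidFit(0, -4, 0, 1, 0, 0, 0, 10, converged=True)
        y, _ = dr.predict_response_grid(fit, np.array([-1.83]))
        expected = 1.0 / (1.0 + np.exp(-4 * -1.83))
        assert y[0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.000655, abs=1e-5)

    def test_default_grid_has_101_finite_points(self):
        fit = dr.SigmoidFit(0, -4, 0, 1, 0, 0, 0, 10, converged=True)
        y, extra = dr.predict_response_grid(fit)
        assert len(y) == 101
        assert np.isfinite(y).all()

    def test_loess_extrapolates_flat_with_flag(self):
        p = pts(np.linspace(-1, 0.5, 30),
                np.linspace(-1, 0.5, 30) * 0.5)
        lo = dr.fit_loess(p)
        y, extra = dr.predict_response_grid(lo, np.array([-1.8, 0.0, 0.9]))
        assert extra[0] and extra[2] and not extra[1]
        assert y[0] == pytest.approx(lo.predict(np.array([-1.0]))[0], abs=1e-9)


class TestRestrictedFit:
    def test_default_window_filters_points(self):
        x = np.array([-1.5, -0.9, -0.5, 0.0, 0.3, 0.58, 0.7, -1.0, 0.585])
        p = pts(x, x * 0.5)
        lin, sig, d, n_used = dr.refit_restricted(p)
        assert n_used == 7   # x in [-1.0, 0.585] inclusive

    def test_infinite_bounds_match_unrestricted(self):
        p = make_sigmoid_points(0, -4, 0, 1, n=60, seed=10)
        lin_u = dr.fit_linear(p)
        sig_u = dr.fit_sigmoid(p)
        lin_r, sig_r, d, n_used = dr.refit_restricted(
            p, x_bounds=(-np.inf, np.inf))
        assert n_used == 60
        assert lin_r.slope == pytest.approx(lin_u.slope, abs=1e-12)
        assert sig_r.rss == pytest.approx(sig_u.rss, rel=1e-6)

    def test_too_few_points_skipped(self):
        p = pts([-3, -2.5, 2.0, 2.5], [0, 0, 1, 1])
        lin, sig, d, n_used = dr.refit_restricted(p)
        assert lin is None and np.isnan(d)
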