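"""Calibration fits, prediction intervals and decision thresholds."""

import numpy as np
import pytest
from scipy import optimize
from sklearn.base import clone

from hbpcount import (
    BPCalibrator,
    calibration_table,
    confidence_thresholds,
    fit_linear,
    fit_logit,
    predict_with_pi,
)


def logit(x):
    return np.log(x / (1 - x))


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_three_point_closed_form(self):
        fit = fit_linear([0, 12, 24], [130, 135, 140])
        assert fit.slope == pytest.approx(5 / 12)
        assert fit.intercept == pytest.approx(130.0)

    def test_matches_statsmodels_prediction_interval(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(0, 24, 40)
        y = 130 + 0.4 * x + rng.normal(0, 2, 40)
        fit = fit_linear(x, y)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        at = np.array([0.0, 7.3, 24.0])
        frame = ols.get_prediction(sm.add_constant(at)).summary_frame(alpha=0.05)
        for i, a in enumerate(at):
            band = predict_with_pi(fit, a)
            assert band.estimate == pytest.approx(frame["mean"].iloc[i])
            assert band.pi_low == pytest.approx(frame["obs_ci_lower"].iloc[i])
            assert band.pi_high == pytest.approx(frame["obs_ci_upper"].iloc[i])

    def test_fit_range_subsets_on_response(self):
        x = np.array([0, 6, 12, 18, 24, 30], dtype=float)
        y = np.array([100, 126, 133, 140, 144, 190], dtype=float)
        fit = fit_linear(x, y, fit_range=(125, 145))
        assert fit.n == 4  # 100 and 190 excluded

    def test_errors(self):
        with pytest.raises(ValueError, match="constant predictor"):
            fit_linear([3, 3, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 3"):
            fit_linear([1, 2], [1, 2])


class TestLogitFit:
    def test_zero_noise_recovery(self):
        x = np.linspace(0.1, 0.9, 15)
        y = 135.0 + 6.5 * logit(x)
        fit = fit_logit(x, y)
        assert fit.slope == pytest.approx(6.5, abs=1e-10)
        assert fit.intercept == pytest.approx(135.0, abs=1e-10)
        assert fit.excluded_boundary_points == 0

    def test_boundary_points_excluded_not_clamped(self):
        x = np.array([0.0, 0.2, 0.5, 0.8, 1.0])
        y = np.array([120, 130, 135, 140, 150.0])
        fit = fit_logit(x, y)
        assert fit.excluded_boundary_points == 2
        assert fit.n == 3

    def test_too_few_interior_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_logit([0.0, 0.5, 1.0], [120, 135, 150])

    def test_matches_generic_least_squares(self, rng):
        x = rng.uniform(0.05, 0.95, 30)
        y = 134 + 7 * logit(x) + rng.normal(0, 3, 30)
        fit = fit_logit(x, y)

        def sse(p):
            return y - (p[0] + p[1] * logit(x))

        opt = optimize.least_squares(sse, x0=[100.0, 1.0]).x
        assert fit.intercept == pytest.approx(opt[0], abs=1e-6)
        assert fit.slope == pytest.approx(opt[1], abs=1e-6)


class TestPredictionIntervals:
    def test_zero_residual_collapses(self):
        fit = fit_linear(np.arange(5.0), 2 * np.arange(5.0))
        band = predict_with_pi(fit, 3.0)
        assert band.pi_low == pytest.approx(band.estimate)
        assert band.pi_high == pytest.approx(band.estimate)

    def test_width_minimal_at_predictor_mean(self, rng):
        x = rng.uniform(0, 24, 50)
        y = 130 + 0.4 * x + rng.normal(0, 2, 50)
        fit = fit_linear(x, y)
        grid = np.linspace(0, 24, 49)
        widths = np.array(
            [predict_with_pi(fit, g).pi_high - predict_with_pi(fit, g).pi_low for g in grid]
        )
        argmin = grid[np.argmin(widths)]
        assert abs(argmin - fit.predictor_mean) <= np.diff(grid)[0]
        assert widths[0] > widths.min() and widths[-1] > widths.min()

    def test_logit_domain_enforced(self):
        fit = fit_logit(np.linspace(0.1, 0.9, 10), np.linspace(120, 150, 10))
        with pytest.raises(ValueError, match="inside"):
            predict_with_pi(fit, 1.0)

    def test_empirical_coverage(self, rng):
        """Fresh-draw coverage of the 95% PI across refitted models."""
        hits = 0
        trials = 2000
        for _ in range(trials):
            x = rng.uniform(0, 24, 25)
            y = 130 + 0.4 * x + rng.normal(0, 2, 25)
            fit = fit_linear(x, y)
            x_new = rng.uniform(0, 24)
            y_new = 130 + 0.4 * x_new + rng.normal(0, 2)
            band = predict_with_pi(fit, x_new)
            hits += band.pi_low <= y_new <= band.pi_high
        assert hits / trials == pytest.approx(0.95, abs=0.015)


class TestConfidenceThresholds:
    def test_integer_domain_rule_bounds(self, rng):
        x = np.repeat(np.arange(25.0), 4)
        y = 130 + 0.42 * x + rng.normal(0, 1.2, len(x))
        fit = fit_linear(x, y)
        thr = confidence_thresholds(fit, 135.0, domain=("counts", 24))
        assert thr.rule_out is not None and thr.rule_in is not None
        assert thr.rule_out < thr.rule_in
        assert float(thr.rule_in).is_integer()

    def test_indeterminate_zone_widens_with_noise(self, rng):
        x = np.repeat(np.arange(25.0), 8)
        zones = []
        for noise in (0.6, 1.8):
            y = 130 + 0.42 * x + rng.normal(0, noise, len(x))
            thr = confidence_thresholds(
                fit_linear(x, y), 135.0, domain=("counts", 24)
            )
            zones.append(thr.rule_in - thr.rule_out)
        assert zones[1] > zones[0]

    def test_band_above_target_degenerates(self):
        x = np.arange(10.0)
        fit = fit_linear(x, 200 + 0.5 * x)  # exact, PI tight, all above 135
        thr = confidence_thresholds(fit, 135.0, domain=("counts", 9))
        assert thr.rule_out is None
        assert thr.rule_in == 0.0

    def test_non_increasing_calibration_rejected(self):
        fit = fit_linear(np.arange(5.0), [140, 139, 138, 137, 136.0])
        with pytest.raises(ValueError, match="non-increasing"):
            confidence_thresholds(fit, 135.0, domain=("counts", 4))

    def test_continuous_ratio_domain(self, rng):
        x = rng.uniform(0.05, 0.95, 200)
        y = 135 + 7 * logit(x) + rng.normal(0, 2.5, 200)
        fit = fit_logit(x, y)
        thr = confidence_thresholds(fit, 135.0, domain=("ratio", (0.0, 1.0)))
        assert 0 < thr.rule_out < 0.5 < thr.rule_in < 1


class TestCalibrationTable:
    def test_monotone_rows_and_grid(self, rng):
        x = rng.uniform(0.05, 0.95, 150)
        y = 135 + 7 * logit(x) + rng.normal(0, 2, 150)
        lin = fit_linear(x, y, predictor="ct_ratio", channel="sbp")
        logit_fit = fit_logit(x, y, channel="sbp")
        table = calibration_table(lin, logit_fit)
        assert set(table.model) == {"linear", "logit"}
        assert ((table.ratio > 0) & (table.ratio < 1)).all()
        for _, grp in table.groupby("model"):
            assert grp.estimate.is_monotonic_increasing
            assert (grp.pi_low <= grp.estimate).all()
            assert (grp.estimate <= grp.pi_high).all()


class TestEstimatorProtocol:
    def test_clone_and_params(self):
        est = BPCalibrator(form="logit", channel="dbp")
        assert clone(est).get_params()["form"] == "logit"

    def test_predict_interval_vectorized(self, rng):
        x = rng.uniform(0, 24, 30)
        y = 130 + 0.4 * x + rng.normal(0, 2, 30)
        est = BPCalibrator().fit(x, y)
        e, lo, hi = est.predict_interval([0.0, 12.0, 24.0])
        assert e.shape == (3,)
        assert (lo <= e).all() and (e <= hi).all()
        band = predict_with_pi(est.to_fit(), 12.0)
        assert e[1] == pytest.approx(band.estimate)

    def test_agrees_near_half_on_cohort(self, cohort_summaries):
        """Linear (near-target window) and logit fits agree at C/T = 0.5."""
        ct = cohort_summaries.ct_sbp.to_numpy()
        y = cohort_summaries.mean_sbp.to_numpy()
        lin = fit_linear(ct, y, fit_range=(125, 145), predictor="ct_ratio")
        log = fit_logit(ct, y)
        assert abs(
            predict_with_pi(lin, 0.5).estimate - predict_with_pi(log, 0.5).estimate
        ) < 1.0
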