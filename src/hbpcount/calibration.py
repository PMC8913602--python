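"""Calibration of count statistics to mean BP with prediction intervals.

Two regression forms map a count statistic x (a high-BP count, or a C/T
ratio) to the series mean BP y:

* linear:  y = C + beta * x, optionally fitted only on cases whose mean BP
  lies in a stated response window (the near-target band where the
  relationship is locally linear);
* logit:   y = C + beta * log(x / (1 - x)) for 0 < x < 1, the natural shape
  over the full C/T range (boundary ratios 0 and 1 are excluded, not
  clamped, and their count is reported).

Both are ordinary least squares on the (possibly transformed) predictor.
Prediction intervals are the classical t-based intervals for a *new*
observation:

    y_hat +/- t_{1-alpha/2, n-2} * s * sqrt(1 + 1/n + (g - g_bar)^2 / S_gg)

where g is the transformed predictor, s the residual SD, and S_gg the
centred predictor sum of squares.  The >=95%-confidence rule-in (rule-out)
threshold is the smallest (largest) predictor value whose PI lies wholly
at/above (below) the BP target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CalibrationFit",
    "PredictionBand",
    "ConfidenceThresholds",
    "BPCalibrator",
    "fit_linear",
    "fit_logit",
    "predict_with_pi",
    "confidence_thresholds",
    "calibration_table",
]


def _logit(x):
    x = np.asarray(x, dtype=float)
    return np.log(x / (1.0 - x))


@dataclass
class CalibrationFit:
    """Fitted count-to-mean-BP map with sufficient statistics for PIs."""

    form: str  # "linear" | "logit"
    predictor: str  # "count" | "ct_ratio"
    channel: str | None
    slope: float
    intercept: float
    residual_sd: float
    n: int
    predictor_mean: float  # mean of the (transformed) predictor
    predictor_ssq: float  # centred sum of squares of the (transformed) predictor
    fit_range: tuple[float, float] | None = None
    excluded_boundary_points: int = 0

    def transform(self, at):
        return _logit(at) if self.form == "logit" else np.asarray(at, dtype=float)

    def estimate(self, at):
        return self.intercept + self.slope * self.transform(at)


@dataclass(frozen=True)
class PredictionBand:
    """Point estimate with its prediction interval at one predictor value."""

    at: float
    estimate: float
    pi_low: float
    pi_high: float
    level: float = 0.95


@dataclass(frozen=True)
class ConfidenceThresholds:
    """Rule-in / rule-out predictor thresholds at a confidence level.

    ``rule_out`` is the largest predictor value whose PI upper limit stays
    below the target (controlled with >= level confidence); ``rule_in`` the
    smallest whose PI lower limit reaches the target.  Either may be None
    when the band never clears the target on that side.
    """

    rule_out: float | None
    rule_in: float | None
    target: float
    level: float = 0.95


class BPCalibrator(RegressorMixin, BaseEstimator):
    """OLS calibration from a count statistic to mean BP, sklearn style.

    Parameters
    ----------
    form : {"linear", "logit"}
        Predictor transform; "logit" expects C/T ratios and drops boundary
        values 0 and 1 before fitting.
    fit_range : (float, float), optional
        Inclusive response (mean BP) window to subset on before fitting.
    predictor : {"count", "ct_ratio"}
        Bookkeeping label describing the predictor scale.
    channel : str, optional
        "sbp" or "dbp", carried through to reports.

    Attributes
    ----------
    slope_, intercept_ : float
        OLS coefficients on the (transformed) predictor scale.
    residual_sd_ : float
        sqrt(SSE / (n - 2)).
    n_ : int
        Points used after subsetting/exclusion.
    excluded_boundary_points_ : int
        Logit form only: ratios at 0 or 1 dropped before fitting.
    """

    def __init__(
        self,
        form: str = "linear",
        fit_range: tuple[float, float] | None = None,
        predictor: str = "count",
        channel: str | None = None,
    ):
        self.form = form
        self.fit_range = fit_range
        self.predictor = predictor
        self.channel = channel

    def fit(self, X, y):
        if self.form not in ("linear", "logit"):
            raise ValueError("form must be 'linear' or 'logit'")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("expected a single predictor column")
            x = x[:, 0]
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("predictor and response lengths differ")
        excluded = 0
        if self.fit_range is not None:
            lo, hi = self.fit_range
            keep = (y >= lo) & (y <= hi)
            x, y = x[keep], y[keep]
        if self.form == "logit":
            if np.any((x < 0) | (x > 1)):
                raise ValueError("logit form requires ratios in [0, 1]")
            interior = (x > 0) & (x < 1)
            excluded = int((~interior).sum())
            x, y = x[interior], y[interior]
        n = len(x)
        if n < 3:
            raise ValueError("need at least 3 points after subsetting")
        g = _logit(x) if self.form == "logit" else x
        gbar = g.mean()
        ssq = float(((g - gbar) ** 2).sum())
        if ssq == 0.0:
            raise ValueError("constant predictor")
        slope = float(((g - gbar) * (y - y.mean())).sum() / ssq)
        intercept = float(y.mean() - slope * gbar)
        resid = y - (intercept + slope * g)
        self.slope_ = slope
        self.intercept_ = intercept
        self.residual_sd_ = float(math.sqrt((resid**2).sum() / (n - 2)))
        self.n_ = n
        self.predictor_mean_ = float(gbar)
        self.predictor_ssq_ = ssq
        self.excluded_boundary_points_ = excluded
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self.to_fit().estimate(np.ravel(X))

    def predict_interval(self, X, level: float = 0.95):
        """Return (estimate, pi_low, pi_high) arrays at predictor values X."""
        check_is_fitted(self)
        fit = self.to_fit()
        at = np.ravel(np.asarray(X, dtype=float))
        est = fit.estimate(at)
        hw = _pi_halfwidth(fit, fit.transform(at), level)
        return est, est - hw, est + hw

    def to_fit(self) -> CalibrationFit:
        check_is_fitted(self)
        return CalibrationFit(
            form=self.form,
            predictor=self.predictor,
            channel=self.channel,
            slope=self.slope_,
            intercept=self.intercept_,
            residual_sd=self.residual_sd_,
            n=self.n_,
            predictor_mean=self.predictor_mean_,
            predictor_ssq=self.predictor_ssq_,
            fit_range=self.fit_range,
            excluded_boundary_points=self.excluded_boundary_points_,
        )


def _pi_halfwidth(fit: CalibrationFit, g, level: float):
    tcrit = stats.t.ppf(0.5 + level / 2, fit.n - 2)
    return (
        tcrit
        * fit.residual_sd
        * np.sqrt(1.0 + 1.0 / fit.n + (g - fit.predictor_mean) ** 2 / fit.predictor_ssq)
    )


def fit_linear(
    x,
    y,
    fit_range: tuple[float, float] | None = None,
    predictor: str = "count",
    channel: str | None = None,
) -> CalibrationFit:
    """OLS line from a count statistic to mean BP (thin estimator wrapper)."""
    return (
        BPCalibrator(form="linear", fit_range=fit_range, predictor=predictor, channel=channel)
        .fit(x, y)
        .to_fit()
    )


def fit_logit(
    ct, y, predictor: str = "ct_ratio", channel: str | None = None
) -> CalibrationFit:
    """OLS on the logit-transformed C/T ratio; boundary ratios excluded."""
    return (
        BPCalibrator(form="logit", predictor=predictor, channel=channel)
        .fit(ct, y)
        .to_fit()
    )


def predict_with_pi(
    fit: CalibrationFit, at: float, level: float = 0.95
) -> PredictionBand:
    """Point estimate and t-based prediction interval at one predictor value."""
    if fit.form == "logit" and not 0 < at < 1:
        raise ValueError("logit predictor must lie strictly inside (0, 1)")
    g = float(fit.transform(at))
    est = fit.intercept + fit.slope * g
    hw = float(_pi_halfwidth(fit, g, level))
    return PredictionBand(at=float(at), estimate=est, pi_low=est - hw, pi_high=est + hw, level=level)


def confidence_thresholds(
    fit: CalibrationFit,
    target: float,
    level: float = 0.95,
    domain: tuple[str, object] = ("counts", 24),
    grid_step: float = 1e-4,
) -> ConfidenceThresholds:
    """Scan the predictor domain for the >=level-confidence decision bounds.

    ``domain=("counts", k)`` scans the integer counts 0..k; ``domain=
    ("ratio", (lo, hi))`` scans a continuous ratio grid at ``grid_step``
    resolution (for the logit form the grid is kept strictly inside (0, 1)).
    Requires a positive slope: BP must increase with the count statistic.
    """
    if fit.slope <= 0:
        raise ValueError("non-increasing calibration")
    kind, spec_ = domain
    if kind == "counts":
        grid = np.arange(int(spec_) + 1, dtype=float)
    elif kind == "ratio":
        lo, hi = spec_
        if fit.form == "logit":
            lo, hi = max(lo, grid_step), min(hi, 1 - grid_step)
        grid = np.arange(lo, hi + grid_step / 2, grid_step)
    else:
        raise ValueError("domain kind must be 'counts' or 'ratio'")
    est = fit.estimate(grid)
    hw = _pi_halfwidth(fit, fit.transform(grid), level)
    below = est + hw < target  # controlled with >= level confidence
    above = est - hw >= target  # uncontrolled with >= level confidence
    rule_out = float(grid[below][-1]) if below.any() else None
    rule_in = float(grid[above][0]) if above.any() else None
    return ConfidenceThresholds(rule_out=rule_out, rule_in=rule_in, target=target, level=level)


def calibration_table(
    linear_fit: CalibrationFit | None,
    logit_fit: CalibrationFit | None,
    at=(0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    level: float = 0.95,
) -> pd.DataFrame:
    """Estimated mean BP with PIs on a C/T-ratio grid for each model form.

    Returns a long table with columns (channel, model, ratio, estimate,
    pi_low, pi_high); grid points outside a logit fit's open domain are
    skipped.
    """
    rows = []
    for name, fit in (("linear", linear_fit), ("logit", logit_fit)):
        if fit is None:
            continue
        for r in at:
            if fit.form == "logit" and not 0 < r < 1:
                continue
            band = predict_with_pi(fit, float(r), level)
            rows.append(
                {
                    "channel": fit.channel,
                    "model": name,
                    "ratio": float(r),
                    "estimate": band.estimate,
                    "pi_low": band.pi_low,
                    "pi_high": band.pi_high,
                }
            )
    return pd.DataFrame(rows)
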