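"""Data model and count statistics for home blood-pressure (HBP) series.

A home blood-pressure monitoring (HBPM) record is a sequence of paired
systolic/diastolic readings.  The decision statistic implemented here is the
*high-BP count*: the number of readings at or above the home target
(135 mmHg systolic, 85 mmHg diastolic), counted separately per channel.
Dividing by the number of readings T gives the C/T ratio, and the decision
rule flags a channel as uncontrolled when C/T >= 0.5 (equivalently, count
>= half of the readings).  The reference standard being predicted is the
*mean*-based definition: mean SBP >= 135 and/or mean DBP >= 85 mmHg.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "BPTarget",
    "HBPSeries",
    "SeriesSummary",
    "CountDecision",
    "CountRuleClassifier",
    "summarize_series",
    "count_rule_decision",
]

#: Plausibility window for a single BP reading, mmHg.
DEFAULT_PLAUSIBLE_RANGE = (30.0, 300.0)


@dataclass(frozen=True)
class BPTarget:
    """Home BP target defining a *high* reading and an *uncontrolled* mean.

    Comparisons against the cuts are inclusive (``>=``) in both the
    per-reading high definition and the mean-based uncontrolled definition.
    """

    sbp_cut: float = 135.0
    dbp_cut: float = 85.0

    def __post_init__(self) -> None:
        if not (self.sbp_cut > 0 and self.dbp_cut > 0):
            raise ValueError("BP cuts must be positive")
        if not self.sbp_cut > self.dbp_cut:
            raise ValueError("sbp_cut must exceed dbp_cut")


@dataclass
class HBPSeries:
    """One patient's (or simulated case's) sequence of paired SBP/DBP readings.

    Parameters
    ----------
    series_id : str
        Identifier of the patient or simulated case.
    sbp, dbp : array-like of float
        Paired readings in mmHg; equal length >= 1, all finite.
    day : array-like of int, optional
        Day label per reading (calendar ordinal or day index), aligned with
        the readings and non-decreasing.  Required for first-day exclusion.
    plausible_range : (float, float)
        Window outside which a reading is rejected as implausible.
    """

    series_id: str
    sbp: np.ndarray
    dbp: np.ndarray
    day: np.ndarray | None = None
    plausible_range: tuple[float, float] = field(
        default=DEFAULT_PLAUSIBLE_RANGE, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        if self.sbp.ndim != 1 or self.dbp.ndim != 1:
            raise ValueError("sbp and dbp must be one-dimensional")
        if len(self.sbp) != len(self.dbp):
            raise ValueError("sbp and dbp must have equal length")
        if len(self.sbp) == 0:
            raise ValueError("empty series")
        for name, arr in (("sbp", self.sbp), ("dbp", self.dbp)):
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise ValueError(
                    f"non-finite {name} reading at index {int(bad[0])}"
                )
        lo, hi = self.plausible_range
        for name, arr in (("sbp", self.sbp), ("dbp", self.dbp)):
            bad = np.flatnonzero((arr < lo) | (arr > hi))
            if bad.size:
                raise ValueError(
                    f"{name} reading {arr[bad[0]]:g} at index {int(bad[0])} "
                    f"outside plausible range [{lo:g}, {hi:g}]"
                )
        if self.day is not None:
            self.day = np.asarray(self.day, dtype=int)
            if len(self.day) != len(self.sbp):
                raise ValueError("day labels must align with readings")
            if np.any(np.diff(self.day) < 0):
                raise ValueError("day labels must be non-decreasing")

    def __len__(self) -> int:
        return len(self.sbp)

    def to_dict(self) -> dict:
        d = {
            "series_id": self.series_id,
            "sbp": self.sbp.tolist(),
            "dbp": self.dbp.tolist(),
        }
        if self.day is not None:
            d["day"] = self.day.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HBPSeries":
        return cls(
            series_id=d["series_id"],
            sbp=d["sbp"],
            dbp=d["dbp"],
            day=d.get("day"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "HBPSeries":
        return cls.from_dict(json.loads(s))


@dataclass
class SeriesSummary:
    """Per-series derived statistics.

    ``high_*_count`` is the count C of readings at/above the channel cut,
    ``ct_*`` the C/T ratio, and ``uncontrolled_*`` the mean-based reference
    standard.  ``high_any_count`` counts readings high in *either* channel;
    it is a non-canonical convenience and enters no decision rule here.
    SDs use the n-1 (sample) denominator and are NaN for single-reading
    series.
    """

    series_id: str
    k: int
    mean_sbp: float
    mean_dbp: float
    sd_sbp: float
    sd_dbp: float
    range_sbp: float
    range_dbp: float
    high_sbp_count: int
    high_dbp_count: int
    ct_sbp: float
    ct_dbp: float
    uncontrolled_sbp: bool
    uncontrolled_dbp: bool
    uncontrolled_any: bool
    high_any_count: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SeriesSummary":
        return cls(**d)


class CountDecision(NamedTuple):
    """Outcome of the count rule: per-channel flags and their disjunction."""

    sbp_flag: bool
    dbp_flag: bool
    any_flag: bool


def summarize_series(series: HBPSeries, target: BPTarget = BPTarget()) -> SeriesSummary:
    """Compute counts, means, SDs, ranges, C/T ratios and controlledness.

    High counts use inclusive comparisons (reading >= cut); uncontrolledness
    compares the arithmetic mean against the same cut, also inclusively.
    """
    sbp, dbp = series.sbp, series.dbp
    k = len(series)
    high_sbp = sbp >= target.sbp_cut
    high_dbp = dbp >= target.dbp_cut
    mean_sbp = float(sbp.mean())
    mean_dbp = float(dbp.mean())
    sd_sbp = float(sbp.std(ddof=1)) if k > 1 else math.nan
    sd_dbp = float(dbp.std(ddof=1)) if k > 1 else math.nan
    n_high_sbp = int(high_sbp.sum())
    n_high_dbp = int(high_dbp.sum())
    unc_sbp = mean_sbp >= target.sbp_cut
    unc_dbp = mean_dbp >= target.dbp_cut
    return SeriesSummary(
        series_id=series.series_id,
        k=k,
        mean_sbp=mean_sbp,
        mean_dbp=mean_dbp,
        sd_sbp=sd_sbp,
        sd_dbp=sd_dbp,
        range_sbp=float(sbp.max() - sbp.min()),
        range_dbp=float(dbp.max() - dbp.min()),
        high_sbp_count=n_high_sbp,
        high_dbp_count=n_high_dbp,
        ct_sbp=n_high_sbp / k,
        ct_dbp=n_high_dbp / k,
        uncontrolled_sbp=bool(unc_sbp),
        uncontrolled_dbp=bool(unc_dbp),
        uncontrolled_any=bool(unc_sbp or unc_dbp),
        high_any_count=int((high_sbp | high_dbp).sum()),
    )


def count_rule_decision(
    summary: SeriesSummary, threshold: float = 0.5
) -> CountDecision:
    """Apply the C/T >= threshold decision rule per channel.

    At the default threshold 0.5 this is the half-of-K rule: a channel is
    flagged when the high count reaches ceil(k/2) (for even k, exactly
    half, e.g. >= 12 of 24 readings).
    """
    sbp_flag = summary.ct_sbp >= threshold
    dbp_flag = summary.ct_dbp >= threshold
    return CountDecision(bool(sbp_flag), bool(dbp_flag), bool(sbp_flag or dbp_flag))


class CountRuleClassifier(ClassifierMixin, BaseEstimator):
    """Threshold classifier on the C/T ratio, scikit-learn style.

    Predicts uncontrolled (1) when the C/T ratio meets the threshold.  The
    rule has no free parameters to estimate; :meth:`fit` validates the input
    and records metadata so the estimator composes with pipelines and
    model-selection utilities.

    Parameters
    ----------
    threshold : float, default 0.5
        Decision cut on the C/T ratio (inclusive).
    """

    def __init__(self, threshold: float = 0.5):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=True)
        if X.shape[1] != 1:
            raise ValueError("expected a single C/T-ratio feature column")
        if np.any((X < 0) | (X > 1)):
            raise ValueError("C/T ratios must lie in [0, 1]")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
        self.n_features_in_ = 1
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_2d=True)
        return (X[:, 0] >= self.threshold).astype(int)

    def decision_function(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_2d=True)
        return X[:, 0] - self.threshold


def summaries_to_frame(
    series_list: Sequence[HBPSeries], target: BPTarget = BPTarget()
):
    """Summarize a collection of series into a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [summarize_series(s, target).to_dict() for s in series_list]
    )
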