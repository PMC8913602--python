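"""ROC analysis for count statistics: AUC, DeLong CIs, Youden thresholds.

The C-statistic (AUC) is computed in its Mann-Whitney form — the
probability that a random uncontrolled case scores above a random
controlled one, ties counted one half — which is exact for the heavily
tied integer count scores used here.  Confidence intervals use DeLong's
structural-component variance estimator.  The predicted-positive
convention throughout is ``score >= threshold``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ROCCurve",
    "DiagnosticIndices",
    "auc",
    "roc_curve",
    "delong_se",
    "delong_ci",
    "indices_at_threshold",
    "best_threshold_youden",
]


@dataclass
class ROCCurve:
    """Threshold sweep of sensitivity/specificity with the AUC.

    Thresholds are midpoints between consecutive distinct scores plus
    -inf/+inf sentinels; a case is predicted positive when its score is at
    or above the threshold, so sensitivity is non-increasing and
    specificity non-decreasing along increasing thresholds.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    auc_ci: tuple[float, float, str] | None = None


@dataclass
class DiagnosticIndices:
    """Confusion-matrix indices at a single score threshold.

    ``ppv``/``npv`` are NaN with the matching ``*_defined`` flag cleared
    when the corresponding margin is empty (no predicted positives or
    negatives); they are never silently reported as 0.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    ccr: float
    youden_j: float
    n: int
    n_positive: int
    ppv_defined: bool = True
    npv_defined: bool = True
    sensitivity_defined: bool = True
    specificity_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sens": self.sensitivity,
            "spec": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "ccr": self.ccr,
            "youden_j": self.youden_j,
            "n": self.n,
            "n_positive": self.n_positive,
        }


def _validate(scores, labels, require_both_classes=True):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype == bool:
        labels = labels.astype(int)
    labels = labels.astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    if require_both_classes and (labels.min() == labels.max()):
        raise ValueError("degenerate labels: both classes must be present")
    return scores, labels


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie).

    Identical to the trapezoidal area under :func:`roc_curve` on the same
    data.
    """
    scores, labels = _validate(scores, labels)
    r = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve(scores, labels) -> ROCCurve:
    """Full sensitivity/specificity sweep with sentinel thresholds."""
    scores, labels = _validate(scores, labels)
    uniq = np.unique(scores)
    mid = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mid, [np.inf]])
    n1 = labels.sum()
    n0 = len(labels) - n1
    pred = scores[None, :] >= thresholds[:, None]
    tp = (pred & (labels == 1)).sum(axis=1)
    fp = (pred & (labels == 0)).sum(axis=1)
    return ROCCurve(
        thresholds=thresholds,
        sens=tp / n1,
        spec=(n0 - fp) / n0,
        auc=auc(scores, labels),
    )


def delong_se(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong standard error from structural components."""
    scores, labels = _validate(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs at least 2 cases per class")
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    a = float((r_all[:m].sum() - m * (m + 1) / 2) / (m * n))
    v10 = (r_all[:m] - r_pos) / n  # per-positive placement values
    v01 = 1.0 - (r_all[m:] - r_neg) / m  # per-negative placement values
    s10 = v10.var(ddof=1)
    s01 = v01.var(ddof=1)
    return a, float(math.sqrt(s10 / m + s01 / n))


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Wald interval auc +/- z*SE on the DeLong variance, clipped to [0,1].

    With zero estimated variance (e.g. perfect separation) the interval
    collapses to the point AUC and a warning is emitted.
    """
    a, se = delong_se(scores, labels)
    if se == 0.0:
        warnings.warn(
            "zero DeLong variance; interval collapsed to the point AUC",
            stacklevel=2,
        )
        return a, a
    z = stats.norm.ppf(0.5 + level / 2)
    return float(np.clip(a - z * se, 0, 1)), float(np.clip(a + z * se, 0, 1))


def indices_at_threshold(
    scores, labels, cut: float, allow_degenerate: bool = False
) -> DiagnosticIndices:
    """Confusion-matrix indices with predicted-positive = score >= cut."""
    scores, labels = _validate(
        scores, labels, require_both_classes=not allow_degenerate
    )
    pred = scores >= cut
    truth = labels == 1
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    n = len(labels)

    def _ratio(num, den):
        return (num / den, True) if den else (math.nan, False)

    sens, sens_ok = _ratio(tp, tp + fn)
    spec, spec_ok = _ratio(tn, tn + fp)
    ppv, ppv_ok = _ratio(tp, tp + fp)
    npv, npv_ok = _ratio(tn, tn + fn)
    return DiagnosticIndices(
        threshold=float(cut),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        ccr=(tp + tn) / n,
        youden_j=sens + spec - 1,
        n=n,
        n_positive=tp + fn,
        ppv_defined=ppv_ok,
        npv_defined=npv_ok,
        sensitivity_defined=sens_ok,
        specificity_defined=spec_ok,
    )


def best_threshold_youden(scores, labels) -> DiagnosticIndices:
    """Indices at the threshold maximizing Youden's J = sens + spec - 1.

    Ties in J are broken toward higher specificity, then toward the higher
    threshold, so the rule errs on the conservative (fewer positives) side.
    """
    curve = roc_curve(scores, labels)
    j = curve.sens + curve.spec - 1
    # lexicographic argmax over (J, spec, threshold); thresholds ascend
    order = np.lexsort((curve.thresholds, curve.spec, j))
    best = order[-1]
    cut = curve.thresholds[best]
    if not np.isfinite(cut):
        # sentinel won (degenerate sweep): replace with an equivalent finite
        # cut under the score >= cut convention
        cut = scores.min() if cut == -np.inf else scores.max() + 1.0
    return indices_at_threshold(scores, labels, float(cut))
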