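"""Reading HBPM cohort files, exclusions, stratification and validation.

The validation pipeline mirrors how an observational HBPM cohort is
analysed: read long-format records (patient, date, SBP, DBP), drop each
patient's first calendar day of readings (a common reproducibility
measure), exclude patients left with fewer than 8 readings, then evaluate
the C/T >= 0.5 decision rule against mean-based uncontrolledness overall
and within strata of series length, within-patient SD, BP range and
near-target mean-BP bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_counts import BPTarget, HBPSeries, SeriesSummary, summarize_series
from .diagnostics import DiagnosticIndices, auc, delong_ci, indices_at_threshold

__all__ = [
    "StratumDefinition",
    "DEFAULT_STRATA",
    "CohortReadResult",
    "ExclusionLog",
    "ValidationRow",
    "ValidationReport",
    "read_hbpm_csv",
    "apply_exclusions",
    "stratify",
    "evaluate_validation",
]

REQUIRED_COLUMNS = ("patient_id", "date", "sbp", "dbp")


@dataclass(frozen=True)
class StratumDefinition:
    """Binning rule for one summary variable.

    With ``band=False``, ``bounds`` are inner cutpoints producing the bins
    (-inf, b0), [b0, b1), ..., [b_last, inf) — half-open on the left, so a
    printed bound like "10-14.9" is the bin [10, 15).  With ``band=True``,
    ``bounds=(lo, hi)`` defines the single bin [lo, hi) and values outside
    are excluded from the stratification (label None).
    """

    variable: str
    bounds: tuple[float, ...]
    labels: tuple[str, ...]
    band: bool = False

    def __post_init__(self) -> None:
        if list(self.bounds) != sorted(set(self.bounds)):
            raise ValueError("bounds must be strictly increasing")
        expected = 1 if self.band else len(self.bounds) + 1
        if self.band and len(self.bounds) != 2:
            raise ValueError("a band needs exactly (low, high) bounds")
        if len(self.labels) != expected:
            raise ValueError("label count does not match bin count")

    def assign(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        out = np.empty(len(values), dtype=object)
        if self.band:
            lo, hi = self.bounds
            inside = (values >= lo) & (values < hi)
            out[:] = None
            out[inside] = self.labels[0]
            return out
        idx = np.searchsorted(self.bounds, values, side="right")
        for i, lab in enumerate(self.labels):
            out[idx == i] = lab
        return out


DEFAULT_STRATA = (
    StratumDefinition("k", (16, 24), ("8-15", "16-23", ">=24")),
    StratumDefinition("sd_sbp", (10, 15), ("<10", "10-14.9", ">=15")),
    StratumDefinition("sd_dbp", (7, 10), ("<7", "7-9.9", ">=10")),
    StratumDefinition("range_sbp", (40, 60), ("<40", "40-59", ">=60")),
    StratumDefinition("range_dbp", (30, 45), ("<30", "30-44", ">=45")),
    StratumDefinition("mean_sbp", (130, 140), ("130-139",), band=True),
    StratumDefinition("mean_dbp", (80, 90), ("80-89",), band=True),
)


@dataclass
class CohortReadResult:
    cohort: list[HBPSeries]
    rejects: pd.DataFrame
    n_rows: int


@dataclass
class ExclusionLog:
    n_input: int
    n_retained: int
    n_excluded_few_readings: int
    n_first_day_readings_removed: int
    excluded_ids: list[str] = field(default_factory=list)


def read_hbpm_csv(path, dialect: dict | None = None) -> CohortReadResult:
    """Read long-format HBPM records into per-patient series.

    ``dialect`` maps the canonical column names (patient_id, date, sbp,
    dbp) to the file's actual headers.  Rows with unparseable dates or
    non-numeric/implausible BP values are collected into the ``rejects``
    frame with a reason column — never silently dropped.  Readings are
    grouped by patient and ordered by date; day labels are calendar
    ordinals.
    """
    colmap = {c: c for c in REQUIRED_COLUMNS}
    if dialect:
        colmap.update(dialect)
    raw = pd.read_csv(path, comment="#")
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    df = pd.DataFrame(
        {canon: raw[actual] for canon, actual in colmap.items()}
    )
    date = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    sbp = pd.to_numeric(df["sbp"], errors="coerce")
    dbp = pd.to_numeric(df["dbp"], errors="coerce")
    reason = np.select(
        [
            date.isna(),
            sbp.isna() | dbp.isna(),
            (sbp < 30) | (sbp > 300) | (dbp < 30) | (dbp > 300),
        ],
        ["unparseable date", "non-numeric BP", "implausible BP"],
        default="",
    )
    bad = reason != ""
    rejects = raw.loc[bad].copy()
    rejects["reject_reason"] = reason[bad]
    ok = df.loc[~bad].copy()
    ok["date"] = date[~bad]
    ok["sbp"] = sbp[~bad]
    ok["dbp"] = dbp[~bad]
    cohort = []
    for pid, grp in ok.groupby("patient_id", sort=True):
        grp = grp.sort_values("date", kind="stable")
        day = grp["date"].map(pd.Timestamp.toordinal).to_numpy()
        cohort.append(
            HBPSeries(
                series_id=str(pid),
                sbp=grp["sbp"].to_numpy(),
                dbp=grp["dbp"].to_numpy(),
                day=day,
            )
        )
    return CohortReadResult(cohort=cohort, rejects=rejects, n_rows=len(raw))


def apply_exclusions(
    cohort: list[HBPSeries],
    min_readings: int = 8,
    drop_first_day: bool = True,
) -> tuple[list[HBPSeries], ExclusionLog]:
    """First-day exclusion, then the minimum-readings filter.

    Each patient's *first day* is their earliest day label present; those
    readings are removed before counting.  Patients left with fewer than
    ``min_readings`` readings are dropped and logged.  Requesting first-day
    exclusion on a series without day labels is an error, not a silent
    skip.
    """
    if not cohort:
        raise ValueError("empty cohort")
    retained = []
    excluded_ids = []
    n_first_day = 0
    for ser in cohort:
        sbp, dbp, day = ser.sbp, ser.dbp, ser.day
        if drop_first_day:
            if day is None:
                raise ValueError(
                    f"series {ser.series_id} has no day labels; "
                    "cannot apply first-day exclusion"
                )
            keep = day > day.min()
            n_first_day += int((~keep).sum())
            sbp, dbp = sbp[keep], dbp[keep]
            day = day[keep]
        if len(sbp) < min_readings:
            excluded_ids.append(ser.series_id)
            continue
        retained.append(
            HBPSeries(series_id=ser.series_id, sbp=sbp, dbp=dbp, day=day)
        )
    log = ExclusionLog(
        n_input=len(cohort),
        n_retained=len(retained),
        n_excluded_few_readings=len(excluded_ids),
        n_first_day_readings_removed=n_first_day,
        excluded_ids=excluded_ids,
    )
    return retained, log


def stratify(
    summaries: pd.DataFrame,
    definitions: tuple[StratumDefinition, ...] = DEFAULT_STRATA,
) -> pd.DataFrame:
    """Add one ``stratum_<variable>`` column per definition."""
    seen = set()
    for d in definitions:
        if d.variable in seen:
            raise ValueError(f"duplicate stratum definition for {d.variable}")
        seen.add(d.variable)
    out = summaries.copy()
    for d in definitions:
        if d.variable not in out.columns:
            raise ValueError(f"summaries lack column {d.variable!r}")
        out[f"stratum_{d.variable}"] = d.assign(out[d.variable].to_numpy())
    return out


@dataclass
class ValidationRow:
    """One evaluation cell: a channel within a stratum (or overall)."""

    channel: str
    variable: str
    stratum: str
    n: int
    n_uncontrolled: int
    indices: DiagnosticIndices
    auc: float
    auc_ci: tuple[float, float] | None
    ci_method: str = "delong"
    auc_available: bool = True


@dataclass
class ValidationReport:
    rows: list[ValidationRow]
    exclusion_log: ExclusionLog | None = None

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "channel": r.channel,
                    "variable": r.variable,
                    "stratum": r.stratum,
                    "n": r.n,
                    "n_uncontrolled": r.n_uncontrolled,
                    "sens": r.indices.sensitivity,
                    "spec": r.indices.specificity,
                    "ppv": r.indices.ppv,
                    "npv": r.indices.npv,
                    "ccr": r.indices.ccr,
                    "auc": r.auc if r.auc_available else np.nan,
                    "auc_lo": r.auc_ci[0] if r.auc_ci else np.nan,
                    "auc_hi": r.auc_ci[1] if r.auc_ci else np.nan,
                    "ci_method": r.ci_method,
                }
            )
        return pd.DataFrame(recs)


def _channel_row(
    sub: pd.DataFrame, channel: str, variable: str, stratum: str, ct_cut: float
) -> ValidationRow:
    scores = sub[f"ct_{channel}"].to_numpy()
    labels = sub[f"uncontrolled_{channel}"].to_numpy().astype(int)
    indices = indices_at_threshold(scores, labels, ct_cut, allow_degenerate=True)
    degenerate = labels.min() == labels.max() if len(labels) else True
    if degenerate or len(labels) < 4:
        return ValidationRow(
            channel=channel,
            variable=variable,
            stratum=stratum,
            n=len(sub),
            n_uncontrolled=int(labels.sum()),
            indices=indices,
            auc=np.nan,
            auc_ci=None,
            auc_available=False,
        )
    a = auc(scores, labels)
    try:
        ci = delong_ci(scores, labels)
    except ValueError:
        ci = None
    return ValidationRow(
        channel=channel,
        variable=variable,
        stratum=stratum,
        n=len(sub),
        n_uncontrolled=int(labels.sum()),
        indices=indices,
        auc=a,
        auc_ci=ci,
    )


def evaluate_validation(
    cohort: list[HBPSeries],
    target: BPTarget = BPTarget(),
    strata: tuple[StratumDefinition, ...] = DEFAULT_STRATA,
    ct_cut: float = 0.5,
    exclusion_log: ExclusionLog | None = None,
) -> ValidationReport:
    """Evaluate the C/T decision rule on a post-exclusion cohort.

    Per channel: the C-statistic of the C/T ratio for mean-based
    uncontrolledness (with DeLong CI) plus confusion-matrix indices at
    C/T >= ``ct_cut``, overall and within each stratum.  Strata containing
    a single outcome class get their C-statistic marked unavailable while
    the indices are still reported.
    """
    summaries = pd.DataFrame(
        [summarize_series(s, target).to_dict() for s in cohort]
    )
    summaries = stratify(summaries, strata)
    rows = []
    for channel in ("sbp", "dbp"):
        rows.append(_channel_row(summaries, channel, "overall", "all", ct_cut))
        for d in strata:
            col = f"stratum_{d.variable}"
            for lab in d.labels:
                sub = summaries[summaries[col] == lab]
                if len(sub) == 0:
                    continue
                rows.append(_channel_row(sub, channel, d.variable, lab, ct_cut))
    return ValidationReport(rows=rows, exclusion_log=exclusion_log)
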