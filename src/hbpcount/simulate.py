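"""Synthetic HBP data: the factorial simulation design and a cohort emulator.

Two generators live here.

``run_simulation`` produces the factorial study: ``n_cases`` true mean BP
pairs drawn uniformly near the 135/85 mmHg target (where the decision is
hardest), each expanded into a normal reading series for every combination
of series length K and reading-level SD.  The *same* mean pairs are reused
in every (K, SD) cell, so cells differ only in series length and noise.

``generate_synthetic_cohort`` emulates a real HBPM validation cohort:
patient-level mean BPs from a correlated bivariate normal, within-patient
reading SDs from a log-normal, per-patient reading counts from a clipped
log-normal on [8, 70], plus a configurable number of short-record patients
and first-day readings so the exclusion pipeline is exercisable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_counts import BPTarget, HBPSeries, summarize_series

__all__ = [
    "SimulationDesign",
    "CohortDesign",
    "sample_mean_bps",
    "generate_series",
    "run_simulation",
    "generate_synthetic_cohort",
    "cohort_to_frame",
    "write_cohort_csv",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Factorial design of the simulated HBP study.

    Defaults give 100 cases per cell, K in {16, 20, 24}, systolic reading
    SDs in {5, 10, 15, 20} mmHg with diastolic SDs at 70% of the systolic
    ones, and true means uniform on [130, 140) / [80, 90) mmHg.
    """

    n_cases: int = 100
    k_values: tuple[int, ...] = (16, 20, 24)
    sd_levels_sbp: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    dbp_sd_ratio: float = 0.7
    mean_sbp_range: tuple[float, float] = (130.0, 140.0)
    mean_dbp_range: tuple[float, float] = (80.0, 90.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        if any(k < 1 for k in self.k_values):
            raise ValueError("k_values must be positive")
        if any(sd <= 0 for sd in self.sd_levels_sbp):
            raise ValueError("SD levels must be positive")
        if not 0 < self.dbp_sd_ratio <= 1:
            raise ValueError("dbp_sd_ratio must lie in (0, 1]")
        for lo, hi in (self.mean_sbp_range, self.mean_dbp_range):
            if hi < lo:
                raise ValueError("mean ranges must be ordered")

    @property
    def sd_levels_dbp(self) -> tuple[float, ...]:
        return tuple(sd * self.dbp_sd_ratio for sd in self.sd_levels_sbp)

    @property
    def n_cells(self) -> int:
        return len(self.k_values) * len(self.sd_levels_sbp)


def sample_mean_bps(
    design: SimulationDesign, rng: np.random.Generator
) -> np.ndarray:
    """Draw the ``(n_cases, 2)`` array of true (mean SBP, mean DBP) pairs.

    Means are uniform on the design ranges.  Callers must draw this exactly
    once per study and reuse the pairs across all (K, SD) cells.
    """
    sbp = rng.uniform(*design.mean_sbp_range, design.n_cases)
    dbp = rng.uniform(*design.mean_dbp_range, design.n_cases)
    return np.column_stack([sbp, dbp])


def generate_series(
    mean_sbp: float,
    mean_dbp: float,
    k: int,
    sd_sbp: float,
    dbp_sd_ratio: float,
    rng: np.random.Generator,
    series_id: str = "sim",
) -> HBPSeries:
    """Generate one series of K normal readings around the given true means.

    SBP readings are Normal(mean_sbp, sd_sbp); DBP readings are
    Normal(mean_dbp, sd_sbp * dbp_sd_ratio), independent across readings
    and channels.  Readings are left unrounded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if sd_sbp <= 0:
        raise ValueError("sd_sbp must be positive")
    sbp = rng.normal(mean_sbp, sd_sbp, k)
    dbp = rng.normal(mean_dbp, sd_sbp * dbp_sd_ratio, k)
    # raw normal draws, deliberately neither rounded nor truncated; the
    # real-data plausibility window does not apply to simulated series
    return HBPSeries(
        series_id=series_id, sbp=sbp, dbp=dbp,
        plausible_range=(-np.inf, np.inf),
    )


def _study_rngs(design: SimulationDesign):
    """Seed-sequence tree: one child stream for the means, one per cell."""
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(1 + design.n_cells)
    means_rng = np.random.default_rng(children[0])
    cell_rngs = {}
    i = 1
    for k in design.k_values:
        for sd in design.sd_levels_sbp:
            cell_rngs[(k, sd)] = np.random.default_rng(children[i])
            i += 1
    return means_rng, cell_rngs


def run_simulation(
    design: SimulationDesign = SimulationDesign(),
    target: BPTarget = BPTarget(),
    return_series: bool = False,
):
    """Run the full factorial simulation.

    Returns a DataFrame with one row per case x K x SD cell (``n_cases *
    len(k_values) * len(sd_levels_sbp)`` rows) carrying the true means, the
    cell tags and every ``SeriesSummary`` field.  With ``return_series``
    also returns the long-format readings table.
    """
    means_rng, cell_rngs = _study_rngs(design)
    means = sample_mean_bps(design, means_rng)
    rows = []
    series_rows: list[dict] = []
    for k in design.k_values:
        for sd in design.sd_levels_sbp:
            rng = cell_rngs[(k, sd)]
            for case in range(design.n_cases):
                sid = f"case{case:03d}_k{k}_sd{sd:g}"
                ser = generate_series(
                    means[case, 0],
                    means[case, 1],
                    k,
                    sd,
                    design.dbp_sd_ratio,
                    rng,
                    series_id=sid,
                )
                summ = summarize_series(ser, target).to_dict()
                summ.update(
                    case_id=case,
                    k=k,
                    sd_level=sd,
                    sd_level_dbp=sd * design.dbp_sd_ratio,
                    true_mean_sbp=means[case, 0],
                    true_mean_dbp=means[case, 1],
                )
                rows.append(summ)
                if return_series:
                    for j in range(k):
                        series_rows.append(
                            {
                                "series_id": sid,
                                "case_id": case,
                                "k": k,
                                "sd_level": sd,
                                "reading_index": j,
                                "sbp": ser.sbp[j],
                                "dbp": ser.dbp[j],
                            }
                        )
    summaries = pd.DataFrame(rows)
    if return_series:
        return summaries, pd.DataFrame(series_rows)
    return summaries


@dataclass(frozen=True)
class CohortDesign:
    """Generator settings for a synthetic HBPM validation cohort.

    Defaults emulate an outpatient cohort of treated hypertensives:
    ``n_patients`` retainable records plus ``n_short_patients`` records that
    fall below the minimum-readings filter once first-day readings are
    dropped, patient-mean SBP/DBP ~ Normal(128.2, 14.8)/(79.9, 9.7) mmHg
    with correlation 0.6 between channels, within-patient reading SDs
    log-normal with means 11.8/8.0 mmHg, and per-patient reading counts on
    [8, 70] concentrated around 16-24.  Readings are grouped two per day;
    every patient additionally gets ``first_day_readings`` readings on
    their first day so that first-day exclusion is exercisable.
    """

    n_patients: int = 412
    n_short_patients: int = 12
    mean_sbp: float = 128.2
    sd_mean_sbp: float = 14.8
    mean_dbp: float = 79.9
    sd_mean_dbp: float = 9.7
    mean_correlation: float = 0.6
    within_sd_sbp_mean: float = 11.8
    within_sd_dbp_mean: float = 8.0
    within_sd_log_sigma: float = 0.35
    k_min: int = 8
    k_max: int = 70
    k_log_mean: float = math.log(20.0)
    k_log_sigma: float = 0.45
    readings_per_day: int = 2
    first_day_readings: int = 2
    round_readings: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_short_patients < 0:
            raise ValueError("n_short_patients must be >= 0")
        for v in (
            self.sd_mean_sbp,
            self.sd_mean_dbp,
            self.within_sd_sbp_mean,
            self.within_sd_dbp_mean,
        ):
            if v <= 0:
                raise ValueError("scale parameters must be positive")
        if not -1 < self.mean_correlation < 1:
            raise ValueError("mean_correlation must lie in (-1, 1)")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("reading-count bounds must satisfy 1 <= k_min <= k_max")
        if self.readings_per_day < 1 or self.first_day_readings < 0:
            raise ValueError("day-structure settings must be non-negative")


def _lognormal_with_mean(mean: float, sigma: float, rng, size: int) -> np.ndarray:
    # mu chosen so E[exp(N(mu, sigma^2))] equals the requested mean
    mu = math.log(mean) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, size)


def generate_synthetic_cohort(
    design: CohortDesign = CohortDesign(),
    rng: np.random.Generator | None = None,
) -> list[HBPSeries]:
    """Generate the synthetic HBPM cohort as a list of day-labelled series.

    The first ``n_patients`` records keep at least ``k_min`` readings after
    first-day exclusion; the trailing ``n_short_patients`` records are
    generated with 2..k_min-1 post-exclusion readings so the minimum-reading
    filter removes exactly that many patients.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    n_total = design.n_patients + design.n_short_patients
    cov = design.mean_correlation * design.sd_mean_sbp * design.sd_mean_dbp
    means = rng.multivariate_normal(
        [design.mean_sbp, design.mean_dbp],
        [[design.sd_mean_sbp**2, cov], [cov, design.sd_mean_dbp**2]],
        size=n_total,
    )
    sd_s = _lognormal_with_mean(
        design.within_sd_sbp_mean, design.within_sd_log_sigma, rng, n_total
    )
    sd_d = _lognormal_with_mean(
        design.within_sd_dbp_mean, design.within_sd_log_sigma, rng, n_total
    )
    k_post = np.clip(
        np.round(rng.lognormal(design.k_log_mean, design.k_log_sigma, n_total)),
        design.k_min,
        design.k_max,
    ).astype(int)
    if design.n_short_patients:
        lo = min(2, design.k_min - 1) if design.k_min > 1 else 1
        k_post[design.n_patients :] = rng.integers(
            lo, design.k_min, design.n_short_patients
        )
    cohort = []
    for i in range(n_total):
        k_total = int(k_post[i]) + design.first_day_readings
        sbp = rng.normal(means[i, 0], sd_s[i], k_total)
        dbp = rng.normal(means[i, 1], sd_d[i], k_total)
        if design.round_readings:
            sbp = np.round(sbp)
            dbp = np.round(dbp)
        day = np.zeros(k_total, dtype=int)
        extra = k_total - design.first_day_readings
        day[design.first_day_readings :] = 1 + np.arange(extra) // design.readings_per_day
        sbp = np.clip(sbp, 30.0, 300.0)  # guard pathological tails
        dbp = np.clip(dbp, 30.0, 300.0)
        cohort.append(
            HBPSeries(series_id=f"pt{i + 1:04d}", sbp=sbp, dbp=dbp, day=day)
        )
    return cohort


def cohort_to_frame(
    cohort: Iterable[HBPSeries], start_date: str = "2018-01-01"
) -> pd.DataFrame:
    """Long-format cohort table (patient_id, date, sbp, dbp)."""
    base = pd.Timestamp(start_date)
    rows = []
    for ser in cohort:
        day = ser.day if ser.day is not None else np.zeros(len(ser), dtype=int)
        for d, s, di in zip(day, ser.sbp, ser.dbp):
            rows.append(
                {
                    "patient_id": ser.series_id,
                    "date": (base + pd.Timedelta(days=int(d))).date().isoformat(),
                    "sbp": s,
                    "dbp": di,
                }
            )
    return pd.DataFrame(rows)


def write_cohort_csv(
    cohort: Sequence[HBPSeries], path, start_date: str = "2018-01-01"
) -> None:
    cohort_to_frame(cohort, start_date).to_csv(path, index=False)
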