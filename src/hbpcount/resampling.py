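"""Bootstrap distributions of performance statistics and design comparison.

Each (K, SD) design cell yields R case-level bootstrap replicates of a
performance statistic (AUC, or CCR at a fixed cut).  The replicate sets are
then compared across the factorial design with a linear mixed model: the
replicate value is regressed on K and SD (numeric covariates, optionally
with their interaction) with a random intercept per design cell, mirroring
how a factorial simulation's bootstrap output is usually analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diagnostics import _validate, auc

__all__ = [
    "BootstrapSet",
    "FixedEffect",
    "EffectComparison",
    "bootstrap_statistic",
    "compare_across_design",
    "compare_channels_mannwhitney",
]


@dataclass
class BootstrapSet:
    """R bootstrap replicates of one statistic in one (K, SD) cell."""

    statistic: str
    channel: str
    k: int
    sd_level: float
    replicates: np.ndarray
    seed: int | None = None
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        self.replicates = np.asarray(self.replicates, dtype=float)
        if np.any((self.replicates < 0) | (self.replicates > 1)):
            raise ValueError("replicates must lie in [0, 1]")

    @property
    def r(self) -> int:
        return len(self.replicates)


@dataclass(frozen=True)
class FixedEffect:
    estimate: float
    se: float
    pvalue: float


@dataclass
class EffectComparison:
    """Fixed-effect table of the mixed model across the (K, SD) design."""

    response: str
    fixed_effects: dict[str, FixedEffect]
    random_intercept_sd: float
    n_obs: int
    degenerate: bool = False
    interaction_included: bool = True


def bootstrap_statistic(
    scores,
    labels,
    statistic: str = "auc",
    R: int = 2000,
    rng: np.random.Generator | None = None,
    fixed_cut: float | None = None,
    channel: str = "sbp",
    k: int = 0,
    sd_level: float = 0.0,
    seed: int | None = None,
    max_redraws: int = 100_000,
) -> BootstrapSet:
    """Case-level bootstrap of a diagnostic statistic.

    Each replicate resamples the (score, label) pairs with replacement at
    the original size and recomputes the statistic.  Resamples containing a
    single outcome class are discarded and redrawn; the redraw count is
    reported on the result.  For ``statistic="ccr"`` the cut is fixed
    *before* resampling (never re-optimised per replicate) and must be
    supplied via ``fixed_cut``.
    """
    scores, labels = _validate(scores, labels)
    if statistic not in ("auc", "ccr"):
        raise ValueError("statistic must be 'auc' or 'ccr'")
    if statistic == "ccr" and fixed_cut is None:
        raise ValueError("ccr bootstrap requires fixed_cut")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(scores)
    reps = np.empty(R)
    redrawn = 0
    for i in range(R):
        while True:
            idx = rng.integers(0, n, n)
            y = labels[idx]
            s = y.sum()
            if 0 < s < n:
                break
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError("too many one-class bootstrap resamples")
        x = scores[idx]
        if statistic == "auc":
            reps[i] = auc(x, y)
        else:
            reps[i] = ((x >= fixed_cut).astype(int) == y).mean()
    return BootstrapSet(
        statistic=statistic,
        channel=channel,
        k=k,
        sd_level=sd_level,
        replicates=reps,
        seed=seed,
        n_redrawn=redrawn,
    )


def replicate_matrix(cells: list[BootstrapSet]) -> pd.DataFrame:
    """Wide replicate table, one column per design cell (R rows)."""
    return pd.DataFrame(
        {f"k{c.k}_sd{c.sd_level:g}": c.replicates for c in cells}
    )


def compare_across_design(
    cells: list[BootstrapSet],
    include_interaction: bool = True,
    factor_coding: bool = False,
) -> EffectComparison:
    """Mixed linear model of replicate values over the (K, SD) design.

    Fixed effects: K, SD and optionally their interaction, entered as
    numeric covariates by default (``factor_coding=True`` switches to
    categorical coding).  Random effect: an intercept per design cell, so
    within-cell bootstrap variation is the residual level.  P-values are
    Wald tests with a normal approximation.

    A response with zero variance cannot identify any effect; the
    comparison is then returned degenerate (all estimates zero, flagged)
    rather than fitted.
    """
    if len({c.k for c in cells}) < 2 or len({c.sd_level for c in cells}) < 2:
        raise ValueError("need >= 2 distinct K and >= 2 distinct SD levels")
    response = cells[0].statistic
    df = pd.concat(
        [
            pd.DataFrame(
                {
                    "value": c.replicates,
                    "k": c.k,
                    "sd": c.sd_level,
                    "cell": f"k{c.k}_sd{c.sd_level:g}",
                }
            )
            for c in cells
        ],
        ignore_index=True,
    )
    n_obs = len(df)
    if np.ptp(df["value"].to_numpy()) == 0.0:
        terms = ["k", "sd"] + (["k:sd"] if include_interaction else [])
        return EffectComparison(
            response=response,
            fixed_effects={t: FixedEffect(0.0, 0.0, 1.0) for t in terms},
            random_intercept_sd=0.0,
            n_obs=n_obs,
            degenerate=True,
            interaction_included=include_interaction,
        )
    import statsmodels.formula.api as smf

    # standardize the response for optimizer conditioning; fixed effects and
    # the random-intercept SD scale back linearly and p-values are invariant
    scale = float(df["value"].std(ddof=1))
    df["value_z"] = (df["value"] - df["value"].mean()) / scale
    k_term = "C(k)" if factor_coding else "k"
    sd_term = "C(sd)" if factor_coding else "sd"
    rhs = f"{k_term} * {sd_term}" if include_interaction else f"{k_term} + {sd_term}"
    model = smf.mixedlm(f"value_z ~ {rhs}", df, groups=df["cell"])
    fit = None
    errors = []
    for method in ("bfgs", "powell", "lbfgs"):
        try:
            cand = model.fit(reml=True, method=method)
        except Exception as exc:  # pragma: no cover - singular designs
            errors.append(f"{method}: {exc}")
            continue
        # a sane fit on the standardized scale has finite, moderate SEs
        if np.isfinite(cand.bse_fe).all() and np.nanmax(cand.bse_fe) < 1e3:
            fit = cand
            break
        errors.append(f"{method}: implausible standard errors")
    if fit is None:  # pragma: no cover - singular designs
        raise RuntimeError(
            "mixed-model fit failed (variance components unidentifiable): "
            + "; ".join(errors)
        )
    effects = {}
    for name in fit.fe_params.index:
        if name == "Intercept":
            continue
        effects[name] = FixedEffect(
            estimate=float(fit.fe_params[name]) * scale,
            se=float(fit.bse_fe[name]) * scale,
            pvalue=float(fit.pvalues[name]),
        )
    re_var = float(np.asarray(fit.cov_re)[0, 0])
    return EffectComparison(
        response=response,
        fixed_effects=effects,
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))) * scale,
        n_obs=n_obs,
        degenerate=False,
        interaction_included=include_interaction,
    )


def compare_channels_mannwhitney(
    replicates_a: np.ndarray, replicates_b: np.ndarray
) -> tuple[float, float]:
    """Convenience Mann-Whitney comparison of two pooled replicate sets."""
    res = stats.mannwhitneyu(replicates_a, replicates_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
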