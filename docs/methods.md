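# Methods

## The decision problem

A home blood-pressure (HBP) series is a sequence of paired
systolic/diastolic readings. The reference standard for *uncontrolled*
BP is mean-based: mean SBP ≥ 135 mmHg and/or mean DBP ≥ 85 mmHg. The
statistic under study is the per-channel **high-BP count** C — readings at
or above the channel cut, compared inclusively — out of T total readings,
and the ratio C/T. The decision rule flags a channel when C/T ≥ 0.5; for
the even series lengths used in the simulation (K = 16, 20, 24) this is
the "half of K" cutoff (≥ 8, 10, 12). For odd K the C/T ≥ 0.5 form is
authoritative, i.e. count ≥ ⌈K/2⌉.

Counts are channel-specific (SBP against 135, DBP against 85). A combined
any-channel count is computed as a convenience field
(`high_any_count`) but feeds no decision; the per-channel definition is
canonical. Series SDs use the sample (n−1) denominator, because
stratification bounds in validation reports refer to observed-cohort SDs;
users who need the population form can recompute from the stored readings.

## Factorial simulation

For each of `n_cases` (default 100) cases, a true mean pair is drawn
uniformly — SBP on [130, 140) mmHg, DBP on [80, 90) mmHg — deliberately
concentrated around the 135/85 target where a clinician's at-a-glance
judgment is hardest. Each case is expanded, for every combination of
K ∈ {16, 20, 24} and systolic reading SD ∈ {5, 10, 15, 20} mmHg, into K
independent Normal(mean, SD) readings; diastolic readings use 70% of the
systolic SD (3.5/7/10.5/14 mmHg), stored as that product exactly. The
default design therefore yields 12 cells × 100 cases = 1200 series.
Readings are raw normal draws — neither rounded nor truncated (an
optional rounding flag exists on the cohort generator only) — and the
clinical plausibility window applied to real data does not apply to
simulated series.

Two structural choices matter for reproducibility:

* the *same* 100 mean pairs are reused in every (K, SD) cell, so cells
  differ only in series length and noise — consistent with re-seeding the
  mean draw once per study;
* randomness flows through a `SeedSequence` tree (one child stream for the
  means, one per cell), so a fixed design seed fixes the whole table
  bit-for-bit on one platform and individual cells can be reproduced
  independently.

The original description of this design was published with R source
containing obvious transcription slips (`>-` where `<-` is meant,
`sdSD[j]` for `sd = SD[j]`, `rnorm(nk, …)` for `rnorm(n = k, …)`); the
generator implements the evident intent. No attempt is made to reproduce
R's Mersenne-Twister stream: quantities derived from simulation output are
matched within sampling tolerance, not bit-exactly. A consequence worth
knowing: because all cells share one mean draw, single-realization cell
statistics co-fluctuate; published single-draw values can sit collectively
a few hundredths above or below the design expectation, which is why the
package's own checks average over replicate studies where a stochastic
cell statistic is asserted.

## Diagnostics

The C-statistic is computed in Mann–Whitney form (ties count ½), which is
exact under the heavy tying of integer count scores and equals the
trapezoidal area under the threshold sweep; the test suite enforces the
identity against an exhaustive pair-counting oracle. ROC thresholds are
midpoints between consecutive distinct scores plus ∓∞ sentinels, with
predicted-positive ⇔ score ≥ threshold (matching cutoff language like
"threshold ≥ 12"). DeLong confidence intervals use the structural-
components variance with a Wald interval clipped to [0, 1]; zero estimated
variance (perfect separation) collapses the interval to the point AUC with
a warning. The Youden-optimal threshold breaks ties toward higher
specificity, then the higher threshold — the conservative direction; the
tie-break is recorded here because other implementations (e.g. pROC's
`best`) may differ. PPV/NPV on an empty margin are NaN with an explicit
`*_defined` flag, never a silent zero.

## Bootstrap and design comparison

Each (K, SD) cell is resampled at the case level: R = 2000 resamples of
the (count, label) pairs with replacement at the original size, statistic
recomputed each time. One-class resamples are rejected and redrawn, with
the redraw count reported — a defined behaviour chosen over erroring or
scoring 0.5. The CCR bootstrap fixes the half-of-K cutoff *before*
resampling; the cutoff is never re-optimised per replicate.

Replicate sets across the 12-cell design are compared with a linear mixed
model: replicate value ~ K + SD (optionally + K×SD, both fits are
available) with a random intercept per cell. K and SD enter as numeric
covariates by default — the design's factors are ordered doses and the
quantities of interest are trends — with categorical coding behind a
flag. P-values are Wald tests under a normal approximation. Numerically,
the response is standardized before fitting (bootstrap AUC spreads of
1e-2–1e-3 otherwise ill-condition the variance-component optimizer) and
estimates are rescaled afterward; optimizers are tried in the order BFGS,
Powell, L-BFGS with a plausibility check on the standard errors, because
L-BFGS can report convergence on a divergent solution for these data. A
zero-variance response returns a flagged degenerate comparison instead of
a fit.

## Calibration and decision thresholds

Mean BP is regressed on the count statistic by OLS in two forms: linear
(optionally restricted to cases whose mean BP lies in an inclusive
response window — defaults [125, 145] mmHg systolic, [75, 95] diastolic,
the near-target band where the relationship is locally linear) and
logit-predictor, y = C + β·log(x/(1−x)) on C/T ratios, the natural shape
over the full ratio range. Boundary ratios 0 and 1 are *excluded* from
logit fits, not clamped; the exclusion count is carried on the fit.
Prediction intervals are the classical t-based new-observation intervals
computed from stored sufficient statistics (n, transformed-predictor mean
and centred sum of squares, residual SD); for the logit form they are
computed on the transformed predictor scale, the standard OLS theory.
The test suite pins the intervals to statsmodels' `get_prediction`
observation intervals as an independent oracle.

Rule-in / rule-out thresholds scan the predictor domain — integer counts
0..K, or a continuous ratio grid at 1e-4 resolution (reported rounded to
2 decimals, the granularity at which such thresholds are used) — for the
smallest value whose PI lower limit reaches the target and the largest
whose PI upper limit stays below it. A non-positive slope is rejected: the
calibration presumes BP increases with the count. Per-SD calibration fits
in the simulation study use the K = 24 cell.

## Synthetic validation cohort

The cohort generator emulates the hierarchical structure of a real
outpatient HBPM dataset of treated hypertensives rather than any single
patient-level record: patient mean SBP/DBP from a bivariate normal with
means 128.2/79.9 mmHg and SDs 14.8/9.7 mmHg, between-channel correlation
0.6 (chosen so the implied prevalence of combined uncontrolled BP lands
near the ~40% observed in such cohorts); within-patient reading SDs
log-normal (ensuring positivity) with means 11.8/8.0 mmHg and log-scale
sigma 0.35; per-patient reading counts from a log-normal centred near 20,
rounded and clipped to [8, 70]. Readings are grouped two per day — real
morning/evening duplication is plausible but undocumented, so this is a
configurable guess — and every patient receives two additional first-day
readings so the first-day exclusion is exercisable. The default cohort is
412 retainable records plus 12 deliberately short records (2–7 readings
after first-day removal), so the standard exclusion pipeline retains
exactly 412 of 424.

What the generator does *not* emulate: diurnal/weekly BP rhythms,
autocorrelation between successive readings, skewness/kurtosis beyond
normality, and any dependence of reading variability on BP level. Tests
passing on this cohort therefore demonstrate that the pipeline recovers
the structure it generates — near-perfect overall discrimination of the
C/T ratio, calibration curves crossing ~135/85 mmHg at a ratio of 0.5 —
not that real-world accuracy equals these values; on real data the same
statistics are expected to be somewhat lower.

Exclusion semantics: a patient's "first day" is the earliest calendar
date present in their records; first-day removal happens before the
minimum-readings filter. Stratification bins are half-open [low, high) so
printed bounds like "10–14.9" cover values such as 14.95; the near-target
mean-BP bands ([130, 140), [80, 90)) are single-band strata whose
complement is excluded rather than binned.

## Problem sizes and numerical choices

Default analyses run at the design's native sizes: 1200 simulated series,
2000 bootstrap replicates per cell (24,000 pooled per channel), 412-patient
cohorts; the whole test suite and the acceptance script each complete in
well under a minute on one CPU. Stochastic cell statistics asserted in
tests are averaged over 10–100 replicate studies (seeded) to estimate the
design expectation rather than a single draw. Continuous threshold
searches resolve 1e-4; interval arithmetic is double precision throughout;
degenerate inputs (empty series, one-class labels, constant predictors,
singular variance components) raise explicit errors or flagged sentinel
values rather than silently propagating.

## Known limitations

* The mixed-model p-values are asymptotic Wald approximations; no
  Satterthwaite/Kenward–Roger small-sample correction is applied (with
  24,000 observations per response this is immaterial).
* The single combined "either-channel" C-statistic sometimes quoted for
  such rules is operationally ambiguous (SBP-only vs any-channel scoring);
  the package exposes per-channel results and the any-channel count
  separately instead of committing to one reading.
* BCa or percentile-t bootstrap intervals, partial AUC, smoothed ROC and
  paired DeLong comparisons are out of scope.
* The logit calibration's prediction intervals are computed on the
  transformed predictor scale; intervals defined on the raw ratio scale
  would differ slightly in the tails.
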