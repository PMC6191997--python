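# Methods

## Model and estimands

The prognostic model is a fixed logistic regression on the log-odds scale:
`y = β₀ + Σ βⱼ xⱼ`, `P(good) = expit(y)`, where a *good* outcome is an
Aphasia Severity Rating Scale (ASRS) score of 4 or 5 and the predictors are
the six SPEAK baseline variables.  Predictor coding: age, Barthel Index and
ScreeLing Phonology enter in natural units; education is the indicator
high = 1; stroke type enters as two indicators (cardio-embolic infarction,
intracerebral hemorrhage) against the non-cardio-embolic-infarction
reference.  Each model term may carry a centering offset, so configurations
using centered coefficients load without code changes.  Probabilities are
clipped to [1e−15, 1 − 1e−15] so downstream log-likelihoods are finite.

External validation treats the model as frozen and estimates:

* **c-index** — for a binary, uncensored outcome this is exactly the
  Mann–Whitney AUC, computed with midranks (ties count ½).  No
  survival-style concordance is implemented.
* **Calibration-in-the-large α** — the MLE intercept of
  `logit P(good) = α + y` with `y` a fixed offset (slope pinned to 1).
  This offset definition is the standard recalibration-framework estimand;
  the intercept of the two-parameter model is reported separately as
  `slope_model_intercept` because the two differ whenever the slope differs
  from 1.
* **Calibration slope β** — the slope of the two-parameter MLE
  `logit P(good) = a + β·y`.
* **Risk groups** — patients sorted ascending by predicted probability
  (stable sort, so ties keep input order) and split into k = 5 contiguous
  groups; with remainder `r = n mod k`, the r lowest-probability groups get
  one extra member.  Per group: mean predicted probability and the exact
  observed proportion of good outcomes.

## Recalibration

The intercept update adds α̂ (offset model, estimated on the supplied data)
to the model intercept; coefficients are untouched, so the updated model's
predictions are a monotone transform of the old ones and the c-index is
bit-identical.  Re-estimating α under the updated model on the same data
gives 0 (MLE fixed point), and a second update is the identity — both are
tested at 1e−6.

The intercept+slope update maps `intercept → a + β̂·intercept` and scales
every coefficient by β̂; refitting on the same data returns (0, 1).  A
published updated model whose update data are unavailable can instead be
reproduced verbatim with `shift_intercept` (an explicit delta).  A full
coefficient refit is deliberately out of scope: the use case is updating a
validated model, not deriving a new one.

## Numerical choices

* The offset-model MLE is found by Brent root-finding on the score
  `Σ(outcome) − Σ expit(α + y)`, which is strictly decreasing with a
  guaranteed sign change whenever both outcome classes are present; the
  offset model therefore cannot separate.  Tolerance: |score| < 1e−6
  (scaled by n/1000 for large n).
* The two-parameter fit uses Newton's method (statsmodels Logit, max 100
  iterations, tol 1e−10).  Complete or quasi-complete separation — a
  statsmodels separation error, runaway parameters (|β|·sd(y) > 50), or the
  fit reproducing every outcome to 1e−10 — raises an explicit
  `SeparationError` rather than returning a silently huge estimate; the
  score equations are verified at the solution (max-norm < 1e−6, scaled).
* Constant linear predictors make the slope unidentified → `ValueError`.
* c-index CIs: analytic DeLong by default (its variance is computed with
  the midrank algorithm and validated against R's pROC on a frozen
  fixture); optionally a seeded percentile bootstrap (default 2000
  resamples; resamples with a single outcome class are redrawn).  Intervals
  are clipped to [0, 1] and always contain the point estimate; under
  perfect separation the DeLong interval degenerates at 1.
* Integer-scale imputation (Barthel, baseline ASRS) uses round-half-up of
  the mean; real-valued fields keep the exact mean.  Mode ties are broken
  by a fixed canonical order (low < high; non-cardio-embolic <
  cardio-embolic < hemorrhage; female < male) and logged with a warning.
  Imputation statistics are computed on the analyzed (post-exclusion)
  records, matching how such cohorts are tabled.  The outcome itself is
  never mode/mean imputed — only the 3-month carry-back rule applies.

## The synthetic-data generator

`generate_baseline_cohort` draws each field independently (a Gaussian-copula
correlation knob exists for age/Barthel/ScreeLing but defaults to
independence, since real predictor correlations are not published):

| field | distribution | default |
| --- | --- | --- |
| age (years) | truncated normal on [18, 85] | mean 65, scale 12 |
| sex | Bernoulli | P(female) = 0.43 |
| education | Bernoulli | P(low) = 0.54 |
| stroke type | categorical | 0.62 / 0.18 / 0.18, 0.02 unknown |
| Barthel Index (0–20) | two-component discrete mixture | median 16, IQR 6–20 |
| ScreeLing Phonology (0–24) | truncated normal | mean 15, scale 6.5 |
| baseline ASRS | categorical | 0.13/0.16/0.21/0.29/0.21/0 |

Truncated normals are moment-matched: asymmetric truncation shifts the mean
of a naive truncated normal (for age by over a year), so the location
parameter is solved by root-finding to make the *realized* mean equal the
target — published cohort means are observed means.  The realized SD is
slightly below the scale parameter; only the mean is matched.

The Barthel quantile triple (median 16, quartiles 6 and 20) forces at least
25% of mass exactly at 20 plus a distinct low mode; the generator uses
weight 0.255 on Binomial(20, 0.25) (severe dependence, mean 5) and weight
0.745 on `20 − min(NegBinom(r = 0.4, p = 0.08), 20)` (mild, piled at full
independence), tuned once so the distribution's quartiles are exactly
(6, 16, 20).

`generate_outcomes` inverts the calibration model: good outcome ~
Bernoulli(expit(α + β·y)) under an explicit truth (α, β), then maps good →
ASRS ∈ {4, 5} and poor → ASRS ∈ {0..3} so dichotomization recovers the
draw exactly.  The packaged emulation truth is **α = −1.98, β = 0.88**
(default seed 20180915): an over-optimistic model with ~12% weakened
predictor effects.  One subtlety is intentional and documented in the
tests: when the generating slope is below 1, the offset-model α̂ absorbs
part of the slope misfit, so on a simulated population it lands below the
generating −1.98 (around −2.3 with the packaged model's linear-predictor
distribution).  The exactly identified recovery checks therefore use
matched designs: slope truth with the two-parameter fit, offset truth
(slope 1) with the offset fit.

Missingness defaults mirror the documented patient flow (6-month outcome
missing with probability 28/153; among those, 3-month score available with
probability 7/28; Barthel missing 14/131).  `flow_fixture()` is a fully
deterministic 153-patient table whose analyzed subset reproduces the
published baseline counts exactly and whose flow is exactly
153 → 1 ineligible, 21 excluded, 7 carried back, 131 analyzed.

What the generator does **not** emulate: predictor–outcome structure beyond
the linear predictor (outcomes depend on baselines only through y),
longitudinal ASRS trajectories, treatment arms, informative missingness
(all masking is completely at random), and real predictor correlations
unless the copula knob is set.  Passing tests therefore demonstrate correct
recovery of known truths under these idealized conditions, not performance
on real clinical data.

## Packaged model configurations

The published SPEAK coefficient values live in a supplement that is not
redistributed here, so the packaged `speak12`/`speak6` configurations are
**synthetic stand-ins**: the documented structure and coding with plausible
coefficients (ScreeLing +0.20, Barthel +0.10, age −0.03 per year, high
education +0.6, cardio-embolic −0.5, hemorrhage +0.4 on the log-odds
scale), with the SPEAK-12 intercept (−0.0148) fixed by the single
condition that the mean predicted probability on the default simulated
cohort is 0.88 — the mean prediction an over-optimistic 12-month model
produces on such a population.  The SPEAK-6 stand-in lowers only the
intercept, by 1.74, the shift implied by a calibration-in-the-large of
−1.98 before and −0.24 after a published intercept update.  Every
algorithmic test uses synthetic or toy specifications, so no result depends
on the stand-in values.

## Problem sizes

Large-sample checks (parameter recovery, calibrated limits, marginals) use
n = 50,000–100,000, where Fisher standard errors are ≈0.01 for both α and
β; toy oracle checks use 6–20 observations so exhaustive enumeration and
grid search are exact.  The bootstrap-coverage study uses 200 replicates of
n = 500 with 300 resamples per interval.  The sklearn estimator layer
(`PrognosticModel`, `LogisticRecalibrator`) is a thin wrapper over the
functions documented above and adds no numerics of its own.

## Known limitations

* The c-index CI method in the original analysis is unknown; DeLong is the
  default here as the field-standard analytic choice.
* Whether published grouped calibration plots used remainder-adjusted group
  sizes is unknown; the remainder rule here (extra members to the
  lowest-probability groups) is one deterministic convention.
* Simple (single-value) imputation understates uncertainty by design; the
  pipeline intentionally matches the simple-imputation analysis it
  validates rather than multiple imputation.
* A reported 68% observed good-outcome proportion alongside 86/124 in the
  source tables cannot be reconciled exactly; the deterministic fixture
  reproduces the patient-flow counts and leaves the observed proportion
  free.
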