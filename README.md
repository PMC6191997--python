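# speakval

External validation and recalibration of the **SPEAK model**, a logistic
prognostic model for long-term outcome of aphasia after stroke — plus the
synthetic-cohort machinery needed to exercise the whole validation pipeline
when the original patient data are not available.

## The problem

About 30% of stroke patients suffer aphasia, and most ask early on how their
language will recover.  The SPEAK model predicts the probability of a *good*
outcome — a score of 4 or 5 on the 0–5 Aphasia Severity Rating Scale (ASRS) —
from six baseline variables collected in the first days after stroke:
ScreeLing Phonology score (0–24), Barthel Index (0–20), age, education level
(high/low), cardio-embolic infarction (yes/no) and intracerebral hemorrhage
(yes/no).  Before such a model can be used on new patients it must be
externally validated: does it still discriminate, and are its predicted
probabilities still right on average?

The model is

```
y  =  β₀ + β₁·ScreeLing + β₂·Barthel + β₃·age + β₄·eduHigh + β₅·cardioEmb + β₆·ICH
P(good outcome) = 1 / (1 + e^(−y))
```

Validation quantifies:

* **discrimination** — the concordance statistic (c-index), identical to the
  Mann–Whitney AUC for a binary outcome;
* **calibration-in-the-large** *α* — the intercept of
  `logit P(good) = α + y` with the linear predictor *y* as a fixed offset;
  0 when predictions are right on average, negative when the model is
  over-optimistic;
* **calibration slope** *β* — the slope of the two-parameter refit
  `logit P(good) = a + β·y`; 1 under perfect calibration, below 1 when
  predictor effects are weaker in the new data;
* a **calibration plot** of observed outcome proportions against mean
  predicted probability in five equally large predicted-risk groups.

When average calibration fails (for instance because the outcome is measured
at 6 months instead of 12), the model is **recalibrated** by adding α̂ to its
intercept, leaving all coefficients — and hence discrimination — untouched.

The cohort pipeline mirrors how validation cohorts are actually prepared:
ineligible patients are dropped, a missing 6-month outcome is replaced by the
3-month score when available (*carry-back*) and otherwise leads to exclusion,
and missing baseline predictors are simply imputed (mode for categorical,
mean for continuous, rounded half-up on integer scales).

> The packaged `speak12`/`speak6` model configurations carry the documented
> model structure but **synthetic stand-in coefficients** (the published
> coefficient appendix is not redistributed here).  They support simulation
> and pipeline work, not clinical prediction.

## Worked example

Simulate a 131-patient validation-style cohort under the default
miscalibration truth (α = −1.98, β = 0.88 — a model that overestimates good
outcome, with slightly weakened predictor effects), validate the packaged
model on it, and recalibrate:

```python
from speakval import (build_analysis_cohort, external_validation,
                      linear_predictor_frame, load_packaged_model,
                      simulate_rats3_cohort, update_intercept)

spec = load_packaged_model("speak12")
cohort = build_analysis_cohort(simulate_rats3_cohort(n=131, seed=20180915))
result = external_validation(spec, cohort, seed=0)

y = linear_predictor_frame(spec, cohort.records)
speak6 = update_intercept(spec, y, cohort.outcome_array(),
                          new_horizon_months=6, name="SPEAK-6-refit")
```

which prints (via the `result` fields):

```
n analyzed            : 131
c-index (95% CI)      : 0.774 (0.692-0.855)
calibration-in-large  : -2.289
calibration slope     : 0.926
mean predicted        : 0.874
observed proportion   : 0.542
updated intercept     : -2.304 (was -0.015)
alpha after update    : 0.000000
```

Reading: the model ranks patients well (c-index 0.77) but predicts an 87%
chance of good outcome where only 54% recover well — it is badly
miscalibrated in the large (α̂ = −2.3 at n = 131; the slope estimate 0.93 is
noisy at this sample size).  Folding α̂ into the intercept makes
calibration-in-the-large exactly zero on the same data, without changing the
c-index.

The same workflow is available from the shell:

```
speakval simulate --out sim --n 131 --seed 20180915
speakval validate --model speak12 --cohort sim/cohort.csv --out val --plot
speakval recalibrate --model speak12 --cohort sim/cohort.csv --out rec --horizon 6
speakval flowcheck --out flow       # patient-flow accounting on the built-in fixture
```

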