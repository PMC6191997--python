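"""Synthetic validation-style cohorts with controlled miscalibration.

Generates patient tables whose baseline marginals emulate a multicenter
aphasia-after-stroke validation cohort (n = 131 analyzed): age truncated
normal 65 (12) on 18-85, 43% female, 54% low education, stroke type
62/18/18% (2% unknown), Barthel Index with median 16 and IQR 6-20,
ScreeLing Phonology truncated normal 15 (6.5) on 0-24, and baseline ASRS
category frequencies 13/16/21/29/21/0%.

Outcomes are generated under an explicit miscalibration truth
``(alpha, beta)``: good outcome ~ Bernoulli(expit(alpha + beta * y)) with y
the model's linear predictor, then mapped to ASRS scores (good -> {4, 5},
poor -> {0..3}) so that dichotomizing the ASRS downstream recovers the
binary draw exactly.  The packaged default truth is alpha = -1.98,
beta = 0.88 — a model that overestimates the probability of good outcome
and whose predictor effects are ~12% weaker in the new data.

Missingness follows the documented patient flow: 28/153 missing the
6-month outcome, 7 of those 28 with a 3-month score available (carried
back), 14/131 missing Barthel.

``flow_fixture`` is a fully deterministic 153-patient table reproducing the
published patient flow and baseline counts exactly.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import COLUMNS, impute_baseline
from .metrics import CalibrationParameters
from .model import ModelSpecification, linear_predictor_frame, load_packaged_model

__all__ = [
    "CohortMarginals",
    "DEFAULT_SEED",
    "MissingnessPattern",
    "RATS3_TRUTH",
    "apply_missingness",
    "flow_fixture",
    "generate_baseline_cohort",
    "generate_outcomes",
    "simulate_rats3_cohort",
]

#: Default miscalibration truth for the validation-cohort emulation profile.
RATS3_TRUTH = CalibrationParameters(alpha=-1.98, beta=0.88)

#: Default seed of the emulation profile.
DEFAULT_SEED = 20180915

_STROKE = (
    "non_cardioembolic_infarction",
    "cardioembolic_infarction",
    "intracerebral_hemorrhage",
)


class CohortMarginals(BaseModel):
    """Marginal distributions of the baseline variables.

    The Barthel Index generator is a two-component discrete mixture on
    0-20: a low component Binomial(20, barthel_low_p) (severe dependence,
    mean around 5) and a high component ``20 - min(NegBinom(r, p), 20)``
    (mild, piled up at full independence), with weights and shape tuned so
    the distribution's median is 16 and its quartiles are 6 and 20.
    """

    model_config = ConfigDict(validate_assignment=True)

    age_mean: float = 65.0
    age_sd: float = Field(default=12.0, gt=0)
    age_min: float = 18.0
    age_max: float = 85.0
    p_female: float = Field(default=0.43, ge=0, le=1)
    p_low_education: float = Field(default=0.54, ge=0, le=1)
    stroke_probs: tuple[float, float, float] = (0.62, 0.18, 0.18)
    p_stroke_unknown: float = Field(default=0.02, ge=0, le=1)
    barthel_weight_low: float = Field(default=0.255, ge=0, le=1)
    barthel_low_p: float = Field(default=0.25, gt=0, lt=1)
    barthel_high_r: float = Field(default=0.4, gt=0)
    barthel_high_p: float = Field(default=0.08, gt=0, lt=1)
    screeling_mean: float = 15.0
    screeling_sd: float = Field(default=6.5, gt=0)
    asrs_baseline_probs: tuple[float, float, float, float, float, float] = (
        0.13, 0.16, 0.21, 0.29, 0.21, 0.0,
    )

    @model_validator(mode="after")
    def _probs_sum(self) -> "CohortMarginals":
        s = sum(self.stroke_probs) + self.p_stroke_unknown
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"stroke-type probabilities must sum to 1, got {s}")
        s = sum(self.asrs_baseline_probs)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"baseline-ASRS probabilities must sum to 1, got {s}")
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be below age_max")
        return self

    def barthel_pmf(self) -> np.ndarray:
        """Probability mass function of the Barthel mixture on 0..20."""
        ks = np.arange(21)
        low = stats.binom.pmf(ks, 20, self.barthel_low_p)
        tail = stats.nbinom.pmf(np.arange(400), self.barthel_high_r, self.barthel_high_p)
        capped = tail[:21].copy()
        capped[20] += tail[21:].sum()
        high = capped[20 - ks]
        pmf = self.barthel_weight_low * low + (1 - self.barthel_weight_low) * high
        return pmf / pmf.sum()


class MissingnessPattern(BaseModel):
    """Field-wise missingness rates mirroring the documented patient flow."""

    p_missing_6mo: float = Field(default=28 / 153, ge=0, le=1)
    p_3mo_available_given_6mo_missing: float = Field(default=7 / 28, ge=0, le=1)
    p_missing_barthel: float = Field(default=14 / 131, ge=0, le=1)
    p_missing_education: float = Field(default=0.0, ge=0, le=1)
    p_missing_stroke_type: float = Field(default=0.0, ge=0, le=1)


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float, lo: float, hi: float):
    """Quantiles of a truncated normal whose *truncated* mean equals ``mean``.

    Asymmetric truncation shifts the mean of a plain truncated normal away
    from its location parameter (for age on [18, 85] by more than a year),
    so the location is moment-matched by root-finding: the published cohort
    means are observed means, and the generator should reproduce them.
    """

    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    loc = brentq(lambda c: trunc_mean(c) - mean, lo, hi, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=sd)


def generate_baseline_cohort(
    n: int,
    marginals: Optional[CohortMarginals] = None,
    seed=None,
    copula_corr: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Draw ``n`` baseline records from the configured marginals.

    Fields are sampled independently unless ``copula_corr`` (a 3x3
    correlation matrix for age, Barthel, ScreeLing) installs a Gaussian
    copula between the ordered variables.  Outcome columns are left missing;
    all records are eligible.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    m = marginals if marginals is not None else CohortMarginals()
    rng = np.random.default_rng(seed)

    if copula_corr is None:
        z = rng.standard_normal((n, 3))
    else:
        R = np.asarray(copula_corr, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T):
            raise ValueError("copula_corr must be a symmetric 3x3 matrix")
        z = rng.standard_normal((n, 3)) @ np.linalg.cholesky(R).T
    u = stats.norm.cdf(z)

    age = _truncnorm_ppf(u[:, 0], m.age_mean, m.age_sd, m.age_min, m.age_max)
    pmf = m.barthel_pmf()
    barthel = np.searchsorted(np.cumsum(pmf), u[:, 1], side="left").clip(0, 20)
    screeling = _truncnorm_ppf(u[:, 2], m.screeling_mean, m.screeling_sd, 0.0, 24.0)

    sex = np.where(rng.random(n) < m.p_female, "female", "male")
    education = np.where(rng.random(n) < m.p_low_education, "low", "high")
    stroke_levels = np.array(list(_STROKE) + [None], dtype=object)
    stroke_p = list(m.stroke_probs) + [m.p_stroke_unknown]
    stroke = rng.choice(stroke_levels, size=n, p=stroke_p)
    asrs_b = rng.choice(6, size=n, p=list(m.asrs_baseline_probs)).astype(float)

    df = pd.DataFrame(
        {
            "patient_id": [f"S{i + 1:05d}" for i in range(n)],
            "age_years": age,
            "sex": sex,
            "education_level": education,
            "stroke_type": stroke,
            "barthel_index": barthel.astype(float),
            "screeling_phonology": screeling,
            "asrs_baseline": asrs_b,
            "asrs_3mo": np.nan,
            "asrs_6mo": np.nan,
            "eligible": True,
        },
        columns=COLUMNS,
    )
    df["stroke_type"] = df["stroke_type"].where(df["stroke_type"].notna(), np.nan)
    return df


def generate_outcomes(
    linear_predictors,
    truth: CalibrationParameters,
    horizon_months: int = 6,
    seed=None,
    good_weights: Sequence[float] = (0.5, 0.5),
    poor_weights: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> np.ndarray:
    """ASRS outcomes under the miscalibration truth.

    ``P(good_i) = expit(truth.alpha + truth.beta * y_i)``; good outcomes
    receive an ASRS from {4, 5}, poor from {0..3}, so downstream
    dichotomization recovers the Bernoulli draw exactly.
    """
    y = np.asarray(linear_predictors, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("linear predictors must be finite")
    if horizon_months <= 0:
        raise ValueError("horizon_months must be positive")
    rng = np.random.default_rng(seed)
    p = expit(truth.alpha + truth.beta * y)
    good = rng.random(y.size) < p
    asrs_good = rng.choice([4, 5], size=y.size, p=list(good_weights))
    asrs_poor = rng.choice([0, 1, 2, 3], size=y.size, p=list(poor_weights))
    return np.where(good, asrs_good, asrs_poor).astype(int)


def apply_missingness(
    df: pd.DataFrame, pattern: Optional[MissingnessPattern] = None, seed=None
) -> pd.DataFrame:
    """Mask fields at the configured rates (a copy; deterministic given seed).

    The 6-month outcome is masked with ``p_missing_6mo``; among masked rows
    the 3-month outcome survives with ``p_3mo_available_given_6mo_missing``
    and is masked otherwise.  Baseline fields are masked independently.
    """
    pat = pattern if pattern is not None else MissingnessPattern()
    rng = np.random.default_rng(seed)
    out = df.copy()
    n = len(out)

    mask6 = rng.random(n) < pat.p_missing_6mo
    keep3 = rng.random(n) < pat.p_3mo_available_given_6mo_missing
    out.loc[mask6, "asrs_6mo"] = np.nan
    out.loc[mask6 & ~keep3, "asrs_3mo"] = np.nan

    for col, rate in (
        ("barthel_index", pat.p_missing_barthel),
        ("education_level", pat.p_missing_education),
        ("stroke_type", pat.p_missing_stroke_type),
    ):
        mask = rng.random(n) < rate
        out.loc[mask, col] = np.nan
    return out


def simulate_rats3_cohort(
    n: int = 131,
    spec: Optional[ModelSpecification] = None,
    marginals: Optional[CohortMarginals] = None,
    truth: CalibrationParameters = RATS3_TRUTH,
    missingness: Optional[MissingnessPattern] = None,
    seed=DEFAULT_SEED,
    copula_corr: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """The full emulation profile: baselines, model-based outcomes, missingness.

    Linear predictors come from ``spec`` (default: the packaged synthetic
    SPEAK-12 configuration) evaluated on the generated baselines (unknown
    categories filled by simple imputation first, as in the real pipeline);
    6-month ASRS outcomes are generated under ``truth``; 3-month ASRS are an
    independent draw under the same truth (so carried-back outcomes exist);
    ``missingness`` (default: none) is applied last.
    """
    rng = np.random.default_rng(seed)
    model = spec if spec is not None else load_packaged_model("speak12")

    df = generate_baseline_cohort(
        n, marginals=marginals, seed=rng, copula_corr=copula_corr
    )
    complete, _ = impute_baseline(df)
    y = linear_predictor_frame(model, complete)
    df["asrs_6mo"] = generate_outcomes(y, truth, horizon_months=6, seed=rng).astype(float)
    df["asrs_3mo"] = generate_outcomes(y, truth, horizon_months=3, seed=rng).astype(float)
    if missingness is not None:
        df = apply_missingness(df, missingness, seed=rng)
    return df


# ---------------------------------------------------------------------------
# Deterministic patient-flow fixture
# ---------------------------------------------------------------------------

_FIXTURE_SEED = 913

def flow_fixture() -> pd.DataFrame:
    """A deterministic 153-patient cohort reproducing the published flow.

    Of 153 enrolled: 1 ineligible (aphasia later attributed to a brain
    tumor), 28 missing the 6-month ASRS of whom exactly 7 have a 3-month
    score (carried back) and 21 have neither (excluded), leaving 131
    analyzed.  The analyzed records' baseline counts match the published
    validation-cohort table exactly: 56 female; education 60 high / 71 low;
    stroke type 81 / 23 / 24 with 3 unknown; baseline ASRS counts
    17/21/28/38/27/0; 14 missing Barthel scores.  Bit-identical on every
    call.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)

    def counts_column(pairs):
        vals = np.concatenate([np.repeat(v, c) for v, c in pairs])
        return vals[rng.permutation(len(vals))]

    n = 131
    sex = counts_column([("female", 56), ("male", 75)])
    education = counts_column([("high", 60), ("low", 71)])
    stroke = counts_column(
        [(_STROKE[0], 81), (_STROKE[1], 23), (_STROKE[2], 24), (None, 3)]
    )
    asrs_b = counts_column([(0, 17), (1, 21), (2, 28), (3, 38), (4, 27)]).astype(float)

    age = np.round(_truncnorm_ppf(rng.random(n), 65, 12, 18, 85), 1)
    screeling = np.round(_truncnorm_ppf(rng.random(n), 15, 6.5, 0, 24), 0)
    pmf = CohortMarginals().barthel_pmf()
    barthel = np.searchsorted(np.cumsum(pmf), rng.random(n)).clip(0, 20).astype(float)
    barthel[rng.permutation(n)[:14]] = np.nan  # 14 missing Barthel scores

    good = rng.random(n) < 0.68
    asrs_out = np.where(
        good, rng.choice([4, 5], size=n), rng.choice([0, 1, 2, 3], size=n)
    ).astype(float)
    carried = np.zeros(n, dtype=bool)
    carried[rng.permutation(n)[:7]] = True  # 7 carried back from 3 months
    asrs_6mo = np.where(carried, np.nan, asrs_out)
    asrs_3mo = asrs_out.copy()

    analyzed = pd.DataFrame(
        {
            "patient_id": "",
            "age_years": age,
            "sex": sex,
            "education_level": education,
            "stroke_type": stroke,
            "barthel_index": barthel,
            "screeling_phonology": screeling,
            "asrs_baseline": asrs_b,
            "asrs_3mo": asrs_3mo,
            "asrs_6mo": asrs_6mo,
            "eligible": True,
        },
        columns=COLUMNS,
    )

    extra = generate_baseline_cohort(22, seed=rng)
    excluded = extra.iloc[:21].copy()  # no outcome at 3 or 6 months
    excluded["asrs_3mo"] = np.nan
    excluded["asrs_6mo"] = np.nan
    ineligible = extra.iloc[21:].copy()  # the brain-tumor exclusion
    ineligible["eligible"] = False
    ineligible["asrs_3mo"] = 3.0
    ineligible["asrs_6mo"] = 4.0

    df = pd.concat([analyzed, excluded, ineligible], ignore_index=True)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df["patient_id"] = [f"R{i + 1:03d}" for i in range(len(df))]
    df["stroke_type"] = df["stroke_type"].where(df["stroke_type"].notna(), np.nan)
    return df
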