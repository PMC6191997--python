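"""Prognostic-model core: specification, linear predictor, probability, outcome.

The SPEAK models are logistic prognostic models for good long-term outcome of
aphasia after stroke.  A model is an intercept plus a weighted sum of coded
baseline predictors on the log-odds scale (the linear predictor ``y``); the
predicted probability of a good outcome is ``expit(y)``.  Outcome is the
Aphasia Severity Rating Scale (ASRS, 0-5) dichotomized at 4: a score of 4 or
5 is a *good* outcome, below 4 is *poor*.

The six SPEAK predictors and their coding:

================================  =============================================
predictor_id                      coded value
================================  =============================================
``age_years``                     age in years, as-is
``barthel_index``                 Barthel Index (0-20), as-is
``screeling_phonology``           ScreeLing Phonology score (0-24), as-is
``education_high``                1 if education level is high, else 0
``education_low``                 1 if education level is low, else 0
``cardioembolic_infarction``      1 if stroke type is cardio-embolic infarction
``intracerebral_hemorrhage``      1 if stroke type is intracerebral hemorrhage
``sex_female`` / ``sex_male``     1 if sex matches, else 0
================================  =============================================

Non-cardio-embolic infarction is the stroke-type reference category.  Each
term may carry an optional ``center`` offset: the contribution is
``coefficient * (coded - center)``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Callable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.special import expit

from .exceptions import MissingPredictorError, UnknownPredictorError

__all__ = [
    "ASRS_GOOD_CUTOFF",
    "PROB_CLIP",
    "ModelSpecification",
    "ModelTerm",
    "PatientPrediction",
    "PatientRecord",
    "classify_outcome",
    "linear_predictor",
    "linear_predictor_frame",
    "load_model",
    "load_packaged_model",
    "predict_probability",
    "predict_probability_frame",
    "save_model",
]

#: ASRS score at or above which outcome is classified as good.
ASRS_GOOD_CUTOFF = 4

#: Probabilities are clipped to [PROB_CLIP, 1 - PROB_CLIP] so that
#: downstream log-likelihoods never evaluate log(0).
PROB_CLIP = 1e-15

Sex = Literal["female", "male"]
Education = Literal["high", "low"]
StrokeType = Literal[
    "non_cardioembolic_infarction",
    "cardioembolic_infarction",
    "intracerebral_hemorrhage",
]

STROKE_TYPES: tuple[str, ...] = (
    "non_cardioembolic_infarction",
    "cardioembolic_infarction",
    "intracerebral_hemorrhage",
)


class PatientRecord(BaseModel):
    """One patient's baseline predictors and ASRS outcome scores.

    Missing values are ``None``.  ``eligible`` is False for protocol
    exclusions discovered after enrolment (e.g. aphasia later attributed to
    a brain tumor rather than stroke).
    """

    model_config = ConfigDict(validate_assignment=True)

    patient_id: str
    age_years: Optional[float] = Field(default=None, ge=0, le=120)
    sex: Optional[Sex] = None
    education_level: Optional[Education] = None
    stroke_type: Optional[StrokeType] = None
    barthel_index: Optional[int] = Field(default=None, ge=0, le=20)
    screeling_phonology: Optional[float] = Field(default=None, ge=0, le=24)
    asrs_baseline: Optional[int] = Field(default=None, ge=0, le=5)
    asrs_3mo: Optional[int] = Field(default=None, ge=0, le=5)
    asrs_6mo: Optional[int] = Field(default=None, ge=0, le=5)
    eligible: bool = True


# ---------------------------------------------------------------------------
# Predictor coding
# ---------------------------------------------------------------------------

def _indicator(field: str, value: str) -> Callable[[Mapping], Optional[float]]:
    def code(rec: Mapping) -> Optional[float]:
        v = rec.get(field)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return 1.0 if v == value else 0.0

    return code


def _numeric(field: str) -> Callable[[Mapping], Optional[float]]:
    def code(rec: Mapping) -> Optional[float]:
        v = rec.get(field)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    return code


#: predictor_id -> (source record field, scalar coding function)
CODINGS: dict[str, tuple[str, Callable[[Mapping], Optional[float]]]] = {
    "age_years": ("age_years", _numeric("age_years")),
    "barthel_index": ("barthel_index", _numeric("barthel_index")),
    "screeling_phonology": ("screeling_phonology", _numeric("screeling_phonology")),
    "education_high": ("education_level", _indicator("education_level", "high")),
    "education_low": ("education_level", _indicator("education_level", "low")),
    "cardioembolic_infarction": (
        "stroke_type",
        _indicator("stroke_type", "cardioembolic_infarction"),
    ),
    "intracerebral_hemorrhage": (
        "stroke_type",
        _indicator("stroke_type", "intracerebral_hemorrhage"),
    ),
    "sex_female": ("sex", _indicator("sex", "female")),
    "sex_male": ("sex", _indicator("sex", "male")),
}


class ModelTerm(BaseModel):
    """One additive model term: coefficient * (coded predictor - center)."""

    predictor_id: str
    coefficient: float
    center: float = 0.0

    @field_validator("coefficient", "center")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("model coefficients must be finite")
        return v


class ModelSpecification(BaseModel):
    """A logistic prognostic model on the log-odds scale.

    ``intercept`` and every ``terms[i].coefficient`` are log-odds (per unit
    for continuous predictors, per category for indicators).
    ``outcome_horizon_months`` is the follow-up time the model predicts at:
    12 for SPEAK-12, 6 for SPEAK-6.
    """

    name: str
    outcome_horizon_months: int = Field(gt=0)
    intercept: float
    terms: list[ModelTerm] = Field(default_factory=list)
    metadata: dict = Field(default_factory=dict)

    @field_validator("intercept")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("intercept must be finite")
        return v

    @model_validator(mode="after")
    def _unique_terms(self) -> "ModelSpecification":
        ids = [t.predictor_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("predictor_ids must be unique within terms")
        return self

    def coefficients(self) -> dict[str, float]:
        return {t.predictor_id: t.coefficient for t in self.terms}


class PatientPrediction(BaseModel):
    """Linear predictor y (log-odds) and probability of good outcome."""

    patient_id: str
    linear_predictor: float
    probability: float = Field(gt=0.0, lt=1.0)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _as_mapping(record) -> Mapping:
    if isinstance(record, PatientRecord):
        return record.model_dump()
    if isinstance(record, pd.Series):
        return record.to_dict()
    return record


def linear_predictor(spec: ModelSpecification, record) -> float:
    """Evaluate the model's linear predictor y for one patient.

    ``record`` may be a :class:`PatientRecord`, a mapping, or a pandas row.
    Raises :class:`MissingPredictorError` if any predictor named by the model
    is missing (imputation happens upstream), and
    :class:`UnknownPredictorError` for a term with no registered coding.
    """
    rec = _as_mapping(record)
    y = spec.intercept
    for term in spec.terms:
        coding = CODINGS.get(term.predictor_id)
        if coding is None:
            raise UnknownPredictorError(term.predictor_id)
        coded = coding[1](rec)
        if coded is None:
            raise MissingPredictorError(
                term.predictor_id, detail=f"patient {rec.get('patient_id')!r}"
            )
        y += term.coefficient * (coded - term.center)
    return float(y)


def linear_predictor_frame(
    spec: ModelSpecification, frame: pd.DataFrame
) -> np.ndarray:
    """Vectorized linear predictor over a cohort table (one row per patient)."""
    y = np.full(len(frame), spec.intercept, dtype=float)
    for term in spec.terms:
        coding = CODINGS.get(term.predictor_id)
        if coding is None:
            raise UnknownPredictorError(term.predictor_id)
        field, _ = coding
        if field not in frame.columns:
            raise MissingPredictorError(term.predictor_id, detail=f"no column {field!r}")
        col = frame[field]
        if field in ("age_years", "barthel_index", "screeling_phonology"):
            coded = pd.to_numeric(col).to_numpy(dtype=float)
        else:
            target = {
                "education_high": "high",
                "education_low": "low",
                "cardioembolic_infarction": "cardioembolic_infarction",
                "intracerebral_hemorrhage": "intracerebral_hemorrhage",
                "sex_female": "female",
                "sex_male": "male",
            }[term.predictor_id]
            coded = np.where(col.isna(), np.nan, (col == target).astype(float))
        if np.isnan(coded).any():
            n_bad = int(np.isnan(coded).sum())
            raise MissingPredictorError(
                term.predictor_id, detail=f"{n_bad} record(s) missing"
            )
        y += term.coefficient * (coded - term.center)
    return y


def predict_probability(spec: ModelSpecification, record) -> PatientPrediction:
    """Predicted probability of good outcome for one patient."""
    rec = _as_mapping(record)
    y = linear_predictor(spec, rec)
    p = float(np.clip(expit(y), PROB_CLIP, 1.0 - PROB_CLIP))
    return PatientPrediction(
        patient_id=str(rec.get("patient_id")), linear_predictor=y, probability=p
    )


def predict_probability_frame(
    spec: ModelSpecification, frame: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized predictions: columns patient_id, linear_predictor, probability."""
    y = linear_predictor_frame(spec, frame)
    p = np.clip(expit(y), PROB_CLIP, 1.0 - PROB_CLIP)
    return pd.DataFrame(
        {
            "patient_id": frame["patient_id"].to_numpy(),
            "linear_predictor": y,
            "probability": p,
        }
    )


def classify_outcome(asrs) -> str:
    """Dichotomize an ASRS score: ``good`` iff ASRS >= 4, else ``poor``."""
    if asrs is None or (isinstance(asrs, float) and math.isnan(asrs)):
        raise ValueError("ASRS score is missing; cannot classify outcome")
    a = float(asrs)
    if a != int(a) or not 0 <= a <= 5:
        raise ValueError(f"ASRS score must be an integer in [0, 5], got {asrs!r}")
    return "good" if a >= ASRS_GOOD_CUTOFF else "poor"


# ---------------------------------------------------------------------------
# Specification I/O
# ---------------------------------------------------------------------------

def save_model(spec: ModelSpecification, path) -> None:
    """Write a specification to JSON or YAML (by extension), losslessly."""
    path = Path(path)
    payload = spec.model_dump(mode="json")
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path) -> ModelSpecification:
    """Read a specification from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return ModelSpecification.model_validate(payload)


_PACKAGED = {
    "speak12": "speak12_synthetic.json",
    "speak6": "speak6_synthetic.json",
}


def load_packaged_model(name: str = "speak12") -> ModelSpecification:
    """Load a packaged model configuration.

    The packaged SPEAK-12/SPEAK-6 configurations carry the documented model
    structure (the six baseline predictors with their coding) but synthetic
    stand-in coefficients: the published coefficient appendix is not
    redistributed with this package.  They are suitable for simulation and
    pipeline work, not for clinical prediction.
    """
    key = name.lower().replace("-", "")
    if key not in _PACKAGED:
        raise KeyError(f"no packaged model {name!r}; available: {sorted(_PACKAGED)}")
    return load_model(Path(__file__).parent / "data" / _PACKAGED[key])
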