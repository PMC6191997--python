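import numpy as np
import pytest

from speakval import ModelSpecification, ModelTerm, PatientRecord


@pytest.fixture
def toy_spec():
    """Small two-term model: intercept -1.0, age +0.02/yr, ICH -0.8."""
    return ModelSpecification(
        name="toy",
        outcome_horizon_months=6,
        intercept=-1.0,
        terms=[
            ModelTerm(predictor_id="age_years", coefficient=0.02),
            ModelTerm(predictor_id="intracerebral_hemorrhage", coefficient=-0.8),
        ],
    )


@pytest.fixture
def full_record():
    """A complete record at non-reference stroke type."""
    return PatientRecord(
        patient_id="p1",
        age_years=70,
        sex="male",
        education_level="low",
        stroke_type="intracerebral_hemorrhage",
        barthel_index=12,
        screeling_phonology=14.0,
        asrs_baseline=2,
        asrs_3mo=3,
        asrs_6mo=4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
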