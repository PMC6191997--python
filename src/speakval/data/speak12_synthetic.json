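{
  "name": "SPEAK-12-synthetic",
  "outcome_horizon_months": 12,
  "intercept": -0.0148,
  "terms": [
    {"predictor_id": "screeling_phonology", "coefficient": 0.2, "center": 0.0},
    {"predictor_id": "barthel_index", "coefficient": 0.1, "center": 0.0},
    {"predictor_id": "age_years", "coefficient": -0.03, "center": 0.0},
    {"predictor_id": "education_high", "coefficient": 0.6, "center": 0.0},
    {"predictor_id": "cardioembolic_infarction", "coefficient": -0.5, "center": 0.0},
    {"predictor_id": "intracerebral_hemorrhage", "coefficient": 0.4, "center": 0.0}
  ],
  "metadata": {
    "synthetic": true,
    "description": "Synthetic stand-in for the SPEAK-12 model: the documented predictor set and coding with plausible coefficients chosen so that the mean predicted probability of good outcome on the default simulated validation-style cohort is 0.88. The published coefficients are not redistributed; do not use for clinical prediction.",
    "outcome": "good aphasia outcome (ASRS 4 or 5) at 12 months after stroke"
  }
}
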