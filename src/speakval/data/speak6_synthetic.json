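{
  "name": "SPEAK-6-synthetic",
  "outcome_horizon_months": 6,
  "intercept": -1.7548,
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
    "description": "Synthetic stand-in for the SPEAK-6 model: identical coefficients to the SPEAK-12 stand-in with the intercept lowered by 1.74, the shift implied by a calibration-in-the-large of -1.98 before and -0.24 after the published 6-month intercept update. Do not use for clinical prediction.",
    "outcome": "good aphasia outcome (ASRS 4 or 5) at 6 months after stroke"
  }
}
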