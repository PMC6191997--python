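"""Exception hierarchy for speakval."""


class SpeakvalError(Exception):
    """Base class for all speakval errors."""


class MissingPredictorError(SpeakvalError):
    """A record lacks a value required by a model term.

    Carries the offending predictor id so callers can report which
    baseline variable must be imputed upstream.
    """

    def __init__(self, predictor_id: str, detail: str = ""):
        self.predictor_id = predictor_id
        msg = f"missing value for required predictor {predictor_id!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class UnknownPredictorError(SpeakvalError):
    """A model specification names a predictor with no known coding."""

    def __init__(self, predictor_id: str):
        self.predictor_id = predictor_id
        super().__init__(
            f"unknown predictor id {predictor_id!r} in model specification"
        )


class CohortError(SpeakvalError):
    """Invalid cohort table: missing columns, out-of-range values, empty."""


class ConvergenceError(SpeakvalError):
    """A maximum-likelihood fit failed to converge."""


class SeparationError(ConvergenceError):
    """Complete or quasi-complete separation: the MLE does not exist."""
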