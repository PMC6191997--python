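"""scikit-learn-style estimators wrapping the prognostic model and recalibration.

:class:`PrognosticModel` is a frozen, pre-specified classifier: ``fit`` only
resolves and validates the model configuration (no parameters are learned —
using a published prognostic model on new patients means *not* refitting it).
It composes with sklearn model selection and pipelines operating on cohort
DataFrames.

:class:`LogisticRecalibrator` is the fit-shaped half: it learns the
calibration parameters (alpha, beta) of an existing model on new data and
produces an updated model specification.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import recalibrate as _recal
from ._logistic import fit_intercept_slope, fit_offset_intercept
from .model import (
    ModelSpecification,
    PROB_CLIP,
    linear_predictor_frame,
    load_model,
    load_packaged_model,
)

__all__ = ["LogisticRecalibrator", "PrognosticModel"]


def _resolve_spec(spec) -> ModelSpecification:
    if isinstance(spec, ModelSpecification):
        return spec
    if isinstance(spec, str) and spec.lower().replace("-", "") in ("speak12", "speak6"):
        return load_packaged_model(spec)
    return load_model(spec)


class PrognosticModel(ClassifierMixin, BaseEstimator):
    """A pre-specified logistic prognostic model as a sklearn classifier.

    Parameters
    ----------
    spec : ModelSpecification, path, or {"speak12", "speak6"}
        The model configuration.  Packaged names load the synthetic
        stand-in configurations.

    ``X`` is a cohort DataFrame (one row per patient with the baseline
    predictor columns); ``y`` is ignored by :meth:`fit`.
    ``decision_function`` returns the linear predictor,
    ``predict_proba`` the probability of each class in ``classes_``
    (["good", "poor"]), ``predict`` the dichotomized label.
    """

    def __init__(self, spec="speak12"):
        self.spec = spec

    def fit(self, X=None, y=None):
        self.spec_ = _resolve_spec(self.spec)
        self.classes_ = np.array(["good", "poor"])
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "spec_")
        return linear_predictor_frame(self.spec_, X)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p_good = np.clip(expit(self.decision_function(X)), PROB_CLIP, 1 - PROB_CLIP)
        return np.column_stack([p_good, 1.0 - p_good])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        p = self.predict_proba(X)[:, 0]
        return np.where(p >= 0.5, "good", "poor")


class LogisticRecalibrator(BaseEstimator):
    """Learn calibration parameters of a model's linear predictor on new data.

    Parameters
    ----------
    method : {"intercept", "intercept_slope"}
        ``intercept`` fits only calibration-in-the-large (offset model,
        slope pinned to 1); ``intercept_slope`` fits the two-parameter
        recalibration.

    Attributes
    ----------
    alpha_ : float
        Calibration-in-the-large (offset-model intercept).
    beta_ : float
        Calibration slope (1.0 by definition for ``method="intercept"``).
    slope_model_intercept_ : float or None
        Intercept of the two-parameter fit (None for the offset method).
    """

    def __init__(self, method: str = "intercept"):
        self.method = method

    def fit(self, linear_predictors, outcomes):
        y = np.asarray(linear_predictors, dtype=float).ravel()
        out = np.asarray(outcomes)
        if out.dtype.kind in "USO":
            out = (out == "good").astype(int)
        if self.method == "intercept":
            self.alpha_ = fit_offset_intercept(y, out)
            self.beta_ = 1.0
            self.slope_model_intercept_ = None
        elif self.method == "intercept_slope":
            a, b = fit_intercept_slope(y, out)
            self.slope_model_intercept_ = a
            self.alpha_ = fit_offset_intercept(y, out)
            self.beta_ = b
        else:
            raise ValueError(f"unknown recalibration method {self.method!r}")
        self.n_samples_ = int(out.size)
        return self

    def update_spec(
        self,
        spec: ModelSpecification,
        linear_predictors,
        outcomes,
        new_horizon_months: Optional[int] = None,
        name: Optional[str] = None,
    ) -> ModelSpecification:
        """Produce the updated model specification on the supplied data."""
        if self.method == "intercept":
            return _recal.update_intercept(
                spec, linear_predictors, outcomes,
                new_horizon_months=new_horizon_months, name=name,
            )
        return _recal.update_intercept_and_slope(
            spec, linear_predictors, outcomes,
            new_horizon_months=new_horizon_months, name=name,
        )
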