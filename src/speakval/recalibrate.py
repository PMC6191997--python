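"""Model updating: intercept recalibration and intercept+slope recalibration.

The intercept update re-estimates calibration-in-the-large on new data and
folds it into the model's intercept, leaving every coefficient untouched —
the minimal update used to move a model to a new setting or outcome horizon
(e.g. a 12-month model re-aimed at 6 months).  Re-validating the updated
model on the same data gives alpha = 0 exactly (an MLE fixed point), and the
c-index is unchanged because adding a constant to every linear predictor is
a monotone transform.

The intercept+slope update applies the two-parameter recalibration
``y' = a + beta * y``: the intercept becomes ``a + beta * intercept`` and
every coefficient is scaled by ``beta``.  For ``beta > 0`` the ranking of
patients (and hence the c-index) is preserved; refitting on the same data
returns (0, 1).

``shift_intercept`` applies an explicit, externally supplied intercept delta
so a published updated model can be reproduced verbatim even when its
update data are not available.
"""

from __future__ import annotations

import hashlib
from datetime import datetime, timezone
from typing import Optional

import numpy as np

from .metrics import calibration_in_the_large, calibration_slope
from .model import ModelSpecification, ModelTerm

__all__ = ["shift_intercept", "update_intercept", "update_intercept_and_slope"]


def _data_hash(linear_predictors, outcomes) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(linear_predictors, dtype=float).tobytes())
    h.update(np.ascontiguousarray(outcomes, dtype=float).tobytes())
    return h.hexdigest()[:16]


def _updated(
    spec: ModelSpecification,
    *,
    intercept: float,
    scale: float,
    name: Optional[str],
    new_horizon_months: Optional[int],
    provenance: dict,
) -> ModelSpecification:
    terms = [
        ModelTerm(
            predictor_id=t.predictor_id,
            coefficient=t.coefficient * scale,
            center=t.center,
        )
        for t in spec.terms
    ]
    metadata = dict(spec.metadata)
    metadata["recalibration"] = provenance
    return ModelSpecification(
        name=name if name is not None else f"{spec.name}-updated",
        outcome_horizon_months=(
            new_horizon_months
            if new_horizon_months is not None
            else spec.outcome_horizon_months
        ),
        intercept=intercept,
        terms=terms,
        metadata=metadata,
    )


def update_intercept(
    spec: ModelSpecification,
    linear_predictors,
    outcomes,
    new_horizon_months: Optional[int] = None,
    name: Optional[str] = None,
) -> ModelSpecification:
    """Recalibrate the intercept on new data; coefficients unchanged.

    ``linear_predictors`` must be the values of ``spec``'s linear predictor
    on the update data.  The returned model has
    ``intercept' = intercept + alpha_hat`` with ``alpha_hat`` the
    offset-model calibration-in-the-large on the supplied data.
    """
    alpha_hat = calibration_in_the_large(linear_predictors, outcomes)
    provenance = {
        "update": "intercept",
        "parent": spec.name,
        "alpha_hat": alpha_hat,
        "beta_hat": None,
        "data_hash": _data_hash(linear_predictors, outcomes),
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    return _updated(
        spec,
        intercept=spec.intercept + alpha_hat,
        scale=1.0,
        name=name,
        new_horizon_months=new_horizon_months,
        provenance=provenance,
    )


def update_intercept_and_slope(
    spec: ModelSpecification,
    linear_predictors,
    outcomes,
    new_horizon_months: Optional[int] = None,
    name: Optional[str] = None,
) -> ModelSpecification:
    """Two-parameter recalibration: rescale coefficients, reset intercept.

    With ``(a, beta)`` from the two-parameter fit on the supplied data, the
    updated model has ``intercept' = a + beta * intercept`` and every
    coefficient multiplied by ``beta``.
    """
    a, beta = calibration_slope(linear_predictors, outcomes)
    provenance = {
        "update": "intercept_and_slope",
        "parent": spec.name,
        "alpha_hat": a,
        "beta_hat": beta,
        "data_hash": _data_hash(linear_predictors, outcomes),
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    return _updated(
        spec,
        intercept=a + beta * spec.intercept,
        scale=beta,
        name=name,
        new_horizon_months=new_horizon_months,
        provenance=provenance,
    )


def shift_intercept(
    spec: ModelSpecification,
    delta: float,
    new_horizon_months: Optional[int] = None,
    name: Optional[str] = None,
) -> ModelSpecification:
    """Apply an explicit intercept shift (e.g. from a published update)."""
    provenance = {
        "update": "explicit_intercept_shift",
        "parent": spec.name,
        "delta": float(delta),
        "alpha_hat": None,
        "beta_hat": None,
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    return _updated(
        spec,
        intercept=spec.intercept + float(delta),
        scale=1.0,
        name=name,
        new_horizon_months=new_horizon_months,
        provenance=provenance,
    )
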