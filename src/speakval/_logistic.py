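"""Maximum-likelihood logistic fits used by the calibration metrics.

Two fits are needed:

* the *offset* model ``logit P(good) = alpha + y`` with the linear predictor
  ``y`` entered as a fixed offset (slope pinned to 1) — a one-parameter
  problem whose score function is strictly decreasing in ``alpha``, so the
  MLE is found exactly by bracketed root-finding;
* the *slope* model ``logit P(good) = a + b * y`` with two free parameters,
  fitted by Newton's method via statsmodels, with separation detection and a
  score-equation check layered on top.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import ConvergenceError, SeparationError

__all__ = ["fit_offset_intercept", "fit_intercept_slope", "check_two_classes"]

_GRAD_TOL = 1e-6
_PARAM_BOUND = 50.0  # |parameter| beyond this on standardized data => separation


def check_two_classes(outcomes: np.ndarray) -> None:
    """Raise if the 0/1 outcome vector does not contain both classes."""
    outcomes = np.asarray(outcomes)
    if outcomes.size < 2 or outcomes.min() == outcomes.max():
        raise ValueError(
            "both outcome classes (good and poor) must be present; "
            "calibration and discrimination are undefined otherwise"
        )


def fit_offset_intercept(offset: np.ndarray, outcomes: np.ndarray) -> float:
    """MLE intercept alpha of ``logit P = alpha + offset`` (slope fixed at 1).

    The score ``sum(outcomes) - sum(expit(alpha + offset))`` is strictly
    decreasing in alpha with limits +sum(outcomes) and sum(outcomes) - n, so
    with both classes present a unique root exists; Brent's method finds it
    to near machine precision.  This model cannot separate.
    """
    offset = np.asarray(offset, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("linear predictors must be finite")
    check_two_classes(outcomes)

    total = outcomes.sum()

    def score(alpha: float) -> float:
        return total - expit(alpha + offset).sum()

    lo, hi = -40.0, 40.0
    while score(lo) <= 0:
        lo *= 2
        if lo < -1e6:  # pragma: no cover - unreachable with finite offsets
            raise ConvergenceError("offset-model score has no sign change")
    while score(hi) >= 0:
        hi *= 2
        if hi > 1e6:  # pragma: no cover
            raise ConvergenceError("offset-model score has no sign change")
    alpha = brentq(score, lo, hi, xtol=1e-12, rtol=8.9e-16)
    if abs(score(alpha)) > _GRAD_TOL * max(1.0, outcomes.size / 1000.0):
        raise ConvergenceError("offset-model score not zero at solution")
    return float(alpha)


def fit_intercept_slope(
    linear_predictors: np.ndarray, outcomes: np.ndarray
) -> tuple[float, float]:
    """MLE (a, b) of the two-parameter fit ``logit P = a + b * y``.

    Raises :class:`SeparationError` on complete or quasi-complete separation
    (the MLE diverges) and :class:`ConvergenceError` when Newton iterations
    fail or the score equations are not satisfied at the solution.
    """
    y = np.asarray(linear_predictors, dtype=float)
    out = np.asarray(outcomes, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("linear predictors must be finite")
    check_two_classes(out)
    if np.ptp(y) == 0:
        raise ValueError(
            "linear predictors are all equal; the calibration slope is unidentified"
        )

    X = sm.add_constant(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(out, X).fit(disp=0, method="newton", maxiter=100, tol=1e-10)
        except Exception as exc:  # statsmodels raises on perfect separation
            if "separation" in str(exc).lower() or "Singular" in str(exc):
                raise SeparationError(
                    "complete separation: the slope-model MLE does not exist"
                ) from exc
            raise ConvergenceError(str(exc)) from exc

    params = np.asarray(res.params, dtype=float)
    fitted = expit(X @ params)
    # quasi-separation: runaway parameters or all fitted probs saturated
    scale = max(1.0, float(np.std(y)))
    if np.abs(params[1]) * scale > _PARAM_BOUND or np.abs(params[0]) > _PARAM_BOUND * 4:
        raise SeparationError(
            "quasi-complete separation: slope-model parameters diverged"
        )
    if np.all(np.abs(fitted - out) < 1e-10):
        raise SeparationError("complete separation: model fits outcomes exactly")

    grad = X.T @ (out - fitted)
    if np.max(np.abs(grad)) > _GRAD_TOL * max(1.0, out.size / 1000.0):
        raise ConvergenceError(
            f"slope-model score not zero at solution (max |score| = "
            f"{np.max(np.abs(grad)):.3g})"
        )
    return float(params[0]), float(params[1])
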