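"""Discrimination and calibration of probabilistic predictions.

Discrimination is the concordance statistic (c-index): for a binary outcome
with no censoring this is exactly the Mann-Whitney AUC — the probability that
a randomly chosen good-outcome patient received a higher prediction than a
randomly chosen poor-outcome patient, ties counted half.  Its confidence
interval comes from the DeLong covariance (default) or a seeded percentile
bootstrap.

Calibration is summarized by two logistic refits of the outcome on the
model's linear predictor y:

* calibration-in-the-large ``alpha``: intercept of ``logit P = alpha + y``
  with y a fixed offset (slope pinned to 1); 0 under perfect average
  calibration, negative when the model overestimates the probability of a
  good outcome;
* calibration slope ``beta``: slope of the two-parameter fit
  ``logit P = a + beta * y``; 1 under perfect calibration, below 1 when the
  predictor effects are weaker in the validation data.

A calibration plot groups patients into k (default 5) equally large groups
by ascending predicted probability and plots observed proportions against
group-mean predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from ._logistic import check_two_classes, fit_intercept_slope, fit_offset_intercept
from .exceptions import CohortError
from .model import ModelSpecification, PROB_CLIP, linear_predictor_frame

__all__ = [
    "CalibrationParameters",
    "RiskGroup",
    "ValidationResult",
    "calibration_groups",
    "calibration_in_the_large",
    "calibration_slope",
    "concordance",
    "concordance_ci",
    "external_validation",
    "plot_calibration",
    "risk_groups_to_tsv",
]


@dataclass(frozen=True)
class CalibrationParameters:
    """(alpha, beta) — estimands of calibration, or simulation truth.

    Perfect calibration is alpha = 0, beta = 1.
    """

    alpha: float
    beta: float

    @property
    def is_perfect(self) -> bool:
        return self.alpha == 0.0 and self.beta == 1.0


@dataclass(frozen=True)
class RiskGroup:
    """One predicted-risk group of a calibration plot."""

    n: int
    mean_predicted: float
    observed_proportion: float


@dataclass
class ValidationResult:
    """External-validation summary: discrimination + calibration."""

    c_index: float
    c_index_ci: tuple[float, float]
    calibration: CalibrationParameters
    slope_model_intercept: float
    mean_predicted: float
    observed_proportion: float
    risk_groups: list[RiskGroup]
    n: int
    ci_method: str = "analytic_delong"
    ci_level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "c_index": self.c_index,
            "c_index_ci": list(self.c_index_ci),
            "ci_method": self.ci_method,
            "ci_level": self.ci_level,
            "calibration_in_the_large": self.calibration.alpha,
            "calibration_slope": self.calibration.beta,
            "slope_model_intercept": self.slope_model_intercept,
            "mean_predicted": self.mean_predicted,
            "observed_proportion": self.observed_proportion,
            "risk_groups": [
                {
                    "n": g.n,
                    "mean_predicted": g.mean_predicted,
                    "observed_proportion": g.observed_proportion,
                }
                for g in self.risk_groups
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

def _as_pred_out(predictions, outcomes) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(predictions, dtype=float)
    out = np.asarray(outcomes)
    if out.dtype.kind in "USO":
        out = (out == "good").astype(int)
    out = out.astype(int)
    if pred.shape != out.shape or pred.ndim != 1:
        raise ValueError("predictions and outcomes must be 1-D of equal length")
    if not np.all((out == 0) | (out == 1)):
        raise ValueError("outcomes must be binary (0/1 or 'good'/'poor')")
    return pred, out


def concordance(predictions, outcomes) -> float:
    """c-index: fraction of (good, poor) pairs ranked correctly, ties 0.5.

    Computed with midranks (Mann-Whitney), identical to exhaustive pair
    enumeration.  Requires both outcome classes.
    """
    pred, out = _as_pred_out(predictions, outcomes)
    check_two_classes(out)
    n_pos = int(out.sum())
    n_neg = out.size - n_pos
    ranks = stats.rankdata(pred)  # average ranks handle ties as 1/2
    auc = (ranks[out == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def _delong_components(pred, out):
    """Per-observation structural components V10 (cases), V01 (controls)."""
    pos = pred[out == 1]
    neg = pred[out == 0]
    m, n = pos.size, neg.size
    # midranks within combined and within each class (Sun & Xu algorithm)
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return v10, v01


def _delong_se(pred, out) -> float:
    v10, v01 = _delong_components(pred, out)
    m, n = v10.size, v01.size
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    return float(np.sqrt(var))


def concordance_ci(
    predictions,
    outcomes,
    method: str = "analytic_delong",
    level: float = 0.95,
    seed: Optional[int] = None,
    n_boot: int = 2000,
) -> tuple[float, float]:
    """Confidence interval for the c-index.

    ``analytic_delong`` uses the DeLong variance of the Mann-Whitney
    statistic (degenerate at the point estimate under perfect separation);
    ``bootstrap`` draws ``n_boot`` seeded case-resamples and takes
    percentile bounds.  The interval always contains the point estimate and
    is clipped to [0, 1].
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    pred, out = _as_pred_out(predictions, outcomes)
    check_two_classes(out)
    theta = concordance(pred, out)

    if method == "analytic_delong":
        se = _delong_se(pred, out)
        z = stats.norm.ppf(0.5 + level / 2.0)
        lo, hi = theta - z * se, theta + z * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = pred.size
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            while True:
                idx = rng.integers(0, n, n)
                ob = out[idx]
                if 0 < ob.sum() < n:
                    break
            aucs[b] = concordance(pred[idx], ob)
        tail = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(aucs, [tail, 100.0 - tail])
    else:
        raise ValueError(f"unknown CI method {method!r}")

    lo = min(float(lo), theta)
    hi = max(float(hi), theta)
    return (max(lo, 0.0), min(hi, 1.0))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibration_in_the_large(linear_predictors, outcomes) -> float:
    """MLE alpha of ``logit P(good) = alpha + y`` with y a fixed offset."""
    _, out = _as_pred_out(linear_predictors, outcomes)
    return fit_offset_intercept(np.asarray(linear_predictors, dtype=float), out)


def calibration_slope(linear_predictors, outcomes) -> tuple[float, float]:
    """MLE (a, beta) of the two-parameter fit ``logit P(good) = a + beta*y``."""
    _, out = _as_pred_out(linear_predictors, outcomes)
    return fit_intercept_slope(np.asarray(linear_predictors, dtype=float), out)


def calibration_groups(predictions, outcomes, k: int = 5) -> list[RiskGroup]:
    """Split patients into k equally large predicted-risk groups.

    Stable ascending sort by prediction; with remainder ``r = n mod k`` the
    r lowest-probability groups receive one extra member.  Per group:
    mean predicted probability and observed good-outcome proportion.
    """
    pred, out = _as_pred_out(predictions, outcomes)
    n = pred.size
    if k < 2:
        raise ValueError("need at least 2 risk groups")
    if n < k:
        raise ValueError(f"cannot form {k} groups from {n} observations")
    order = np.argsort(pred, kind="stable")
    base, r = divmod(n, k)
    sizes = [base + 1] * r + [base] * (k - r)
    groups = []
    start = 0
    for size in sizes:
        idx = order[start : start + size]
        groups.append(
            RiskGroup(
                n=size,
                mean_predicted=float(pred[idx].mean()),
                observed_proportion=float(out[idx].mean()),
            )
        )
        start += size
    return groups


# ---------------------------------------------------------------------------
# Composite external validation
# ---------------------------------------------------------------------------

def external_validation(
    spec: ModelSpecification,
    cohort,
    k: int = 5,
    ci_method: str = "analytic_delong",
    level: float = 0.95,
    seed: Optional[int] = None,
) -> ValidationResult:
    """Full external validation of a model on an analysis cohort.

    ``cohort`` is an :class:`speakval.cohort.AnalysisCohort` (records free of
    missing predictors, outcomes resolved).  Deterministic given ``seed``.
    """
    records = cohort.records
    if len(records) == 0:
        raise CohortError("empty analysis cohort")
    y = linear_predictor_frame(spec, records)
    p = np.clip(expit(y), PROB_CLIP, 1.0 - PROB_CLIP)
    out = cohort.outcome_array()
    check_two_classes(out)

    c = concordance(p, out)
    ci = concordance_ci(p, out, method=ci_method, level=level, seed=seed)
    alpha = calibration_in_the_large(y, out)
    a, beta = calibration_slope(y, out)
    groups = calibration_groups(p, out, k=k)

    return ValidationResult(
        c_index=c,
        c_index_ci=ci,
        calibration=CalibrationParameters(alpha=alpha, beta=beta),
        slope_model_intercept=a,
        mean_predicted=float(p.mean()),
        observed_proportion=float(out.mean()),
        risk_groups=groups,
        n=int(out.size),
        ci_method=ci_method,
        ci_level=level,
    )


def risk_groups_to_tsv(groups: Sequence[RiskGroup]) -> str:
    """Risk groups as TSV (n, mean_predicted, observed_proportion)."""
    lines = ["n\tmean_predicted\tobserved_proportion"]
    for g in groups:
        lines.append(f"{g.n}\t{g.mean_predicted:.6g}\t{g.observed_proportion:.6g}")
    return "\n".join(lines) + "\n"


def plot_calibration(result: ValidationResult, path, title: Optional[str] = None):
    """Write a calibration plot (observed vs mean predicted, with diagonal)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 1], [0, 1], color="grey", lw=1, label="perfect calibration")
    xs = [g.mean_predicted for g in result.risk_groups]
    ys = [g.observed_proportion for g in result.risk_groups]
    ax.plot(xs, ys, "o-", color="black", label="risk groups")
    ax.set_xlabel("mean predicted probability of good outcome")
    ax.set_ylabel("observed proportion of good outcome")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend(loc="upper left", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
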