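"""Cohort pipeline: reading, outcome resolution, imputation, exclusions, summaries.

Mirrors how a validation cohort is prepared in practice:

1. read the patient-level table;
2. drop ineligible patients (post-hoc protocol exclusions);
3. resolve each patient's outcome — the 6-month ASRS when available, the
   3-month ASRS *carried back* when not, exclusion when both are missing;
4. simply impute remaining missing baseline predictors (mode for
   categorical, mean for continuous — the mean rounded half-up on
   integer-valued scales);
5. summarize baselines in the conventional Table-style layout.

The outcome itself is never mode/mean imputed; only the carry-back rule
applies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .exceptions import CohortError
from .model import STROKE_TYPES, PatientRecord, classify_outcome

__all__ = [
    "COLUMNS",
    "AnalysisCohort",
    "ExclusionReport",
    "OutcomeLabel",
    "baseline_summary",
    "build_analysis_cohort",
    "frame_to_records",
    "impute_baseline",
    "read_cohort",
    "records_to_frame",
    "resolve_outcome",
    "summary_to_tsv",
    "write_cohort",
]

COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "education_level",
    "stroke_type",
    "barthel_index",
    "screeling_phonology",
    "asrs_baseline",
    "asrs_3mo",
    "asrs_6mo",
    "eligible",
]

_NUMERIC_RANGES = {
    "age_years": (0.0, 120.0, False),
    "barthel_index": (0.0, 20.0, True),
    "screeling_phonology": (0.0, 24.0, False),
    "asrs_baseline": (0.0, 5.0, True),
    "asrs_3mo": (0.0, 5.0, True),
    "asrs_6mo": (0.0, 5.0, True),
}

_CATEGORY_LEVELS = {
    "sex": ("female", "male"),
    "education_level": ("high", "low"),
    "stroke_type": STROKE_TYPES,
}

#: Canonical category order used to break mode ties deterministically.
CANONICAL_ORDER = {
    "education_level": ("low", "high"),
    "stroke_type": STROKE_TYPES,
    "sex": ("female", "male"),
}

_CATEGORICAL_FIELDS = ("sex", "education_level", "stroke_type")
_REAL_FIELDS = ("age_years", "screeling_phonology")
_INTEGER_FIELDS = ("barthel_index", "asrs_baseline")


@dataclass(frozen=True)
class OutcomeLabel:
    """Dichotomized outcome for one analyzed patient and its provenance."""

    patient_id: str
    label: Literal["good", "poor"]
    source: Literal["six_month", "three_month_carried_back"]


@dataclass(frozen=True)
class ExclusionReport:
    """Patient-flow bookkeeping from enrolment to the analysis set."""

    n_enrolled: int
    n_ineligible: int
    n_missing_6mo: int
    n_carried_back_3mo: int
    n_excluded_no_outcome: int
    n_analyzed: int

    def __post_init__(self):
        if self.n_analyzed != self.n_enrolled - self.n_ineligible - self.n_excluded_no_outcome:
            raise ValueError("flow identity violated: analyzed != enrolled - ineligible - excluded")
        if self.n_excluded_no_outcome != self.n_missing_6mo - self.n_carried_back_3mo:
            raise ValueError("flow identity violated: excluded != missing 6mo - carried back")

    def to_dict(self) -> dict:
        return {
            "n_enrolled": self.n_enrolled,
            "n_ineligible": self.n_ineligible,
            "n_missing_6mo": self.n_missing_6mo,
            "n_carried_back_3mo": self.n_carried_back_3mo,
            "n_excluded_no_outcome": self.n_excluded_no_outcome,
            "n_analyzed": self.n_analyzed,
        }


@dataclass
class AnalysisCohort:
    """Post-imputation analysis set: records, outcomes, log, flow report."""

    records: pd.DataFrame
    outcomes: list[OutcomeLabel]
    imputation_log: list[dict] = field(default_factory=list)
    report: Optional[ExclusionReport] = None

    def outcome_array(self) -> np.ndarray:
        """Outcomes as 0/1 (1 = good), aligned with ``records`` rows."""
        return np.array([1 if o.label == "good" else 0 for o in self.outcomes])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV into a typed DataFrame.

    Missing values are empty cells or ``NA``.  Raises :class:`CohortError`
    naming the first missing mandatory column, or the offending data row
    (1-based, excluding the header) for out-of-range values.
    """
    df = pd.read_csv(
        path, dtype=str, na_values=["", "NA"], keep_default_na=False,
        skipinitialspace=True,
    )
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortError(f"cohort file lacks mandatory column(s): {missing_cols}")
    return _coerce_frame(df[COLUMNS].copy())


def _coerce_frame(df: pd.DataFrame) -> pd.DataFrame:
    df["patient_id"] = df["patient_id"].astype(str)
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise CohortError(f"duplicate patient_id {dup!r}")
    for col, (lo, hi, integer) in _NUMERIC_RANGES.items():
        try:
            vals = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise CohortError(f"column {col!r} is not numeric: {exc}") from exc
        vals = vals.astype(float)
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        if integer:
            bad |= vals.notna() & (vals != np.floor(vals))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise CohortError(
                f"out-of-range value {df[col][bad.to_numpy()].iloc[0]!r} in column "
                f"{col!r} at data row {row}"
            )
        df[col] = vals
    for col, levels in _CATEGORY_LEVELS.items():
        vals = df[col].where(df[col].notna(), None)
        bad = vals.notna() & ~vals.isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise CohortError(
                f"invalid value {vals[bad.to_numpy()].iloc[0]!r} in column {col!r} "
                f"at data row {row}; allowed: {levels}"
            )
        df[col] = vals.astype(object).where(vals.notna(), np.nan)
    raw = df["eligible"]
    if raw.dtype == object:
        mapping = {"true": True, "false": False, "1": True, "0": False,
                   "yes": True, "no": False}
        parsed = raw.astype(str).str.strip().str.lower().map(mapping)
        parsed = parsed.where(raw.notna(), True)  # missing => eligible
        if parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna().to_numpy())[0]) + 1
            raise CohortError(f"invalid boolean in column 'eligible' at data row {row}")
        df["eligible"] = parsed.astype(bool)
    else:
        df["eligible"] = raw.fillna(True).astype(bool)
    return df.reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort DataFrame in the CSV dialect ``read_cohort`` accepts."""
    out = df[COLUMNS].copy()
    for col, (_, _, integer) in _NUMERIC_RANGES.items():
        if integer:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else str(int(v))
            )
    out.to_csv(path, index=False, na_rep="")


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Convert a list of PatientRecord to the canonical cohort DataFrame."""
    rows = [r.model_dump() for r in records]
    df = pd.DataFrame(rows, columns=COLUMNS)
    for col in _NUMERIC_RANGES:
        df[col] = pd.to_numeric(df[col]).astype(float)
    df["eligible"] = df["eligible"].astype(bool)
    return df


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Convert a cohort DataFrame to validated PatientRecord objects."""
    records = []
    for _, row in df.iterrows():
        d = row.to_dict()
        for k, v in list(d.items()):
            if isinstance(v, float) and math.isnan(v):
                d[k] = None
        for k in ("barthel_index", "asrs_baseline", "asrs_3mo", "asrs_6mo"):
            if d[k] is not None:
                d[k] = int(d[k])
        records.append(PatientRecord(**d))
    return records


# ---------------------------------------------------------------------------
# Outcome resolution (carry-back rule)
# ---------------------------------------------------------------------------

def resolve_outcome(record) -> Optional[OutcomeLabel]:
    """Resolve one patient's dichotomous outcome.

    Uses the 6-month ASRS when present; otherwise the 3-month ASRS, flagged
    ``three_month_carried_back``; returns ``None`` (the exclusion signal)
    when both are missing.
    """
    if isinstance(record, PatientRecord):
        pid, a6, a3 = record.patient_id, record.asrs_6mo, record.asrs_3mo
    else:
        d = record if isinstance(record, dict) else record.to_dict()
        pid, a6, a3 = d["patient_id"], d["asrs_6mo"], d["asrs_3mo"]

    def _present(v):
        return v is not None and not (isinstance(v, float) and math.isnan(v))

    if _present(a6):
        return OutcomeLabel(str(pid), classify_outcome(a6), "six_month")
    if _present(a3):
        return OutcomeLabel(str(pid), classify_outcome(a3), "three_month_carried_back")
    return None


# ---------------------------------------------------------------------------
# Simple imputation
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def impute_baseline(df: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Simple imputation of missing baseline predictors.

    Mode for categorical/binary fields (ties broken by the canonical order
    in :data:`CANONICAL_ORDER` and logged); arithmetic mean for continuous
    fields, rounded half-up on integer-valued scales (Barthel, ASRS).
    Observed values are never touched; outcome columns are never imputed.
    Idempotent: re-running on the output is a no-op.
    """
    out = df.copy()
    log: list[dict] = []

    for fieldname in _CATEGORICAL_FIELDS:
        mask = out[fieldname].isna()
        if not mask.any():
            continue
        observed = out.loc[~mask, fieldname]
        if observed.empty:
            raise CohortError(f"cannot impute {fieldname!r}: no observed values")
        counts = observed.value_counts()
        top = counts.max()
        tied = sorted(counts[counts == top].index)
        if len(tied) > 1:
            order = CANONICAL_ORDER[fieldname]
            value = min(tied, key=lambda v: order.index(v))
            warnings.warn(
                f"mode tie for {fieldname!r} among {tied}; choosing {value!r} "
                "by canonical order",
                stacklevel=2,
            )
        else:
            value = tied[0]
        for pid in out.loc[mask, "patient_id"]:
            log.append({"patient_id": pid, "field": fieldname, "imputed_value": value})
        out.loc[mask, fieldname] = value

    for fieldname in _REAL_FIELDS + _INTEGER_FIELDS:
        mask = out[fieldname].isna()
        if not mask.any():
            continue
        observed = out.loc[~mask, fieldname]
        if observed.empty:
            raise CohortError(f"cannot impute {fieldname!r}: no observed values")
        mean = float(observed.mean())
        value: float = float(_round_half_up(mean)) if fieldname in _INTEGER_FIELDS else mean
        for pid in out.loc[mask, "patient_id"]:
            log.append({"patient_id": pid, "field": fieldname, "imputed_value": value})
        out.loc[mask, fieldname] = value

    return out, log


# ---------------------------------------------------------------------------
# Analysis-cohort assembly
# ---------------------------------------------------------------------------

def build_analysis_cohort(df: pd.DataFrame) -> AnalysisCohort:
    """Enrolled table -> analysis set: exclusions, carry-back, imputation.

    Deterministic.  Raises :class:`CohortError` on an empty table or when
    every eligible patient lacks an outcome.
    """
    if len(df) == 0:
        raise CohortError("empty cohort")
    n_enrolled = len(df)
    eligible = df[df["eligible"].astype(bool)]
    n_ineligible = n_enrolled - len(eligible)

    missing6 = eligible["asrs_6mo"].isna()
    carried = missing6 & eligible["asrs_3mo"].notna()
    no_outcome = missing6 & eligible["asrs_3mo"].isna()

    analyzed = eligible[~no_outcome].copy()
    if len(analyzed) == 0:
        raise CohortError("no patient has any outcome data; nothing to analyze")

    outcomes = []
    for _, row in analyzed.iterrows():
        label = resolve_outcome(row)
        assert label is not None
        outcomes.append(label)

    imputed, log = impute_baseline(analyzed.reset_index(drop=True))

    report = ExclusionReport(
        n_enrolled=n_enrolled,
        n_ineligible=n_ineligible,
        n_missing_6mo=int(missing6.sum()),
        n_carried_back_3mo=int(carried.sum()),
        n_excluded_no_outcome=int(no_outcome.sum()),
        n_analyzed=len(analyzed),
    )
    return AnalysisCohort(records=imputed, outcomes=outcomes,
                          imputation_log=log, report=report)


# ---------------------------------------------------------------------------
# Baseline summary (Table-style)
# ---------------------------------------------------------------------------

def _pct(count: int, n: int) -> int:
    return int(math.floor(100.0 * count / n + 0.5))


def _counts_block(series: pd.Series, levels, n: int) -> dict:
    counts = {lvl: int((series == lvl).sum()) for lvl in levels}
    return {
        "counts": counts,
        "percent": {lvl: _pct(c, n) for lvl, c in counts.items()},
        "n_missing": int(series.isna().sum()),
    }


def baseline_summary(df: pd.DataFrame) -> dict:
    """Summarize baseline variables the way validation cohorts are tabled.

    Mean (SD) for age and ScreeLing Phonology; median (IQR) for the Barthel
    Index; counts with integer-rounded percentages for sex, education,
    stroke type and baseline ASRS.  Missing values are counted, not imputed.
    A single-record group reports SD 0 with a warning.
    """
    if len(df) == 0:
        raise CohortError("cannot summarize an empty cohort")
    n = len(df)
    summary: dict = {"n": n}

    for col in ("age_years", "screeling_phonology"):
        obs = df[col].dropna()
        if len(obs) == 1:
            warnings.warn(f"SD of a single observation for {col!r} reported as 0",
                          stacklevel=2)
            sd = 0.0
        else:
            sd = float(obs.std(ddof=1))
        summary[col] = {
            "mean": float(obs.mean()), "sd": sd, "n_missing": int(df[col].isna().sum())
        }

    obs = df["barthel_index"].dropna()
    summary["barthel_index"] = {
        "median": float(obs.median()),
        "iqr": [float(obs.quantile(0.25)), float(obs.quantile(0.75))],
        "n_missing": int(df["barthel_index"].isna().sum()),
    }

    summary["sex"] = _counts_block(df["sex"], ("female", "male"), n)
    summary["education_level"] = _counts_block(df["education_level"], ("high", "low"), n)
    summary["stroke_type"] = _counts_block(df["stroke_type"], STROKE_TYPES, n)
    summary["asrs_baseline"] = _counts_block(df["asrs_baseline"], range(6), n)
    summary["asrs_baseline"]["counts"] = {
        str(k): v for k, v in summary["asrs_baseline"]["counts"].items()
    }
    summary["asrs_baseline"]["percent"] = {
        str(k): v for k, v in summary["asrs_baseline"]["percent"].items()
    }
    return summary


def summary_to_tsv(summary: dict) -> str:
    """Flatten a baseline summary to TSV (variable, statistic, value)."""
    lines = ["variable\tstatistic\tvalue"]

    def emit(var, stat, value):
        lines.append(f"{var}\t{stat}\t{value}")

    emit("cohort", "n", summary["n"])
    for col in ("age_years", "screeling_phonology"):
        emit(col, "mean", f"{summary[col]['mean']:.6g}")
        emit(col, "sd", f"{summary[col]['sd']:.6g}")
        emit(col, "n_missing", summary[col]["n_missing"])
    b = summary["barthel_index"]
    emit("barthel_index", "median", f"{b['median']:.6g}")
    emit("barthel_index", "iqr", f"{b['iqr'][0]:.6g}-{b['iqr'][1]:.6g}")
    emit("barthel_index", "n_missing", b["n_missing"])
    for col in ("sex", "education_level", "stroke_type", "asrs_baseline"):
        block = summary[col]
        for lvl, c in block["counts"].items():
            emit(col, f"n[{lvl}]", f"{c} ({block['percent'][lvl]}%)")
        emit(col, "n_missing", block["n_missing"])
    return "\n".join(lines) + "\n"
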