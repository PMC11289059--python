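"""Data-cleaning rules for PRT trial tables.

Pipeline order is fixed: participant exclusion first, then the RT window
filter; variance-stabilising transforms and winsorization act downstream on
derived quantities.  Surviving values are never modified — rows are removed
or (for winsorization) replaced by fences, exactly as specified.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats.mstats import winsorize as _percentile_winsorize

__all__ = [
    "ExclusionReport",
    "FilterReport",
    "SchemaError",
    "exclude_participants",
    "filter_rts",
    "transform_rt",
    "transform_accuracy",
    "winsorize",
    "preprocess",
]

ACCURACY_MIN = 0.5
SINGLE_BUTTON_MAX = 0.75
RT_LO = 0.250
RT_HI = 2.500


class SchemaError(ValueError):
    """Trial table missing required columns."""


@dataclass
class ExclusionReport:
    """Per-participant exclusion audit."""

    table: pd.DataFrame  # participant_id, accuracy, max_button_prop, excluded, reason

    @property
    def n_excluded(self) -> int:
        return int(self.table["excluded"].sum())

    def to_dict(self) -> dict:
        return {"n_excluded": self.n_excluded,
                "participants": self.table.to_dict(orient="records")}


@dataclass
class FilterReport:
    n_before: int
    n_after: int
    lo: float
    hi: float

    @property
    def fraction_removed(self) -> float:
        if self.n_before == 0:
            return 0.0
        return (self.n_before - self.n_after) / self.n_before

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fraction_removed"] = self.fraction_removed
        return d


def _require(trials: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")


def _main_task(trials: pd.DataFrame) -> pd.DataFrame:
    if "training" in trials.columns:
        return trials[~trials["training"].astype(bool)]
    return trials


def exclude_participants(trials: pd.DataFrame):
    """Remove participants with overall accuracy below 50% and/or a single
    response button on more than 75% of trials (strict inequalities; main-task
    trials only).

    Returns ``(kept_trials, ExclusionReport)``.
    """
    _require(trials, ["participant_id", "correct", "response"])
    main = _main_task(trials)
    rows = []
    excluded_ids = []
    for pid, sub in main.groupby("participant_id", sort=True):
        acc = float(sub["correct"].mean())
        btn = float(sub["response"].value_counts(normalize=True).max())
        reasons = []
        if acc < ACCURACY_MIN:
            reasons.append("accuracy")
        if btn > SINGLE_BUTTON_MAX:
            reasons.append("single-button")
        excluded = bool(reasons)
        if excluded:
            excluded_ids.append(pid)
        rows.append({"participant_id": pid, "accuracy": acc,
                     "max_button_prop": btn, "excluded": excluded,
                     "reason": "+".join(reasons)})
    report = ExclusionReport(pd.DataFrame(rows))
    kept = trials[~trials["participant_id"].isin(excluded_ids)].reset_index(drop=True)
    return kept, report


def filter_rts(trials: pd.DataFrame, lo: float = RT_LO, hi: float = RT_HI):
    """Drop trials with rt < ``lo`` or rt > ``hi`` seconds (bounds themselves
    are kept).  Negative RTs indicate corrupt input and raise."""
    _require(trials, ["rt"])
    rt = trials["rt"].astype(float)
    if (rt < 0).any():
        raise ValueError("negative RTs in input — corrupt trial table")
    keep = (rt >= lo) & (rt <= hi)
    kept = trials[keep].reset_index(drop=True)
    report = FilterReport(n_before=len(trials), n_after=len(kept), lo=lo, hi=hi)
    return kept, report


def transform_rt(rt):
    """Elementwise log10 of positive RTs (variance stabilisation)."""
    arr = np.asarray(rt, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("rt values must be > 0 for log10 transform")
    return np.log10(arr)


def transform_accuracy(p):
    """Arcsine-square-root transform of proportions in [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(arr))


def _winsorize_tukey(x: np.ndarray, k: float = 1.5):
    # nearest-rank quartiles: clipping then never moves the quartile order
    # statistics, which makes the procedure exactly idempotent
    q1, q3 = np.percentile(x, [25, 75], method="nearest")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    out = np.clip(x, lo, hi)
    return out, int(np.sum((x < lo) | (x > hi)))


def winsorize(values, grouping=None, method: str = "tukey", k: float = 1.5,
              limits: float = 0.05):
    """Winsorize ``values`` within groups.

    method="tukey" (default): values outside [Q1 - k*IQR, Q3 + k*IQR] are
    replaced by the nearer fence.  method="percentile": symmetric
    scipy.stats.mstats percentile winsorization with the given limits.

    Returns ``(winsorized array, n_replaced)``.  Each group needs >= 4 values.
    """
    x = np.asarray(values, dtype=float)
    if grouping is None:
        grouping = np.zeros(len(x), dtype=int)
    g = np.asarray(grouping)
    if len(g) != len(x):
        raise ValueError("grouping length must match values")
    out = np.array(x, copy=True)
    n_replaced = 0
    for lvl in pd.unique(g):
        idx = np.flatnonzero(g == lvl)
        if len(idx) < 4:
            raise ValueError(
                f"group {lvl!r} has {len(idx)} < 4 values; too small to winsorize"
            )
        if method == "tukey":
            out[idx], nr = _winsorize_tukey(x[idx], k=k)
            n_replaced += nr
        elif method == "percentile":
            w = np.asarray(_percentile_winsorize(x[idx], limits=(limits, limits)))
            n_replaced += int(np.sum(w != x[idx]))
            out[idx] = w
        else:
            raise ValueError("method must be 'tukey' or 'percentile'")
    return out, n_replaced


def preprocess(trials: pd.DataFrame, lo: float = RT_LO, hi: float = RT_HI):
    """Full cleaning pass: exclusion, then the RT window on main-task trials
    (training rows are dropped from the analysis table).

    Returns ``(analysis_trials, ExclusionReport, FilterReport)``.
    """
    kept, excl = exclude_participants(trials)
    main = _main_task(kept).reset_index(drop=True)
    filtered, filt = filter_rts(main, lo=lo, hi=hi)
    return filtered, excl, filt
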