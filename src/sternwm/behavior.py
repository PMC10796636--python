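"""Behavioral statistics: per-load accuracy, median reaction times, and the
one-way repeated-measures ANOVA on per-subject median RTs.

Reaction time is defined relative to probe onset:
``RT = ts_response - ts_probe``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import TrialSternberg

LOADS = (1, 2, 3)


@dataclass
class BehaviorSummary:
    """Session-level behavior; entries are NaN for loads with no trials."""

    accuracy_by_load: dict[int, float]  # percent
    median_rt_by_load: dict[int, float]  # seconds
    n_trials_by_load: dict[int, int]
    session_accuracy: float  # percent
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "load": list(LOADS),
            "n_trials": [self.n_trials_by_load[l] for l in LOADS],
            "accuracy_pct": [self.accuracy_by_load[l] for l in LOADS],
            "median_rt_s": [self.median_rt_by_load[l] for l in LOADS],
        })


@dataclass
class RmAnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def reaction_times(trials: list[TrialSternberg]) -> np.ndarray:
    rts = np.array([t.ts_response - t.ts_probe for t in trials])
    if np.any(rts <= 0):
        bad = int(np.argmax(rts <= 0))
        raise ValueError(f"non-positive reaction time on trial index {bad}")
    return rts


def behavior_by_load(trials: list[TrialSternberg],
                     correct_only_rt: bool = False) -> BehaviorSummary:
    """Accuracy (percent) and median RT per memory load and overall.

    ``correct_only_rt`` restricts the RT medians to correct trials;
    by default all responded trials enter the medians.
    """
    rts = reaction_times(trials)
    loads = np.array([t.load for t in trials])
    correct = np.array([t.response_accuracy for t in trials], dtype=float)

    acc: dict[int, float] = {}
    med: dict[int, float] = {}
    n: dict[int, int] = {}
    for load in LOADS:
        mask = loads == load
        n[load] = int(mask.sum())
        if n[load] == 0:
            acc[load] = float("nan")
            med[load] = float("nan")
            continue
        acc[load] = 100.0 * float(correct[mask].mean())
        rt_mask = mask & (correct == 1) if correct_only_rt else mask
        med[load] = float(np.median(rts[rt_mask])) if rt_mask.any() else float("nan")
    return BehaviorSummary(accuracy_by_load=acc, median_rt_by_load=med,
                           n_trials_by_load=n,
                           session_accuracy=100.0 * float(correct.mean()),
                           n_trials=len(trials))


def rm_anova_rt(per_subject_medians: np.ndarray | pd.DataFrame) -> RmAnovaResult:
    """One-way repeated-measures ANOVA (subjects x conditions).

    Partitions total variability into condition, subject and residual
    sums of squares; ``F = (SS_cond/df1) / (SS_resid/df2)`` with
    ``df1 = k-1`` and ``df2 = (k-1)(n-1)``.  Missing cells are rejected,
    never imputed.
    """
    X = np.asarray(per_subject_medians, dtype=float)
    if X.ndim != 2:
        raise ValueError("need a 2-D subjects x conditions table")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 conditions, got {n}x{k}")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing cells are not allowed")

    grand = X.mean()
    ss_cond = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_resid = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_resid = ss_resid / df2
    if ms_resid <= 0:
        # degenerate: no residual variability; rounding can leave a tiny
        # nonzero ss_cond, so compare against the total scale
        F = 0.0 if ss_cond <= 1e-12 * max(ss_total, 1e-300) else float("inf")
    else:
        F = float((ss_cond / df1) / ms_resid)
    from scipy import stats
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return RmAnovaResult(F=F, df1=df1, df2=df2, p=p)


def subject_median_rt_table(per_session: list[tuple[str, BehaviorSummary]]
                            ) -> pd.DataFrame:
    """Aggregate session summaries to one row of per-load median RTs per
    subject (mean across a subject's sessions), the dataset-level ANOVA
    input."""
    rows = []
    for subject_id, summ in per_session:
        rows.append({"subject": subject_id,
                     **{f"load{l}": summ.median_rt_by_load[l] for l in LOADS}})
    df = pd.DataFrame(rows)
    return df.groupby("subject", sort=True).mean()
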