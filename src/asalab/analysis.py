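"""Trial endpoints and statistics.

The primary endpoint of the paradigm is the between-group difference in the
change of cumulative work for alcohol (cWFA) from the pre-treatment to the
on-treatment session; cWFA is the number of correct attention-task trials
performed toward alcohol rewards from the start of voluntary work (T = 0),
including trials of work-sets left incomplete.  Secondary endpoints are the
cumulative work for saline (cWFS) and peak/mean BrAC.  The 150-min work
phase splits into an ascending [0, 75) and a plateau [75, 150] window, which
by design carry predominantly positive vs. putatively negative
reinforcement.

Statistics follow the trial's analysis plan: pooled-variance two-sided
Student t-tests (the printed degrees of freedom n1 + n2 - 2 force the pooled
rather than the Welch form), Cohen's d with a normal-approximation
confidence interval, Pearson/Spearman correlations, slope-based analysis of
the subjective scales, and the intention-to-treat imputation rule (a missing
second session is replaced by the subject's baseline plus the mean change of
the remaining subjects in the same arm).  All functions accept either group
summaries (n, mean, sd), so printed tables can be re-analyzed directly, or
raw vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .session import SessionLog

__all__ = [
    "GroupSummary",
    "cumulative_work",
    "two_sample_t",
    "cohens_d_ci",
    "impute_missing_change",
    "pearson_r",
    "spearman_rho",
    "subjective_slopes",
    "session_endpoints",
    "endpoint_table",
    "analyze_endpoints",
]

ASCENDING_WINDOW = (0.0, 75.0)
PLATEAU_WINDOW = (75.0, 150.0)
SUBJECTIVE_SCALES = ("stimulation", "sedation", "wellbeing", "desire", "drunkenness")


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics (n, mean, sd) of one group's scores."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.sd < 0:
            raise ValueError("sd cannot be negative")

    @classmethod
    def of(cls, values: Iterable[float]) -> "GroupSummary":
        arr = np.asarray(list(values), dtype=float)
        return cls(n=arr.size, mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def cumulative_work(
    log: SessionLog, kind: str, window: tuple[float, float] = (0.0, 150.0)
) -> int:
    """Correct attention-task trials for ``kind`` with event time in
    ``[t0, t1)``; T = 0 is the start of voluntary work, so priming trials
    never count."""
    t0, t1 = window
    if t0 < 0.0 or t1 > log.vwr_duration_min + 1e-9 or t0 > t1:
        raise ValueError(f"window {window} outside the work phase [0, {log.vwr_duration_min}]")
    return sum(
        1
        for e in log.events
        if e.kind == "trial_success" and e.reward_kind == kind and t0 <= e.t < t1
    )


def _pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    return math.sqrt(pooled_var)


def two_sample_t(a: GroupSummary, b: GroupSummary) -> tuple[float, int, float]:
    """Pooled-variance (Student) two-sample t-test from summaries.

    Returns ``(t, df, p)`` with df = n_a + n_b - 2 and a two-sided p-value.
    """
    sp = _pooled_sd(a, b)
    if sp == 0:
        raise ValueError("zero pooled variance")
    df = a.n + b.n - 2
    t = (a.mean - b.mean) / (sp * math.sqrt(1.0 / a.n + 1.0 / b.n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def cohens_d_ci(
    a: GroupSummary, b: GroupSummary, level: float = 0.95
) -> tuple[float, float, float]:
    """Cohen's d = (mean_a - mean_b) / pooled SD with a normal-approximation CI.

    The standard error is sqrt((n_a+n_b)/(n_a*n_b) + d^2/(2*(n_a+n_b))).
    """
    sp = _pooled_sd(a, b)
    if sp == 0:
        raise ValueError("zero pooled standard deviation")
    d = (a.mean - b.mean) / sp
    n_tot = a.n + b.n
    se = math.sqrt(n_tot / (a.n * b.n) + d * d / (2.0 * n_tot))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return d, d - z * se, d + z * se


def impute_missing_change(baseline: float, other_changes: Sequence[float]) -> float:
    """Intention-to-treat imputation of a missing second session.

    The subject's change score is set to the mean change of the remaining
    subjects in the same arm, i.e. the imputed session-2 value is
    ``baseline + mean(other_changes)`` where changes are session2 - session1.
    """
    if len(other_changes) == 0:
        raise ValueError("need at least one observed change to impute from")
    return float(baseline + np.mean(other_changes))


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return x, y


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value."""
    x, y = _check_pair(x, y)
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p-value."""
    x, y = _check_pair(x, y)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def subjective_slopes(assessments: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Slopes of one subjective scale between assessment points 2-3 and 3-4.

    ``assessments`` holds exactly four (time, score) pairs: baseline, the
    priming-interval rating, the ascending-phase rating, and the end rating.
    Returns (ascending_slope, plateau_slope) in VAS points per minute.
    """
    if len(assessments) != 4:
        raise ValueError("need exactly four assessment time points")
    pts = sorted((float(t), float(v)) for t, v in assessments)
    (t2, s2), (t3, s3), (t4, s4) = pts[1], pts[2], pts[3]
    if t3 == t2 or t4 == t3:
        raise ValueError("assessment time points must be distinct")
    return (s3 - s2) / (t3 - t2), (s4 - s3) / (t4 - t3)


# ---------------------------------------------------------------------------
# endpoint extraction from session logs


def session_endpoints(log: SessionLog) -> dict:
    """Per-session endpoint row: cWFA/cWFS (full and per phase), peak and
    mean BrAC over the work phase, and subjective slopes per scale."""
    row = {
        "subject_id": log.subject_id,
        "session_index": log.session_index,
        "cwfa": cumulative_work(log, "alcohol"),
        "cwfs": cumulative_work(log, "saline"),
        "cwfa_ascending": cumulative_work(log, "alcohol", ASCENDING_WINDOW),
        "cwfa_plateau": cumulative_work(log, "alcohol", PLATEAU_WINDOW),
        "cwfs_ascending": cumulative_work(log, "saline", ASCENDING_WINDOW),
        "cwfs_plateau": cumulative_work(log, "saline", PLATEAU_WINDOW),
    }
    series = np.asarray(log.brac_series, dtype=float)
    if series.size:
        vwr = series[series[:, 0] >= 0.0]
        row["peak_brac"] = float(vwr[:, 1].max()) if vwr.size else 0.0
        row["mean_brac"] = float(vwr[:, 1].mean()) if vwr.size else 0.0
    else:
        row["peak_brac"] = row["mean_brac"] = float("nan")
    if len(log.assessments) == 4:
        for scale in SUBJECTIVE_SCALES:
            pts = [(t, getattr(s, scale)) for t, s in log.assessments]
            asc, plat = subjective_slopes(pts)
            row[f"{scale}_slope_ascending"] = asc
            row[f"{scale}_slope_plateau"] = plat
    return row


def endpoint_table(logs: Iterable[SessionLog]) -> pd.DataFrame:
    """Stack per-session endpoint rows into a table."""
    return pd.DataFrame([session_endpoints(log) for log in logs])


def analyze_endpoints(
    endpoints: pd.DataFrame,
    group_col: str = "group",
    treated: str = "naltrexone",
    control: str = "placebo",
    variables: Sequence[str] = ("cwfa", "cwfa_ascending", "cwfa_plateau", "cwfs",
                               "peak_brac", "mean_brac"),
) -> dict:
    """Group statistics of session-2-minus-session-1 change scores.

    ``endpoints`` must hold one row per subject with ``<var>_s1``/``<var>_s2``
    columns and a group column.  For each variable the pooled t-test and
    Cohen's d (control minus treated, so a positive d means the treated arm
    reduced more) are reported.
    """
    out: dict = {}
    for var in variables:
        delta = endpoints[f"{var}_s2"] - endpoints[f"{var}_s1"]
        a = GroupSummary.of(delta[endpoints[group_col] == control])
        b = GroupSummary.of(delta[endpoints[group_col] == treated])
        t, df, p = two_sample_t(a, b)
        d, lo, hi = cohens_d_ci(a, b)
        out[var] = {
            "mean_change_control": a.mean,
            "sd_change_control": a.sd,
            "mean_change_treated": b.mean,
            "sd_change_treated": b.sd,
            "t": t,
            "df": df,
            "p": p,
            "d": d,
            "d_ci": (lo, hi),
        }
    return out
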