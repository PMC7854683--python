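"""Task-centric statistics, group contrasts, and the confidence score.

For a labelled group of learners each task gets (1) its completion
frequency — the fraction of group members who completed it — and (2) its
mean rank — the mean 1-based position among completers, in each learner's
own sequence.  Contrasting a high- and a low-performing group places each
task in a quadrant plane: dfreq = freq(HP) − freq(LP) on x, and
drank = mean_rank(LP) − mean_rank(HP) on y, so the upper half means the
task is completed earlier on average by the high performers.

The confidence score of a student over their end-of-session survey
responses is C = confident / (confident + revisit + support).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sequence_core import Cohort, GroupLabelling, TaskCatalog

__all__ = [
    "TaskStats",
    "TaskContrast",
    "ConfidenceReport",
    "ConfidenceTestResult",
    "task_completion_stats",
    "group_task_contrast",
    "confidence_scores",
    "group_confidence_test",
]


@dataclass(frozen=True)
class TaskStats:
    """Per-task completion frequency and mean rank within one group.

    ``mean_rank`` is NaN exactly where ``frequency`` is zero."""

    frequency: np.ndarray
    mean_rank: np.ndarray
    label: str
    n_members: int


@dataclass(frozen=True)
class TaskContrast:
    """Per-task group differences plus per-type median/IQR summaries."""

    dfreq: np.ndarray
    drank: np.ndarray
    quadrant: tuple[str | None, ...]
    type_summary: pd.DataFrame

    def to_frame(self, catalog: TaskCatalog) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "task_id": range(1, catalog.T + 1),
                "type": catalog.type_of,
                "dfreq": self.dfreq,
                "drank": self.drank,
                "quadrant": self.quadrant,
            }
        )


@dataclass(frozen=True)
class ConfidenceReport:
    """Per-student scores, per-task confident proportions, and the raw
    response table used by the group test."""

    per_student: dict[str, float]
    per_task_proportion: np.ndarray
    responses: pd.DataFrame


@dataclass(frozen=True)
class ConfidenceTestResult:
    statistic: float
    pvalue: float
    group_means: dict[str, float]
    group_stds: dict[str, float]
    n_pairs: int
    pairing: str


def task_completion_stats(
    cohort: Cohort, groups: GroupLabelling, label: str
) -> TaskStats:
    """Completion frequency and mean rank per task over one labelled group."""
    members = set(groups.members(label))
    recs = [r for r in cohort.learners if r.learner_id in members]
    if not recs:
        raise ValueError(f"group {label!r} is empty")
    T = cohort.catalog.T
    n_done = np.zeros(T)
    rank_sum = np.zeros(T)
    for rec in recs:
        for pos, task in enumerate(rec.sequence, start=1):
            n_done[task - 1] += 1
            rank_sum[task - 1] += pos
    freq = n_done / len(recs)
    mean_rank = np.full(T, np.nan)
    done = n_done > 0
    mean_rank[done] = rank_sum[done] / n_done[done]
    return TaskStats(
        frequency=freq, mean_rank=mean_rank, label=label, n_members=len(recs)
    )


def _quadrant(df: float, dr: float) -> str | None:
    if np.isnan(dr) or np.isnan(df):
        return None
    vert = "upper" if dr > 0 else ("lower" if dr < 0 else "mid")
    horiz = "right" if df > 0 else ("left" if df < 0 else "centre")
    return f"{vert}-{horiz}"


def group_task_contrast(
    stats_hp: TaskStats, stats_lp: TaskStats, catalog: TaskCatalog
) -> TaskContrast:
    """Quadrant contrast of two groups' task statistics.

    dfreq > 0: completed more frequently by the first (high-performing)
    group; drank > 0: completed earlier on average by the first group.
    Tasks lacking a mean rank in either group have drank NaN and are
    excluded from the per-type summaries.
    """
    dfreq = stats_hp.frequency - stats_lp.frequency
    drank = stats_lp.mean_rank - stats_hp.mean_rank
    quadrant = tuple(_quadrant(f, r) for f, r in zip(dfreq, drank))

    rows = []
    types = np.asarray(catalog.type_of)
    both = ~np.isnan(drank)
    for task_type in sorted(set(catalog.type_of)):
        sel = (types == task_type) & both
        n = int(sel.sum())
        if n:
            f, r = dfreq[sel], drank[sel]
            rows.append(
                {
                    "type": task_type,
                    "n_tasks": n,
                    "median_dfreq": float(np.median(f)),
                    "iqr_dfreq": float(np.subtract(*np.percentile(f, [75, 25]))),
                    "median_drank": float(np.median(r)),
                    "iqr_drank": float(np.subtract(*np.percentile(r, [75, 25]))),
                }
            )
        else:
            rows.append(
                {
                    "type": task_type,
                    "n_tasks": 0,
                    "median_dfreq": np.nan,
                    "iqr_dfreq": np.nan,
                    "median_drank": np.nan,
                    "iqr_drank": np.nan,
                }
            )
    return TaskContrast(
        dfreq=dfreq,
        drank=drank,
        quadrant=quadrant,
        type_summary=pd.DataFrame(rows),
    )


def confidence_scores(cohort: Cohort) -> ConfidenceReport:
    """Per-student confidence C and per-task confident proportion.

    C is computed over the tasks a student actually answered; students with
    no responses get NaN.  The per-task proportion is across the students
    who answered that task.
    """
    rows = []
    for rec in cohort.learners:
        if rec.confidence:
            for task, resp in rec.confidence.items():
                rows.append((rec.learner_id, task, resp))
    if not rows:
        raise ValueError("no confidence responses present in the cohort")
    responses = pd.DataFrame(rows, columns=["learner_id", "task_id", "response"])

    per_student: dict[str, float] = {}
    for rec in cohort.learners:
        if rec.confidence:
            vals = list(rec.confidence.values())
            per_student[rec.learner_id] = vals.count("confident") / len(vals)
        else:
            per_student[rec.learner_id] = np.nan

    T = cohort.catalog.T
    prop = np.full(T, np.nan)
    grouped = responses.groupby("task_id")["response"]
    agg = grouped.apply(lambda s: (s == "confident").mean())
    prop[np.asarray(agg.index, dtype=int) - 1] = agg.to_numpy()
    return ConfidenceReport(
        per_student=per_student, per_task_proportion=prop, responses=responses
    )


def group_confidence_test(
    report: ConfidenceReport,
    groups: GroupLabelling,
    labels: tuple[str, str] = ("g1", "g2"),
    pairing: str = "task",
) -> ConfidenceTestResult:
    """Compare confidence between two groups.

    ``pairing='task'`` (default): for each task answered by both groups,
    take the group's confident proportion; paired two-sided t-test across
    tasks.  ``pairing='student'``: per-student C compared between groups
    with Welch's two-sample t-test (students cannot be paired across
    groups).
    """
    la, lb = labels
    resp = report.responses
    in_a = resp["learner_id"].isin(set(groups.members(la)))
    in_b = resp["learner_id"].isin(set(groups.members(lb)))
    if not in_a.any() or not in_b.any():
        raise ValueError("both groups need at least one confidence response")

    if pairing == "task":
        conf = resp.assign(is_conf=resp["response"] == "confident")
        mean_a = conf[in_a].groupby("task_id")["is_conf"].mean()
        mean_b = conf[in_b].groupby("task_id")["is_conf"].mean()
        common = mean_a.index.intersection(mean_b.index)
        if len(common) < 2:
            raise ValueError("fewer than 2 tasks answered by both groups")
        a = mean_a.loc[common].to_numpy(dtype=float)
        b = mean_b.loc[common].to_numpy(dtype=float)
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(a, b)
        n_pairs = len(common)
    elif pairing == "student":
        a = np.array(
            [
                report.per_student[m]
                for m in groups.members(la)
                if np.isfinite(report.per_student.get(m, np.nan))
            ]
        )
        b = np.array(
            [
                report.per_student[m]
                for m in groups.members(lb)
                if np.isfinite(report.per_student.get(m, np.nan))
            ]
        )
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs at least 2 scored students")
        t, p = sps.ttest_ind(a, b, equal_var=False)
        n_pairs = min(len(a), len(b))
    else:
        raise ValueError("pairing must be 'task' or 'student'")

    return ConfidenceTestResult(
        statistic=float(t),
        pvalue=float(p),
        group_means={la: float(np.mean(a)), lb: float(np.mean(b))},
        group_stds={la: float(np.std(a, ddof=1)), lb: float(np.std(b, ddof=1))},
        n_pairs=n_pairs,
        pairing=pairing,
    )
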