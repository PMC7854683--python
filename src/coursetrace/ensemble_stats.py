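"""Ensemble descriptive statistics over completion sequences.

Given the ensemble of learner sequences this module computes

* the position matrix ``P`` — ``p_ij`` is the probability that task *i* was
  completed as the *j*-th task across the cohort (rows normalised from the
  raw counts ``n_ij``);
* transition summaries at task or session resolution — raw counts ``m_ij``
  (task *j* immediately preceded by task *i*), the joint probability
  ``p_{i→j} = m_ij / Σ m``, and the conditional ``π_ij = p_{i→j} / Σ_j
  p_{i→j}``.  π is *not* a stochastic process matrix: acquisition is
  irreversible, π only summarises observed successions;
* signed group differences Δπ and Jensen–Shannon distance profiles between
  two groups' transition matrices;
* per-learner deviation matrices: the signed, normalised gap between the
  actual completion position of each task and its nominal rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .sequence_core import Cohort

__all__ = [
    "PositionMatrix",
    "TransitionSummary",
    "DeviationMatrix",
    "JSProfile",
    "position_probability_matrix",
    "transition_summary",
    "delta_transition",
    "js_profile",
    "deviation_matrix",
    "transition_graphml",
]

START_STATE = 0  # virtual state preceding the first completion


@dataclass(frozen=True)
class PositionMatrix:
    """Counts ``n_ij`` and row-normalised probabilities ``p_ij`` (T×T).

    ``never_completed[i]`` flags tasks no learner completed; their P rows
    are identically zero rather than undefined-NaN so the matrix stays a
    plain 2-D histogram.
    """

    counts: np.ndarray
    P: np.ndarray
    never_completed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        t = self.P.shape[0]
        idx = pd.Index(range(1, t + 1), name="task_id")
        return pd.DataFrame(self.P, index=idx, columns=range(1, t + 1))


@dataclass(frozen=True)
class TransitionSummary:
    """Transition counts and probabilities at task or session resolution.

    ``states`` are 1-based task or session IDs, optionally preceded by the
    virtual START state 0.  ``conditional`` rows with no outgoing
    transition are NaN and flagged False in ``row_defined`` — never
    silently uniform.
    """

    states: tuple[int, ...]
    counts: np.ndarray
    joint: np.ndarray
    conditional: np.ndarray
    resolution: str
    include_start: bool

    @property
    def row_defined(self) -> np.ndarray:
        return self.counts.sum(axis=1) > 0

    def to_frame(self, which: str = "conditional") -> pd.DataFrame:
        mat = getattr(self, which)
        idx = pd.Index(self.states, name=f"{self.resolution}_from")
        return pd.DataFrame(mat, index=idx, columns=self.states)


@dataclass(frozen=True)
class DeviationMatrix:
    """Signed normalised deviation from nominal order per learner/position.

    Entry (k, j) is ``(j+1)/n_k - rank(t_j)/T`` for learner k's j-th
    completion: positive means the task was completed later than its
    nominal rank suggests, negative earlier.  Positions past the learner's
    last completion are NaN (the censored region)."""

    D: np.ndarray
    learner_ids: tuple[str, ...]
    completed_length: np.ndarray
    order_by: str


@dataclass(frozen=True)
class JSProfile:
    """Row-wise (outgoing) and column-wise (incoming) Jensen–Shannon
    distances between two transition matrices; NaN where either side is
    undefined."""

    row_distances: np.ndarray
    col_distances: np.ndarray
    mean_outgoing: float
    mean_incoming: float
    skipped_rows: tuple[int, ...]
    skipped_cols: tuple[int, ...]
    states: tuple[int, ...]


def position_probability_matrix(cohort: Cohort) -> PositionMatrix:
    """2-D completion histogram: rows index tasks by nominal ID, columns
    index the position in the learner's own sequence.

    A cohort in which every learner completes every task in nominal order
    yields the identity matrix.
    """
    T = cohort.catalog.T
    counts = np.zeros((T, T), dtype=np.int64)
    for rec in cohort.learners:
        for pos, task in enumerate(rec.sequence):
            counts[task - 1, pos] += 1
    row_sums = counts.sum(axis=1)
    never = row_sums == 0
    P = np.zeros_like(counts, dtype=float)
    nz = ~never
    P[nz] = counts[nz] / row_sums[nz, None]
    return PositionMatrix(counts=counts, P=P, never_completed=never)


def transition_summary(
    cohort: Cohort,
    resolution: str = "task",
    include_start: bool | None = None,
) -> TransitionSummary:
    """Count immediate successions across the ensemble and normalise.

    At session resolution task IDs are substituted by session IDs first, so
    within-session moves become self-loops (retained in the matrices).  The
    virtual START state makes the first completion itself a transition; it
    defaults off at task resolution and on at session resolution.
    """
    if resolution not in ("task", "session"):
        raise ValueError("resolution must be 'task' or 'session'")
    if include_start is None:
        include_start = resolution == "session"

    if resolution == "task":
        n_states = cohort.catalog.T
        relabel = {t: t for t in range(1, n_states + 1)}
    else:
        n_states = cohort.catalog.S
        relabel = {
            t: cohort.catalog.session(t) for t in range(1, cohort.catalog.T + 1)
        }

    offset = 1 if include_start else 0
    k = n_states + offset
    counts = np.zeros((k, k), dtype=np.int64)
    for rec in cohort.learners:
        seq = [relabel[t] for t in rec.sequence]
        if include_start and seq:
            counts[0, seq[0] - 1 + offset] += 1
        for a, b in zip(seq, seq[1:]):
            counts[a - 1 + offset, b - 1 + offset] += 1

    total = counts.sum()
    joint = counts / total if total > 0 else np.zeros_like(counts, dtype=float)
    row_sums = counts.sum(axis=1)
    conditional = np.full((k, k), np.nan)
    defined = row_sums > 0
    conditional[defined] = counts[defined] / row_sums[defined, None]

    states = tuple(range(1 - offset, n_states + 1))
    return TransitionSummary(
        states=states,
        counts=counts,
        joint=joint,
        conditional=conditional,
        resolution=resolution,
        include_start=include_start,
    )


def _check_compatible(a: TransitionSummary, b: TransitionSummary) -> None:
    if a.resolution != b.resolution or a.states != b.states:
        raise ValueError(
            "transition summaries have mismatched resolution or state sets"
        )


def delta_transition(
    pi_a: TransitionSummary, pi_b: TransitionSummary
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed conditional-probability difference ``Δπ = π_A − π_B``.

    Returns ``(delta, positive_part, negative_part)``.  Rows undefined in
    either summary (no outgoing transitions) are NaN throughout and thereby
    excluded from both parts.
    """
    _check_compatible(pi_a, pi_b)
    delta = pi_a.conditional - pi_b.conditional
    pos = np.where(delta > 0, delta, 0.0)
    neg = np.where(delta < 0, -delta, 0.0)
    undefined = ~(pi_a.row_defined & pi_b.row_defined)
    pos[undefined] = np.nan
    neg[undefined] = np.nan
    return delta, pos, neg


def _js_distance(p: np.ndarray, q: np.ndarray) -> float:
    # base-2 J-S distance: 0 = identical, 1 = disjoint support
    return float(jensenshannon(p, q, base=2))


def js_profile(
    pi_a: TransitionSummary,
    pi_b: TransitionSummary,
    column_mode: str = "renormalised",
) -> JSProfile:
    """Jensen–Shannon distance between two groups' transition matrices.

    Outgoing profile: distance between matching conditional rows.  Incoming
    profile: between matching columns, renormalised to sum to 1 (default)
    or taken from the joint matrix (``column_mode='joint'``).  Rows or
    columns undefined on either side are NaN and listed as skipped.
    """
    _check_compatible(pi_a, pi_b)
    if column_mode not in ("renormalised", "joint"):
        raise ValueError("column_mode must be 'renormalised' or 'joint'")
    k = len(pi_a.states)
    row_d = np.full(k, np.nan)
    defined = pi_a.row_defined & pi_b.row_defined
    for i in np.flatnonzero(defined):
        row_d[i] = _js_distance(pi_a.conditional[i], pi_b.conditional[i])

    col_d = np.full(k, np.nan)
    if column_mode == "renormalised":
        mat_a = np.where(np.isnan(pi_a.conditional), 0.0, pi_a.conditional)
        mat_b = np.where(np.isnan(pi_b.conditional), 0.0, pi_b.conditional)
    else:
        mat_a, mat_b = pi_a.joint, pi_b.joint
    for j in range(k):
        ca, cb = mat_a[:, j], mat_b[:, j]
        sa, sb = ca.sum(), cb.sum()
        if sa > 0 and sb > 0:
            col_d[j] = _js_distance(ca / sa, cb / sb)

    return JSProfile(
        row_distances=row_d,
        col_distances=col_d,
        mean_outgoing=float(np.nanmean(row_d)) if np.any(~np.isnan(row_d)) else np.nan,
        mean_incoming=float(np.nanmean(col_d)) if np.any(~np.isnan(col_d)) else np.nan,
        skipped_rows=tuple(
            s for s, ok in zip(pi_a.states, ~np.isnan(row_d)) if not ok
        ),
        skipped_cols=tuple(
            s for s, ok in zip(pi_a.states, ~np.isnan(col_d)) if not ok
        ),
        states=pi_a.states,
    )


def deviation_matrix(cohort: Cohort, order_by: str = "grade") -> DeviationMatrix:
    """Per-learner deviation heatmap from the nominal order.

    For learner *k* with ``n_k`` completions, position *j* holds
    ``j / n_k − rank(t_j) / T`` (both fractions in (0, 1]), so a learner
    who completes the whole course exactly in nominal order gets an
    all-zero row.  Learners are ordered by descending grade (ties broken
    by ID) or by ID.
    """
    if order_by not in ("grade", "id"):
        raise ValueError("order_by must be 'grade' or 'id'")
    recs = list(cohort.learners)
    if order_by == "grade":
        recs.sort(
            key=lambda r: (
                -(r.grade if r.grade is not None else -np.inf),
                r.learner_id,
            )
        )
    else:
        recs.sort(key=lambda r: r.learner_id)

    T = cohort.catalog.T
    D = np.full((len(recs), T), np.nan)
    lengths = np.zeros(len(recs), dtype=np.int64)
    for k, rec in enumerate(recs):
        n_k = len(rec.sequence)
        lengths[k] = n_k
        for j, task in enumerate(rec.sequence, start=1):
            D[k, j - 1] = j / n_k - task / T
    return DeviationMatrix(
        D=D,
        learner_ids=tuple(r.learner_id for r in recs),
        completed_length=lengths,
        order_by=order_by,
    )


def transition_graphml(summary: TransitionSummary, path: str | Path) -> None:
    """Export the conditional transition matrix as a weighted directed
    GraphML graph (self-loops dropped, as in circular renderings)."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(summary.states)
    k = len(summary.states)
    for i in range(k):
        for j in range(k):
            w = summary.conditional[i, j]
            if i != j and np.isfinite(w) and w > 0:
                g.add_edge(summary.states[i], summary.states[j], weight=float(w))
    nx.write_graphml(g, str(path))
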