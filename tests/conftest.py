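"""Shared fixtures and independent brute-force oracles.

The oracle functions recount every descriptive statistic with plain
dictionary loops, independently of the array implementations they check.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
import pytest

from coursetrace import Cohort, LearnerRecord, TaskCatalog


@pytest.fixture
def tiny_catalog() -> TaskCatalog:
    return TaskCatalog(session_of=(1, 1, 2), type_of=("reading_video",) * 3)


@pytest.fixture
def tiny_cohort(tiny_catalog) -> Cohort:
    """Three learners over three tasks, used by several hand-worked examples."""
    return Cohort(
        tiny_catalog,
        (
            LearnerRecord("A", (1, 2, 3), grade=80.0),
            LearnerRecord("B", (2, 1, 3), grade=60.0),
            LearnerRecord("C", (1, 3), grade=50.0),
        ),
    )


def random_cohort(seed: int, n_max: int = 5, t_max: int = 6) -> Cohort:
    """Small random cohort: random T, S, learner count, and sequences that
    are random-length prefixes of random permutations (so some tasks may
    be skipped entirely)."""
    rng = np.random.default_rng(seed)
    T = int(rng.integers(2, t_max + 1))
    S = int(rng.integers(1, T + 1))
    # contiguous session blocks
    cuts = np.sort(rng.choice(np.arange(1, T), size=S - 1, replace=False)) if S > 1 else []
    session_of, s = [], 1
    for t in range(T):
        if s < S and t in cuts:
            s += 1
        session_of.append(s)
    n = int(rng.integers(1, n_max + 1))
    learners = []
    for k in range(n):
        perm = rng.permutation(T) + 1
        length = int(rng.integers(0, T + 1))
        learners.append(
            LearnerRecord(
                learner_id=f"L{k}",
                sequence=tuple(int(t) for t in perm[:length]),
                grade=float(rng.uniform(0, 100)),
            )
        )
    catalog = TaskCatalog(
        session_of=tuple(session_of), type_of=("quiz",) * T
    )
    return Cohort(catalog, tuple(learners))


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_position_counts(cohort: Cohort) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = defaultdict(int)
    for rec in cohort.learners:
        for pos, task in enumerate(rec.sequence, start=1):
            counts[(task, pos)] += 1
    return dict(counts)


def brute_transition_counts(
    cohort: Cohort, resolution: str, include_start: bool
) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = defaultdict(int)
    for rec in cohort.learners:
        if resolution == "session":
            seq = [cohort.catalog.session(t) for t in rec.sequence]
        else:
            seq = list(rec.sequence)
        if include_start and seq:
            counts[(0, seq[0])] += 1
        for a, b in zip(seq, seq[1:]):
            counts[(a, b)] += 1
    return dict(counts)


def brute_task_stats(cohort: Cohort, member_ids: set[str]):
    """(frequency, mean_rank) dicts keyed by task, recomputed naively."""
    recs = [r for r in cohort.learners if r.learner_id in member_ids]
    freq, rank = {}, {}
    for t in range(1, cohort.catalog.T + 1):
        positions = [
            rec.sequence.index(t) + 1 for rec in recs if t in rec.sequence
        ]
        freq[t] = len(positions) / len(recs)
        rank[t] = sum(positions) / len(positions) if positions else None
    return freq, rank


def brute_deviation(cohort: Cohort) -> dict[str, list[float]]:
    T = cohort.catalog.T
    out = {}
    for rec in cohort.learners:
        n = len(rec.sequence)
        out[rec.learner_id] = [
            (j + 1) / n - task / T for j, task in enumerate(rec.sequence)
        ]
    return out


def js_distance_by_hand(p, q) -> float:
    """Base-2 Jensen–Shannon distance from the entropy definition,
    H(m) - (H(p) + H(q))/2 with m the midpoint, 0·log0 = 0."""

    def h(v):
        return -sum(x * math.log2(x) for x in v if x > 0)

    m = [(a + b) / 2 for a, b in zip(p, q)]
    div = h(m) - (h(p) + h(q)) / 2
    return math.sqrt(max(div, 0.0))
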