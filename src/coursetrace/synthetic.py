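"""Synthetic cohort generator.

Real LMS completion logs of the kind this package analyses are private, so
the generator produces cohorts with the statistical signatures such data
shows: strong but imperfect adherence to the nominal task order, session
blocks, jump-ahead pulls toward coursework, a rising skip rate along the
course (broadening position histograms), a subgroup that skips designated
tasks (bimodal position histograms downstream), and group-dependent grades
and confidence responses.

Two modes are provided:

* *model-only* — sequences drawn straight from the hypercubic model for a
  given θ, with no post-processing; the right substrate for parameter
  recovery and oracle tests because it matches the model assumptions
  exactly.
* *behavioural* — model draws post-processed by skips, branching and
  jump-ahead relocation; deliberately violates the model assumptions the
  way real learners do.

Everything is reproducible from the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hypertraps import simulate_sequence
from .sequence_core import (
    TASK_TYPES,
    Cohort,
    LearnerRecord,
    TaskCatalog,
)

__all__ = [
    "GroupSpec",
    "ScenarioConfig",
    "GroundTruth",
    "make_catalog",
    "behavioural_theta",
    "simulate_cohort",
    "model_only_cohort",
    "scenario_from_yaml",
]


@dataclass(frozen=True)
class GroupSpec:
    """One performance stratum of the synthetic cohort.

    ``adherence_within`` / ``adherence_between`` are the log-propensity
    boosts from a task to its nominal successor inside a session and
    across a session boundary; ``coursework_pull`` is a basal log-boost of
    coursework tasks (skipping ahead to marked work).  ``completion_mean``
    / ``completion_std`` set the fraction of the course a member
    completes; ``confident_prob`` the chance each survey response is
    'confident'.
    """

    label: str
    size: int
    grade_mean: float
    grade_std: float
    adherence_within: float = 7.0
    adherence_between: float = 7.0
    coursework_pull: float = 0.0
    confident_prob: float = 0.7
    completion_mean: float = 0.9
    completion_std: float = 0.08
    jump_ahead_prob: float = 0.0
    jump_ahead_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("group size must be positive")
        for p in (self.confident_prob, self.jump_ahead_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _default_groups() -> tuple[GroupSpec, ...]:
    # An 81-learner cohort in three strata: top quartile (20), middle (41),
    # bottom quartile (20).  Grade means/stds follow the course summary the
    # generator emulates (79.3/3.3 top, 55.6/4.6 bottom, 68.4 overall);
    # confidence 0.76 vs 0.65 for top vs bottom.  High performers adhere
    # more tightly to the session progression; low performers adhere
    # within sessions but jump between non-sequential sessions and pull
    # coursework early, completing less of the course.
    return (
        GroupSpec(
            label="high",
            size=20,
            grade_mean=79.3,
            grade_std=3.3,
            adherence_within=7.5,
            adherence_between=9.0,
            coursework_pull=0.0,
            confident_prob=0.76,
            completion_mean=0.95,
            completion_std=0.05,
        ),
        GroupSpec(
            label="mid",
            size=41,
            grade_mean=68.4,
            grade_std=5.0,
            adherence_within=8.0,
            adherence_between=8.0,
            coursework_pull=1.0,
            confident_prob=0.70,
            completion_mean=0.85,
            completion_std=0.10,
        ),
        GroupSpec(
            label="low",
            size=20,
            grade_mean=55.6,
            grade_std=4.6,
            adherence_within=9.0,
            adherence_between=6.5,
            coursework_pull=3.0,
            confident_prob=0.65,
            completion_mean=0.70,
            completion_std=0.12,
            jump_ahead_prob=0.5,
        ),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of a synthetic study: course shape, strata,
    skip/branch behaviour, and the mandatory seed."""

    seed: int
    T: int = 123
    S: int = 10
    groups: tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    skip_rate_start: float = 0.02
    skip_rate_end: float = 0.25
    branch_tasks: tuple[int, ...] = (78, 81)
    branch_fraction: float = 0.4
    coursework_sessions: tuple[int, ...] = (3, 4, 4, 9)
    type_mix: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.T < self.S or self.S < 1:
            raise ValueError("need T >= S >= 1")
        for p in (
            self.skip_rate_start,
            self.skip_rate_end,
            self.branch_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def N(self) -> int:
        return sum(g.size for g in self.groups)


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth for recovery tests: the θ used per group, the
    true group of every learner, and the generator mode."""

    thetas: dict[str, np.ndarray]
    group_of: dict[str, str]
    mode: str


def make_catalog(
    T: int,
    S: int,
    type_mix: dict[str, float] | None = None,
    seed: int = 0,
    coursework_sessions: tuple[int, ...] = (3, 4, 4, 9),
) -> TaskCatalog:
    """Build a course layout: contiguous near-equal session blocks, task
    types drawn from ``type_mix``, coursework placed in the stated
    sessions (one coursework task per listed entry; repeats allowed).
    """
    if T < S or S < 1:
        raise ValueError("need T >= S >= 1")
    rng = np.random.default_rng(seed)

    # near-equal contiguous session blocks
    base, extra = divmod(T, S)
    sizes = [base + (1 if s < extra else 0) for s in range(S)]
    session_of: list[int] = []
    for s, sz in enumerate(sizes, start=1):
        session_of.extend([s] * sz)

    if type_mix is None:
        # plausible mix for a reading-heavy online course with frequent
        # interactive checkpoints
        type_mix = {
            "reading_video": 0.45,
            "quiz": 0.12,
            "multi_response_poll": 0.12,
            "g_chart": 0.10,
            "discussion_post": 0.16,
        }
        cw_sessions: tuple[int, ...] = tuple(
            s for s in coursework_sessions if s <= S
        )
    else:
        cw_sessions = tuple(s for s in coursework_sessions if s <= S)
        if "coursework" in type_mix:
            raise ValueError(
                "place coursework via coursework_sessions, not the mix"
            )
    unknown = set(type_mix) - set(TASK_TYPES)
    if unknown:
        raise ValueError(f"unknown task types in mix: {sorted(unknown)}")
    total = sum(type_mix.values())
    if total <= 0:
        raise ValueError("type mix must have positive total weight")
    names = sorted(type_mix)
    probs = np.array([type_mix[n] / total for n in names])

    type_of = list(rng.choice(names, size=T, p=probs))
    # coursework overwrites one task per listed session occurrence
    session_starts = np.cumsum([0] + sizes)
    used: set[int] = set()
    for s in cw_sessions:
        lo, hi = session_starts[s - 1], session_starts[s]
        candidates = [i for i in range(lo, hi) if i not in used]
        if not candidates:
            raise ValueError(
                f"session {s} has no free slot for a coursework task"
            )
        pick = int(rng.choice(candidates))
        type_of[pick] = "coursework"
        used.add(pick)
    return TaskCatalog(session_of=tuple(session_of), type_of=tuple(type_of))


def behavioural_theta(
    scenario: ScenarioConfig, label: str, catalog: TaskCatalog
) -> np.ndarray:
    """θ encoding one group's adherence style.

    Each task boosts its nominal successor (within- or between-session
    strength as appropriate); coursework tasks get a basal boost for
    groups that pull coursework early.  Zero adherence gives θ = 0, i.e.
    uniformly random orderings.
    """
    spec = _group(scenario, label)
    T = catalog.T
    theta = np.zeros((T, T))
    # start anchor: entering the course at task 1 is part of adherence,
    # otherwise the first pick would be uniform over all T tasks
    theta[0, 0] = max(spec.adherence_within, spec.adherence_between)
    for i in range(1, T):
        same = catalog.session(i) == catalog.session(i + 1)
        theta[i - 1, i] = (
            spec.adherence_within if same else spec.adherence_between
        )
    if spec.coursework_pull:
        for t in catalog.tasks_of_type("coursework"):
            theta[t - 1, t - 1] += spec.coursework_pull
    return theta


def _group(scenario: ScenarioConfig, label: str) -> GroupSpec:
    for g in scenario.groups:
        if g.label == label:
            return g
    raise KeyError(f"no group labelled {label!r}")


def _postprocess_sequence(
    seq: tuple[int, ...],
    spec: GroupSpec,
    scenario: ScenarioConfig,
    catalog: TaskCatalog,
    in_branch: bool,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    T = scenario.T
    work = list(seq)

    # branch: a stated subgroup skips the designated tasks entirely
    if in_branch:
        drop = set(scenario.branch_tasks)
        work = [t for t in work if t not in drop]

    # skip-rate curve: per-task drop probability rising along the course;
    # removal preserves the relative order of retained tasks
    s0, s1 = scenario.skip_rate_start, scenario.skip_rate_end
    kept = []
    for t in work:
        p_skip = s0 + (s1 - s0) * (t - 1) / max(T - 1, 1)
        if rng.random() >= p_skip:
            kept.append(t)
    work = kept

    # jump-ahead: relocate coursework earlier in the sequence
    if spec.jump_ahead_prob > 0:
        cw = set(catalog.tasks_of_type("coursework"))
        for t in [t for t in work if t in cw]:
            if rng.random() < spec.jump_ahead_prob:
                pos = work.index(t)
                new_pos = max(0, int(pos * spec.jump_ahead_fraction))
                work.insert(new_pos, work.pop(pos))

    # censoring: keep only the completed fraction of the remaining course
    frac = float(
        np.clip(rng.normal(spec.completion_mean, spec.completion_std), 0.0, 1.0)
    )
    n_keep = int(round(frac * len(work)))
    return tuple(work[:n_keep])


def simulate_cohort(
    scenario: ScenarioConfig, catalog: TaskCatalog | None = None
) -> tuple[Cohort, GroundTruth]:
    """Generate a behavioural synthetic cohort.

    Sequences are drawn from each group's θ, then post-processed by the
    branch rule, the rising skip-rate curve, coursework jump-ahead, and
    censoring; grades and per-task confidence responses are drawn per
    group.  Identical scenarios (including seed) give identical cohorts.
    """
    rng = np.random.default_rng(scenario.seed)
    if catalog is None:
        catalog = make_catalog(
            scenario.T,
            scenario.S,
            type_mix=scenario.type_mix,
            seed=scenario.seed,
            coursework_sessions=scenario.coursework_sessions,
        )
    if catalog.T != scenario.T or catalog.S != scenario.S:
        raise ValueError("catalog shape disagrees with scenario")

    thetas = {
        g.label: behavioural_theta(scenario, g.label, catalog)
        for g in scenario.groups
    }
    learners: list[LearnerRecord] = []
    group_of: dict[str, str] = {}
    for spec in scenario.groups:
        theta = thetas[spec.label]
        for i in range(spec.size):
            lid = f"{spec.label}-{i:03d}"
            in_branch = rng.random() < scenario.branch_fraction
            full = simulate_sequence(theta, rng=rng)
            seq = _postprocess_sequence(
                full, spec, scenario, catalog, in_branch, rng
            )
            grade = float(
                np.clip(rng.normal(spec.grade_mean, spec.grade_std), 0.0, 100.0)
            )
            confidence = {
                t: (
                    "confident"
                    if rng.random() < spec.confident_prob
                    else ("revisit" if rng.random() < 0.5 else "support")
                )
                for t in seq
            }
            learners.append(
                LearnerRecord(
                    learner_id=lid,
                    sequence=seq,
                    grade=grade,
                    confidence=confidence,
                )
            )
            group_of[lid] = spec.label
    cohort = Cohort(catalog, tuple(learners))
    return cohort, GroundTruth(
        thetas=thetas, group_of=group_of, mode="behavioural"
    )


def model_only_cohort(
    theta: np.ndarray,
    N: int,
    length: int | None = None,
    seed: int = 0,
    catalog: TaskCatalog | None = None,
    id_prefix: str = "m",
) -> tuple[Cohort, GroundTruth]:
    """N sequences drawn straight from the model — no skips, no censoring
    beyond the optional fixed length.  Used for recovery and oracle tests."""
    theta = np.asarray(theta, dtype=float)
    T = theta.shape[0]
    if catalog is None:
        catalog = TaskCatalog(
            session_of=(1,) * T, type_of=("reading_video",) * T
        )
    if catalog.T != T:
        raise ValueError("catalog size disagrees with theta")
    rng = np.random.default_rng(seed)
    learners = tuple(
        LearnerRecord(
            learner_id=f"{id_prefix}-{i:05d}",
            sequence=simulate_sequence(theta, length=length, rng=rng),
        )
        for i in range(N)
    )
    cohort = Cohort(catalog, learners)
    truth = GroundTruth(
        thetas={"all": theta},
        group_of={rec.learner_id: "all" for rec in learners},
        mode="model",
    )
    return cohort, truth


def scenario_from_yaml(path) -> ScenarioConfig:
    """Load a :class:`ScenarioConfig` from a YAML document.

    Top-level keys mirror the dataclass fields; ``groups`` is a list of
    mappings with :class:`GroupSpec` fields.
    """
    import yaml
    from pathlib import Path

    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError("scenario YAML must be a mapping")
    if "groups" in doc:
        doc["groups"] = tuple(GroupSpec(**g) for g in doc["groups"])
    for key in ("branch_tasks", "coursework_sessions"):
        if key in doc:
            doc[key] = tuple(doc[key])
    return ScenarioConfig(**doc)
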