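"""Core data model for ordered task-completion sequences.

A course is laid out as ``T`` tasks with a *nominal order* 1..T, grouped into
``S`` weekly sessions.  Each learner is described by the ordered set of
distinct tasks they completed — possibly skipping tasks and stopping early.
This module holds the catalog/learner/cohort containers, CSV ingestion and
validation, grade-quantile grouping, and prefix extraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TASK_TYPES",
    "CONFIDENCE_RESPONSES",
    "CohortValidationError",
    "TaskCatalog",
    "LearnerRecord",
    "Cohort",
    "GroupLabelling",
    "load_cohort",
    "split_by_grade_quantile",
    "prefix",
    "read_catalog",
    "write_catalog",
    "write_cohort",
    "read_cohort",
    "cohort_to_json",
    "cohort_from_json",
]

#: The six task categories a course layout may contain.
TASK_TYPES = (
    "coursework",
    "quiz",
    "multi_response_poll",
    "reading_video",
    "g_chart",
    "discussion_post",
)

#: Allowed end-of-session self-assessment responses.
CONFIDENCE_RESPONSES = ("confident", "revisit", "support")


class CohortValidationError(ValueError):
    """Raised when event logs or containers violate the sequence-data contract."""


@dataclass(frozen=True)
class TaskCatalog:
    """The nominal course design.

    Task IDs are exactly 1..T and the nominal rank of a task equals its ID.
    ``session_of[i]`` is the 1-based session of task ``i + 1``; sessions must
    form contiguous, non-decreasing blocks covering 1..S.
    """

    session_of: tuple[int, ...]
    type_of: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.session_of) != len(self.type_of):
            raise CohortValidationError("session and type vectors differ in length")
        if len(self.session_of) == 0:
            raise CohortValidationError("catalog must contain at least one task")
        sessions = self.session_of
        if sessions[0] != 1:
            raise CohortValidationError("task 1 must belong to session 1")
        for a, b in zip(sessions, sessions[1:]):
            if b < a or b > a + 1:
                raise CohortValidationError(
                    "session indices must be non-decreasing in nominal order "
                    "and contiguous"
                )
        for t in self.type_of:
            if t not in TASK_TYPES:
                raise CohortValidationError(f"unknown task type {t!r}")

    @property
    def T(self) -> int:
        """Number of tasks."""
        return len(self.session_of)

    @property
    def S(self) -> int:
        """Number of sessions."""
        return self.session_of[-1]

    def session(self, task_id: int) -> int:
        return self.session_of[task_id - 1]

    def tasks_in_session(self, session: int) -> tuple[int, ...]:
        return tuple(
            t for t, s in enumerate(self.session_of, start=1) if s == session
        )

    def tasks_of_type(self, task_type: str) -> tuple[int, ...]:
        return tuple(
            t for t, ty in enumerate(self.type_of, start=1) if ty == task_type
        )


@dataclass(frozen=True)
class LearnerRecord:
    """One learner: an ordered sequence of distinct completed task IDs plus
    optional grade (percentage), demographics, and confidence responses."""

    learner_id: str
    sequence: tuple[int, ...]
    grade: float | None = None
    demographics: Mapping[str, object] | None = None
    confidence: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.sequence)) != len(self.sequence):
            raise CohortValidationError(
                f"learner {self.learner_id!r}: task repeated in sequence"
            )
        if self.grade is not None and not (0.0 <= self.grade <= 100.0):
            raise CohortValidationError(
                f"learner {self.learner_id!r}: grade {self.grade} outside [0, 100]"
            )
        if self.confidence is not None:
            for task, resp in self.confidence.items():
                if resp not in CONFIDENCE_RESPONSES:
                    raise CohortValidationError(
                        f"learner {self.learner_id!r}: invalid confidence "
                        f"response {resp!r} for task {task}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Cohort:
    """A task catalog together with the ensemble of learner sequences."""

    catalog: TaskCatalog
    learners: tuple[LearnerRecord, ...]

    def __post_init__(self) -> None:
        if len(self.learners) == 0:
            raise CohortValidationError("cohort must contain at least one learner")
        ids = [rec.learner_id for rec in self.learners]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("learner IDs must be unique")
        valid = set(range(1, self.catalog.T + 1))
        for rec in self.learners:
            bad = set(rec.sequence) - valid
            if bad:
                raise CohortValidationError(
                    f"learner {rec.learner_id!r}: unknown task IDs {sorted(bad)}"
                )
            if rec.confidence is not None:
                bad = set(rec.confidence) - valid
                if bad:
                    raise CohortValidationError(
                        f"learner {rec.learner_id!r}: confidence responses for "
                        f"unknown task IDs {sorted(bad)}"
                    )

    @property
    def N(self) -> int:
        return len(self.learners)

    def learner(self, learner_id: str) -> LearnerRecord:
        for rec in self.learners:
            if rec.learner_id == learner_id:
                return rec
        raise KeyError(learner_id)

    def subset(self, learner_ids: Iterable[str]) -> "Cohort":
        wanted = set(learner_ids)
        return Cohort(
            self.catalog,
            tuple(rec for rec in self.learners if rec.learner_id in wanted),
        )


@dataclass(frozen=True)
class GroupLabelling:
    """A partial labelling of learners into named groups (e.g. g1 / g2)."""

    group_of: Mapping[str, str]
    description: str = ""

    def members(self, label: str) -> tuple[str, ...]:
        return tuple(sorted(k for k, v in self.group_of.items() if v == label))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.group_of.values())))


# ---------------------------------------------------------------------------
# Ingestion


def _order_events(group: pd.DataFrame, learner_id: str) -> pd.DataFrame:
    """Sort one learner's events: explicit order_index wins over timestamps;
    equal timestamps with no order column are refused rather than guessed."""
    if "order_index" in group.columns and group["order_index"].notna().all():
        return group.sort_values("order_index", kind="stable")
    if "timestamp" not in group.columns or group["timestamp"].isna().any():
        raise CohortValidationError(
            f"learner {learner_id!r}: events need either a complete "
            "order_index or a complete timestamp column"
        )
    ts = pd.to_datetime(group["timestamp"])
    if ts.duplicated().any():
        tied = ts[ts.duplicated(keep=False)].iloc[0]
        raise CohortValidationError(
            f"learner {learner_id!r}: tied timestamps at {tied}; "
            "supply an order_index column to disambiguate"
        )
    return group.assign(_ts=ts).sort_values("_ts", kind="stable")


def load_cohort(
    events: pd.DataFrame | str | Path,
    catalog: TaskCatalog,
    grades: pd.DataFrame | str | Path | None = None,
    confidence: pd.DataFrame | str | Path | None = None,
    demographics: pd.DataFrame | str | Path | None = None,
) -> Cohort:
    """Build a validated :class:`Cohort` from completion-event logs.

    Parameters
    ----------
    events
        Table (or CSV path) with columns ``learner_id``, ``task_id`` and
        ``timestamp`` (ISO-8601) and/or ``order_index``.  Repeated
        completions of a task keep the earliest event only.
    catalog
        The course design; every ``task_id`` must exist in it.
    grades, confidence, demographics
        Optional side tables: ``learner_id, grade``;
        ``learner_id, task_id, response``; ``learner_id, <columns...>``.
    """
    if not isinstance(events, pd.DataFrame):
        events = pd.read_csv(events)
    required = {"learner_id", "task_id"}
    missing = required - set(events.columns)
    if missing:
        raise CohortValidationError(f"events missing columns {sorted(missing)}")

    bad = ~events["task_id"].isin(range(1, catalog.T + 1))
    if bad.any():
        row = events.index[bad][0]
        raise CohortValidationError(
            f"events row {row}: unknown task_id "
            f"{events.loc[row, 'task_id']} (catalog has 1..{catalog.T})"
        )

    grade_of: dict[str, float] = {}
    if grades is not None:
        if not isinstance(grades, pd.DataFrame):
            grades = pd.read_csv(grades)
        grade_of = {
            str(r.learner_id): float(r.grade) for r in grades.itertuples()
        }

    conf_of: dict[str, dict[int, str]] = {}
    if confidence is not None:
        if not isinstance(confidence, pd.DataFrame):
            confidence = pd.read_csv(confidence)
        for r in confidence.itertuples():
            conf_of.setdefault(str(r.learner_id), {})[int(r.task_id)] = str(
                r.response
            )

    demo_of: dict[str, dict[str, object]] = {}
    if demographics is not None:
        if not isinstance(demographics, pd.DataFrame):
            demographics = pd.read_csv(demographics)
        for _, row in demographics.iterrows():
            lid = str(row["learner_id"])
            demo_of[lid] = {
                k: row[k] for k in demographics.columns if k != "learner_id"
            }

    learners = []
    for lid, group in events.groupby("learner_id", sort=True):
        lid = str(lid)
        ordered = _order_events(group, lid)
        seq: list[int] = []
        seen: set[int] = set()
        for task in ordered["task_id"]:
            task = int(task)
            if task not in seen:  # keep-first deduplication
                seen.add(task)
                seq.append(task)
        learners.append(
            LearnerRecord(
                learner_id=lid,
                sequence=tuple(seq),
                grade=grade_of.get(lid),
                demographics=demo_of.get(lid),
                confidence=conf_of.get(lid),
            )
        )
    return Cohort(catalog, tuple(learners))


# ---------------------------------------------------------------------------
# Grouping and prefixes


def split_by_grade_quantile(
    cohort: Cohort, fraction: float = 0.25
) -> GroupLabelling:
    """Label the top ``fraction`` of learners by grade as ``g1`` and the
    bottom ``fraction`` as ``g2``.

    Each group has exactly ``floor(N * fraction)`` members.  Learners are
    ranked by grade with learner_id as a lexicographic tie-break, so the
    split is deterministic and the two groups are always disjoint.
    """
    if not (0.0 < fraction <= 0.5):
        raise ValueError("fraction must lie in (0, 0.5]")
    ungraded = [rec.learner_id for rec in cohort.learners if rec.grade is None]
    if ungraded:
        raise CohortValidationError(
            f"learners without grades cannot be split: {ungraded}"
        )
    k = math.floor(cohort.N * fraction)
    if k == 0:
        raise ValueError(
            f"fraction {fraction} selects zero learners from N={cohort.N}"
        )
    ranked = sorted(cohort.learners, key=lambda r: (r.grade, r.learner_id))
    group_of = {rec.learner_id: "g2" for rec in ranked[:k]}
    group_of.update({rec.learner_id: "g1" for rec in ranked[-k:]})
    return GroupLabelling(
        group_of=group_of,
        description=f"grade quantile split, fraction={fraction}",
    )


def prefix(record: LearnerRecord, n: int) -> LearnerRecord:
    """First ``min(n, len(sequence))`` completed tasks, metadata carried over."""
    if n < 0:
        raise ValueError("prefix length must be non-negative")
    return replace(record, sequence=record.sequence[:n])


# ---------------------------------------------------------------------------
# Canonical CSV / JSON layouts


def read_catalog(path: str | Path) -> TaskCatalog:
    """Read ``catalog.csv`` (columns task_id, session, type)."""
    df = pd.read_csv(path).sort_values("task_id")
    ids = df["task_id"].tolist()
    if ids != list(range(1, len(ids) + 1)):
        raise CohortValidationError("catalog task IDs must be exactly 1..T")
    return TaskCatalog(
        session_of=tuple(int(s) for s in df["session"]),
        type_of=tuple(str(t) for t in df["type"]),
    )


def write_catalog(catalog: TaskCatalog, path: str | Path) -> None:
    pd.DataFrame(
        {
            "task_id": range(1, catalog.T + 1),
            "session": catalog.session_of,
            "type": catalog.type_of,
        }
    ).to_csv(path, index=False)


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Emit the canonical CSV layout: events.csv (with order_index),
    catalog.csv, grades.csv, confidence.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_catalog(cohort.catalog, directory / "catalog.csv")

    ev_rows = []
    grade_rows = []
    conf_rows = []
    for rec in cohort.learners:
        for idx, task in enumerate(rec.sequence, start=1):
            ev_rows.append((rec.learner_id, task, idx))
        if rec.grade is not None:
            grade_rows.append((rec.learner_id, rec.grade))
        if rec.confidence:
            for task in sorted(rec.confidence):
                conf_rows.append((rec.learner_id, task, rec.confidence[task]))
    pd.DataFrame(
        ev_rows, columns=["learner_id", "task_id", "order_index"]
    ).to_csv(directory / "events.csv", index=False)
    pd.DataFrame(grade_rows, columns=["learner_id", "grade"]).to_csv(
        directory / "grades.csv", index=False
    )
    pd.DataFrame(
        conf_rows, columns=["learner_id", "task_id", "response"]
    ).to_csv(directory / "confidence.csv", index=False)


def read_cohort(directory: str | Path) -> Cohort:
    """Inverse of :func:`write_cohort`."""
    directory = Path(directory)
    catalog = read_catalog(directory / "catalog.csv")
    grades = directory / "grades.csv"
    confidence = directory / "confidence.csv"

    def _nonempty(p: Path) -> pd.DataFrame | None:
        if not p.exists():
            return None
        df = pd.read_csv(p)
        return df if len(df) else None

    return load_cohort(
        directory / "events.csv",
        catalog,
        grades=_nonempty(grades),
        confidence=_nonempty(confidence),
    )


def cohort_to_json(cohort: Cohort, path: str | Path | None = None) -> str:
    """Serialize a cohort (catalog + learners) to a JSON document."""
    doc = {
        "catalog": {
            "session": list(cohort.catalog.session_of),
            "type": list(cohort.catalog.type_of),
        },
        "learners": [
            {
                "learner_id": rec.learner_id,
                "sequence": list(rec.sequence),
                "grade": rec.grade,
                "demographics": dict(rec.demographics)
                if rec.demographics
                else None,
                "confidence": {str(k): v for k, v in rec.confidence.items()}
                if rec.confidence
                else None,
            }
            for rec in cohort.learners
        ],
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def cohort_from_json(source: str | Path) -> Cohort:
    p = Path(str(source))
    text = p.read_text() if p.exists() else str(source)
    doc = json.loads(text)
    catalog = TaskCatalog(
        session_of=tuple(doc["catalog"]["session"]),
        type_of=tuple(doc["catalog"]["type"]),
    )
    learners = tuple(
        LearnerRecord(
            learner_id=entry["learner_id"],
            sequence=tuple(entry["sequence"]),
            grade=entry.get("grade"),
            demographics=entry.get("demographics"),
            confidence={int(k): v for k, v in entry["confidence"].items()}
            if entry.get("confidence")
            else None,
        )
        for entry in doc["learners"]
    )
    return Cohort(catalog, learners)
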