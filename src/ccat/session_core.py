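"""Shared trial/session framework for the task battery.

Every task — the four adaptive training programs and the four
decision-making assessments — is driven through the same contract:

* a :class:`RunSeed` derives an independent, reproducible random stream
  per (task, session), so adding or reordering tasks never perturbs the
  schedules of other tasks;
* a registered *runner* executes the task's trial loop against a
  responder agent and emits an ordered list of :class:`TrialEvent`;
* logs are serialized as JSON Lines (one event per line, versioned
  header) and can be re-scored offline.

Identical ``(seed, stream_id, config)`` with a deterministic agent
yields byte-identical serialized logs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from types import MappingProxyType
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LOG_FORMAT = "ccat-trial-log"
LOG_VERSION = 1

PRACTICE = "practice"
MAIN = "main"

FEEDBACK_GREEN = "green_check"
FEEDBACK_RED = "red_cross"
FEEDBACK_NONE = "none"


class CcatError(Exception):
    """Base class for all engine errors."""


class ConfigurationError(CcatError):
    """Invalid or infeasible task/study configuration."""


class InvalidStimulusError(CcatError):
    """A stimulus violates the task's structural rules."""


class ProtocolViolationError(CcatError):
    """An agent returned a response outside the task's response alphabet."""


class UndefinedScoreError(CcatError):
    """A score is undefined for the given log (e.g. empty main phase)."""


class LogIntegrityError(CcatError):
    """A trial log is corrupted or inconsistent with its schedule."""


class TaskId(str, Enum):
    """The eight tasks in the battery."""

    ABM = "ABM"          # attention bias modification training
    ACT = "ACT"          # attention control training
    NBACK = "NBACK"      # adaptive n-back working-memory training
    MATRIX = "MATRIX"    # spatial working-memory (memory matrix) training
    DDT = "DDT"          # delay discounting titration
    IGT = "IGT"          # Iowa gambling task
    BART = "BART"        # balloon analogue risk task
    STROOP = "STROOP"    # drug-word colour-naming Stroop

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


TRAINING_TASKS = (TaskId.ABM, TaskId.ACT, TaskId.NBACK, TaskId.MATRIX)
ASSESSMENT_TASKS = (TaskId.DDT, TaskId.IGT, TaskId.BART, TaskId.STROOP)


@dataclass(frozen=True)
class TrialEvent:
    """One stimulus-response record.

    ``correct`` is true iff ``given_response`` is non-null and equals
    ``correct_response``; training tasks give green-check / red-cross
    feedback accordingly, assessments give none. A timeout is logged
    with ``given_response=None`` and counts as incorrect.
    """

    task_id: str
    session_id: str
    trial_index: int
    phase: str
    stimulus: dict
    correct_response: str | None
    given_response: str | None
    latency_ms: float
    correct: bool
    feedback: str

    def to_dict(self) -> dict:
        return {
            "task_id": self.task_id,
            "session_id": self.session_id,
            "trial_index": self.trial_index,
            "phase": self.phase,
            "stimulus": self.stimulus,
            "correct_response": self.correct_response,
            "given_response": self.given_response,
            "latency_ms": self.latency_ms,
            "correct": self.correct,
            "feedback": self.feedback,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialEvent":
        try:
            return cls(**{k: d[k] for k in (
                "task_id", "session_id", "trial_index", "phase", "stimulus",
                "correct_response", "given_response", "latency_ms", "correct",
                "feedback")})
        except KeyError as exc:  # pragma: no cover - defensive
            raise LogIntegrityError(f"trial record missing field: {exc}") from exc


def make_event(
    task_id: TaskId | str,
    session_id: str,
    trial_index: int,
    phase: str,
    stimulus: dict,
    correct_response: str | None,
    given_response: str | None,
    latency_ms: float,
    *,
    training_feedback: bool = True,
) -> TrialEvent:
    """Build a :class:`TrialEvent`, deriving ``correct`` and feedback.

    ``training_feedback=False`` logs ``feedback="none"`` (assessments).
    """
    correct = given_response is not None and given_response == correct_response
    if training_feedback:
        feedback = FEEDBACK_GREEN if correct else FEEDBACK_RED
    else:
        feedback = FEEDBACK_NONE
    return TrialEvent(
        task_id=str(TaskId(task_id)),
        session_id=session_id,
        trial_index=int(trial_index),
        phase=phase,
        stimulus=dict(stimulus),
        correct_response=correct_response,
        given_response=given_response,
        latency_ms=float(latency_ms),
        correct=correct,
        feedback=feedback,
    )


def check_token(given: str | None, alphabet: Sequence[str], task_id: TaskId | str) -> None:
    """Raise :class:`ProtocolViolationError` for an out-of-alphabet response.

    ``None`` (timeout) is always admissible.
    """
    if given is not None and given not in alphabet:
        raise ProtocolViolationError(
            f"{task_id}: agent returned {given!r}, expected one of {tuple(alphabet)} or None"
        )


# ---------------------------------------------------------------------------
# Seeding


@dataclass(frozen=True)
class RunSeed:
    """Master seed plus a task/session-scoped stream identifier.

    Streams are derived by hashing ``stream_id`` (SHA-256) into extra
    entropy words for :class:`numpy.random.SeedSequence`, so each
    (task, session) stream is statistically independent and stable
    across platforms and battery composition.
    """

    seed: int
    stream_id: str = "root"

    def child(self, label: str) -> "RunSeed":
        return RunSeed(self.seed, f"{self.stream_id}/{label}")

    def rng(self) -> np.random.Generator:
        digest = hashlib.sha256(self.stream_id.encode("utf-8")).digest()
        words = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), *words]))


# ---------------------------------------------------------------------------
# Session plan


def _default_programs() -> Mapping[str, int]:
    return MappingProxyType({t.value: 2 for t in TRAINING_TASKS})


@dataclass(frozen=True)
class SessionPlan:
    """Training schedule: defaults reproduce the study protocol
    (20 sessions, five per week over 4 weeks, each of the four training
    programs run twice per session)."""

    n_sessions: int = 20
    sessions_per_week: int = 5
    programs_per_session: Mapping[str, int] = field(default_factory=_default_programs)

    def __post_init__(self) -> None:
        if self.n_sessions < 1 or self.sessions_per_week < 1:
            raise ConfigurationError("session counts must be positive")
        for task, reps in self.programs_per_session.items():
            TaskId(task)
            if reps < 0:
                raise ConfigurationError(f"negative repetitions for {task}")

    @property
    def weeks(self) -> float:
        return self.n_sessions / self.sessions_per_week


# ---------------------------------------------------------------------------
# Runner registry and session loop

Runner = Callable[[object, object, RunSeed, str], list[TrialEvent]]

_RUNNERS: dict[str, Runner] = {}


def register_runner(task_id: TaskId | str) -> Callable[[Runner], Runner]:
    def deco(fn: Runner) -> Runner:
        _RUNNERS[TaskId(task_id).value] = fn
        return fn
    return deco


def run_session(task_spec, agent, seed: RunSeed, session_id: str = "session-0") -> list[TrialEvent]:
    """Execute one run of a task against ``agent`` and return the full log.

    ``task_spec`` must expose a ``task_id`` attribute naming a registered
    task; the agent must implement the response contract of that task.
    The log ends when the task's termination rule fires (its configured
    trial budget, or the simulated-time budget when one is set).
    """
    task_id = getattr(task_spec, "task_id", None)
    if task_id is None or TaskId(task_id).value not in _RUNNERS:
        raise ConfigurationError(f"unknown or unregistered task_id: {task_id!r}")
    events = _RUNNERS[TaskId(task_id).value](task_spec, agent, seed, session_id)
    _check_log(events)
    return events


def _check_log(events: Sequence[TrialEvent]) -> None:
    last = -1
    for ev in events:
        if ev.trial_index <= last:
            raise LogIntegrityError(
                f"trial_index not strictly increasing at {ev.trial_index}")
        last = ev.trial_index


def session_accuracy(log: Sequence[TrialEvent]) -> float:
    """Proportion correct over main-phase trials (practice excluded).

    Raises :class:`UndefinedScoreError` when the log has no main-phase
    trials, mirroring the accuracy summary shown at the end of a
    training session.
    """
    main = [ev for ev in log if ev.phase == MAIN]
    if not main:
        raise UndefinedScoreError("log contains no main-phase trials")
    return sum(ev.correct for ev in main) / len(main)


# ---------------------------------------------------------------------------
# Log I/O


def dumps_event(ev: TrialEvent) -> str:
    return json.dumps(ev.to_dict(), sort_keys=True, separators=(",", ":"))


def write_log(events: Iterable[TrialEvent], path: str | Path) -> None:
    """Write a JSONL trial log with a versioned header line."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(json.dumps({"format": LOG_FORMAT, "version": LOG_VERSION},
                            sort_keys=True, separators=(",", ":")) + "\n")
        for ev in events:
            fh.write(dumps_event(ev) + "\n")


def read_log(path: str | Path) -> list[TrialEvent]:
    path = Path(path)
    events: list[TrialEvent] = []
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        try:
            header = json.loads(header_line)
        except json.JSONDecodeError as exc:
            raise LogIntegrityError(f"{path}: unreadable header") from exc
        if not isinstance(header, dict) or header.get("format") != LOG_FORMAT:
            raise LogIntegrityError(f"{path}: not a {LOG_FORMAT} file")
        if header.get("version") != LOG_VERSION:
            raise LogIntegrityError(f"{path}: unsupported log version {header.get('version')}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                events.append(TrialEvent.from_dict(json.loads(line)))
            except (json.JSONDecodeError, TypeError) as exc:
                raise LogIntegrityError(f"{path}:{lineno}: corrupt record") from exc
    _check_log(events)
    return events


def events_to_frame(events: Sequence[TrialEvent]) -> pd.DataFrame:
    """Flatten a log into a DataFrame; stimulus fields get a ``stim_`` prefix."""
    rows = []
    for ev in events:
        row = ev.to_dict()
        stim = row.pop("stimulus")
        for k, v in stim.items():
            row[f"stim_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
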