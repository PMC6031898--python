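"""The four training programs as explicit state machines.

* **ABM** — attention bias modification: judge whether the colour *named*
  by the word on the left matches the ink colour of the item on the
  right, while ignoring drug-related distractor content.
* **ACT** — attention control training: report the border colour of the
  picture (of the neutral picture when a drug-related one is also shown).
* **NBACK** — adaptive n-back (1- to 3-back) on shape+colour figures with
  a drug-picture distractor; level advances after two consecutive blocks
  at >=90% accuracy and never decreases.
* **MATRIX** — memory-matrix span task: recall highlighted grid cells;
  three successes in a row raise the span, three failures lower it.

Each task exposes its correct-response rule, its seeded schedule
generator, and a registered session runner that drives an agent through
the trial loop.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .lexicon import Lexicon, default_lexicon
from .session_core import (
    MAIN,
    PRACTICE,
    ConfigurationError,
    InvalidStimulusError,
    LogIntegrityError,
    RunSeed,
    TaskId,
    TrialEvent,
    check_token,
    make_event,
    register_runner,
)

COLORS = ("red", "yellow", "blue", "green")
SHAPES = ("triangle", "circle", "rectangle")
CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
YES = "yes"
NO = "no"

METH = "meth"
NEUTRAL = "neutral"


class TaskConfigBase(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


def exact_count(ratio: float, n: int, what: str) -> int:
    """Number of items implied by an exact balance ratio.

    Schedules are balanced by construction, so ``ratio * n`` must be
    (numerically) an integer; anything else is an infeasible request.
    """
    x = ratio * n
    if abs(x - round(x)) > 1e-9:
        raise ConfigurationError(
            f"infeasible balance: {what} ratio {ratio} of {n} trials is not an integer")
    return int(round(x))


def _other_color(color: str, rng: np.random.Generator) -> str:
    others = [c for c in COLORS if c != color]
    return others[int(rng.integers(len(others)))]


# ===========================================================================
# ABM — attention bias modification


class ABMConfig(TaskConfigBase):
    task_id: Literal["ABM"] = "ABM"
    n_practice: int = Field(20, ge=0)
    n_main: int = Field(120, ge=0)
    consistent_ratio: float = Field(0.5, ge=0.0, le=1.0)
    meth_distractor_rate: float = Field(1.0, ge=0.0, le=1.0)
    response_deadline_ms: float | None = None
    iti_ms: float = Field(500.0, ge=0.0)
    time_budget_s: float | None = Field(None, gt=0.0)


@dataclass(frozen=True)
class ABMStimulus:
    """Left box: a colour word (its own ink is irrelevant). Right box: a
    word item printed in some ink; the ink is what the left word is judged
    against. The drug-picture distractor never enters the rule."""

    left_word_meaning: str
    left_word_ink: str
    right_item_text_category: str   # meth_word | neutral_word
    right_item_ink: str
    distractor_picture_category: str  # meth | none
    right_item_token: str = ""
    distractor_token: str = ""

    def __post_init__(self) -> None:
        for c in (self.left_word_meaning, self.left_word_ink, self.right_item_ink):
            if c not in COLORS:
                raise InvalidStimulusError(f"colour {c!r} outside the 4-colour alphabet")
        if self.right_item_text_category not in ("meth_word", "neutral_word"):
            raise InvalidStimulusError("bad right-item category")
        if self.distractor_picture_category not in (METH, "none"):
            raise InvalidStimulusError("bad distractor category")

    def payload(self) -> dict:
        return {
            "left_word_meaning": self.left_word_meaning,
            "left_word_ink": self.left_word_ink,
            "right_item_text_category": self.right_item_text_category,
            "right_item_ink": self.right_item_ink,
            "distractor_picture_category": self.distractor_picture_category,
            "right_item_token": self.right_item_token,
            "distractor_token": self.distractor_token,
        }


def abm_correct_response(s: ABMStimulus) -> str:
    """``consistent`` iff the colour the left word *means* equals the ink
    of the right item; the left word's own ink and the distractor are
    ignored by the rule."""
    return CONSISTENT if s.left_word_meaning == s.right_item_ink else INCONSISTENT


def _abm_stimulus(rng: np.random.Generator, lexicon: Lexicon, *,
                  consistent: bool, meth: bool) -> ABMStimulus:
    meaning = COLORS[int(rng.integers(4))]
    right_ink = meaning if consistent else _other_color(meaning, rng)
    if meth:
        cat, pic = "meth_word", METH
        token = lexicon.sample("meth_word", rng)
        distractor = lexicon.sample("meth_picture", rng)
    else:
        cat, pic = "neutral_word", "none"
        token = lexicon.sample("neutral_word", rng)
        distractor = ""
    return ABMStimulus(
        left_word_meaning=meaning,
        left_word_ink=COLORS[int(rng.integers(4))],
        right_item_text_category=cat,
        right_item_ink=right_ink,
        distractor_picture_category=pic,
        right_item_token=token,
        distractor_token=distractor,
    )


def generate_abm_schedule(
    config: ABMConfig, rng: np.random.Generator, lexicon: Lexicon | None = None
) -> tuple[list[ABMStimulus], list[ABMStimulus]]:
    """Return ``(practice, main)`` stimulus lists.

    Practice trials carry no drug content; main trials carry a drug-word
    item and drug-picture distractor at ``meth_distractor_rate`` (exact
    count). Consistent/inconsistent trials are balanced exactly at
    ``consistent_ratio`` in each phase.
    """
    lexicon = lexicon or default_lexicon()

    def phase(n: int, *, meth_rate: float) -> list[ABMStimulus]:
        n_cons = exact_count(config.consistent_ratio, n, "ABM consistent")
        n_meth = exact_count(meth_rate, n, "ABM meth-distractor")
        cons_flags = np.array([True] * n_cons + [False] * (n - n_cons))
        meth_flags = np.array([True] * n_meth + [False] * (n - n_meth))
        rng.shuffle(cons_flags)
        rng.shuffle(meth_flags)
        return [_abm_stimulus(rng, lexicon, consistent=bool(c), meth=bool(m))
                for c, m in zip(cons_flags, meth_flags)]

    return phase(config.n_practice, meth_rate=0.0), phase(config.n_main, meth_rate=config.meth_distractor_rate)


# ===========================================================================
# ACT — attention control training


class ACTConfig(TaskConfigBase):
    task_id: Literal["ACT"] = "ACT"
    n_main: int = Field(240, ge=0)
    two_picture_ratio: float = Field(0.5, ge=0.0, le=1.0)
    response_deadline_ms: float | None = None
    iti_ms: float = Field(500.0, ge=0.0)
    time_budget_s: float | None = Field(None, gt=0.0)


@dataclass(frozen=True)
class ACTStimulus:
    """One picture, or a drug-related / neutral pair; the response is the
    border colour of the (single, or neutral) picture."""

    n_pictures: int
    picture_categories: tuple[str, ...]
    border_colors: tuple[str, ...]
    tokens: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_pictures not in (1, 2):
            raise InvalidStimulusError("n_pictures must be 1 or 2")
        if len(self.picture_categories) != self.n_pictures or len(self.border_colors) != self.n_pictures:
            raise InvalidStimulusError("category/border lists must parallel the pictures")
        for c in self.border_colors:
            if c not in COLORS:
                raise InvalidStimulusError(f"colour {c!r} outside the 4-colour alphabet")
        for cat in self.picture_categories:
            if cat not in (METH, NEUTRAL):
                raise InvalidStimulusError(f"bad picture category {cat!r}")

    def payload(self) -> dict:
        return {
            "n_pictures": self.n_pictures,
            "picture_categories": list(self.picture_categories),
            "border_colors": list(self.border_colors),
            "tokens": list(self.tokens),
        }


def act_correct_response(s: ACTStimulus) -> str:
    """Border colour of the single picture, or of the neutral picture
    when a drug-related picture competes with it."""
    if s.n_pictures == 1:
        return s.border_colors[0]
    if set(s.picture_categories) != {METH, NEUTRAL}:
        raise InvalidStimulusError(
            "two-picture trial must pair one drug-related and one neutral picture")
    return s.border_colors[s.picture_categories.index(NEUTRAL)]


def generate_act_schedule(
    config: ACTConfig, rng: np.random.Generator, lexicon: Lexicon | None = None
) -> list[ACTStimulus]:
    """240 main trials by default, one- and two-picture trials mixed
    exactly at ``two_picture_ratio``; single-picture trials split evenly
    between drug-related and neutral pictures."""
    lexicon = lexicon or default_lexicon()
    n = config.n_main
    n_two = exact_count(config.two_picture_ratio, n, "ACT two-picture")
    n_one = n - n_two
    kinds = ["two"] * n_two + ["one_meth"] * (n_one // 2 + n_one % 2) + ["one_neutral"] * (n_one // 2)
    kinds = list(np.array(kinds)[rng.permutation(n)]) if n else []
    out: list[ACTStimulus] = []
    for kind in kinds:
        if kind == "two":
            colors = rng.choice(len(COLORS), size=2, replace=False)
            cats = (METH, NEUTRAL) if rng.random() < 0.5 else (NEUTRAL, METH)
            toks = tuple(lexicon.sample(f"{c}_picture", rng) for c in cats)
            out.append(ACTStimulus(2, cats, (COLORS[colors[0]], COLORS[colors[1]]), toks))
        else:
            cat = METH if kind == "one_meth" else NEUTRAL
            out.append(ACTStimulus(
                1, (cat,), (COLORS[int(rng.integers(4))],),
                (lexicon.sample(f"{cat}_picture", rng),)))
    return out


# ===========================================================================
# NBACK — adaptive n-back


class NBackConfig(TaskConfigBase):
    task_id: Literal["NBACK"] = "NBACK"
    n_blocks: int = Field(4, ge=1)
    block_size: int = Field(20, ge=1)          # scored trials per block
    target_rate: float = Field(0.3, ge=0.0, le=1.0)
    start_level: int = Field(1, ge=1, le=3)
    max_level: int = Field(3, ge=1, le=3)
    accuracy_threshold: float = Field(0.90, ge=0.0, le=1.0)
    blocks_to_advance: int = Field(2, ge=1)
    response_deadline_ms: float | None = None
    iti_ms: float = Field(500.0, ge=0.0)
    time_budget_s: float | None = Field(None, gt=0.0)


@dataclass(frozen=True)
class NBackStimulus:
    """A shape+colour figure on the right (target stream); a drug-related
    picture sits on the left as a distractor."""

    figure_shape: str
    figure_color: str
    distractor_category: str = METH
    distractor_token: str = ""

    def __post_init__(self) -> None:
        if self.figure_shape not in SHAPES or self.figure_color not in COLORS:
            raise InvalidStimulusError("figure outside the shape/colour alphabet")

    @property
    def figure(self) -> tuple[str, str]:
        return (self.figure_shape, self.figure_color)

    def payload(self) -> dict:
        return {
            "figure_shape": self.figure_shape,
            "figure_color": self.figure_color,
            "distractor_category": self.distractor_category,
            "distractor_token": self.distractor_token,
            "target_position": "right",
            "distractor_position": "left",
        }


FIGURES = tuple(itertools.product(SHAPES, COLORS))


@dataclass(frozen=True)
class NBackState:
    """Adaptive level state; the level only ever moves up (to 3)."""

    level: int = 1
    success_streak: int = 0
    max_level: int = 3


def nback_correct_response(history: Sequence[NBackStimulus], level: int) -> str | None:
    """``yes`` iff the newest figure matches — in both shape and colour —
    the figure ``level`` positions earlier. Returns ``None`` for warm-up
    positions (fewer than ``level`` predecessors): those are unscored."""
    if len(history) <= level:
        return None
    return YES if history[-1].figure == history[-1 - level].figure else NO


def nback_update_level(state: NBackState, block_accuracy: float, *,
                       threshold: float = 0.90, blocks_to_advance: int = 2) -> NBackState:
    """Level advances after ``blocks_to_advance`` consecutive blocks at
    or above ``threshold`` accuracy, capped at ``state.max_level``;
    a sub-threshold block resets the streak. The level never decreases."""
    streak = state.success_streak + 1 if block_accuracy >= threshold else 0
    level = state.level
    if streak >= blocks_to_advance:
        level = min(level + 1, state.max_level)
        streak = 0
    return replace(state, level=level, success_streak=streak)


def generate_nback_block(
    config: NBackConfig, level: int, rng: np.random.Generator,
    lexicon: Lexicon | None = None,
) -> list[NBackStimulus]:
    """A block of ``level + block_size`` stimuli whose scored positions
    contain exactly ``round(target_rate * block_size)`` targets."""
    lexicon = lexicon or default_lexicon()
    n_targets = exact_count(config.target_rate, config.block_size, "n-back target")
    length = level + config.block_size
    target_pos = set(level + rng.choice(config.block_size, size=n_targets, replace=False))
    figures: list[tuple[str, str]] = []
    for i in range(length):
        if i in target_pos:
            figures.append(figures[i - level])
        else:
            fig = FIGURES[int(rng.integers(len(FIGURES)))]
            # lure avoidance: a non-target must differ from the figure n back
            while i >= level and fig == figures[i - level]:
                fig = FIGURES[int(rng.integers(len(FIGURES)))]
            figures.append(fig)
    return [
        NBackStimulus(shape, color, distractor_token=lexicon.sample("meth_picture", rng))
        for shape, color in figures
    ]


def nback_block_trajectory(log: Sequence[TrialEvent], config: NBackConfig | None = None):
    """Replay a logged n-back session: per-block levels and accuracies,
    plus the adaptive state after the final block's update."""
    config = config or NBackConfig()
    blocks: dict[int, list[TrialEvent]] = {}
    for ev in log:
        blocks.setdefault(int(ev.stimulus["block"]), []).append(ev)
    levels, accuracies = [], []
    state = NBackState(level=config.start_level, max_level=config.max_level)
    for b in sorted(blocks):
        evs = blocks[b]
        level = int(evs[0].stimulus["level"])
        if level != state.level:
            raise LogIntegrityError(f"block {b} logged at level {level}, replay says {state.level}")
        acc = sum(e.correct for e in evs) / len(evs)
        levels.append(level)
        accuracies.append(acc)
        state = nback_update_level(state, acc, threshold=config.accuracy_threshold,
                                   blocks_to_advance=config.blocks_to_advance)
    return levels, accuracies, state


# ===========================================================================
# MATRIX — memory matrix


class MatrixConfig(TaskConfigBase):
    task_id: Literal["MATRIX"] = "MATRIX"
    n_main: int = Field(40, ge=0)
    start_span: int = Field(3, ge=1)
    span_min: int = Field(2, ge=1)
    streak_len: int = Field(3, ge=1)
    grid_rows: int = Field(5, ge=2)
    grid_cols: int = Field(5, ge=2)
    big_grid_threshold: int = Field(8, ge=1)   # span above which the grid grows
    big_grid_rows: int = Field(6, ge=2)
    big_grid_cols: int = Field(6, ge=2)
    exposure_s: float = Field(3.0, gt=0.0)
    response_window_s: float = Field(3.0, gt=0.0)
    pattern_preview_s: float = Field(1.0, gt=0.0)
    iti_ms: float = Field(500.0, ge=0.0)
    time_budget_s: float | None = Field(None, gt=0.0)


@dataclass(frozen=True)
class MatrixState:
    """Span staircase state; success and failure streaks are mutually
    exclusive by construction."""

    span: int = 3
    success_streak: int = 0
    failure_streak: int = 0
    span_min: int = 2


@dataclass(frozen=True)
class MatrixTrial:
    grid_dims: tuple[int, int]
    target_cells: frozenset[tuple[int, int]]
    exposure_s: float = 3.0
    response_window_s: float = 3.0
    pattern_preview_s: float = 1.0

    def __post_init__(self) -> None:
        rows, cols = self.grid_dims
        for r, c in self.target_cells:
            if not (0 <= r < rows and 0 <= c < cols):
                raise InvalidStimulusError(f"cell ({r},{c}) outside a {rows}x{cols} grid")


def matrix_update_span(state: MatrixState, trial_success: bool, *,
                       streak_len: int = 3) -> MatrixState:
    """Three successes in a row raise the span by one, three failures
    lower it by one (floored at ``span_min``); either event resets both
    streaks."""
    if trial_success:
        s, f = state.success_streak + 1, 0
    else:
        s, f = 0, state.failure_streak + 1
    span = state.span
    if s >= streak_len:
        span, s = span + 1, 0
    elif f >= streak_len:
        span, f = max(span - 1, state.span_min), 0
    return replace(state, span=span, success_streak=s, failure_streak=f)


def grid_for_span(config: MatrixConfig, span: int) -> tuple[int, int]:
    if span > config.big_grid_threshold:
        return (config.big_grid_rows, config.big_grid_cols)
    return (config.grid_rows, config.grid_cols)


def generate_matrix_trial(state: MatrixState, config: MatrixConfig,
                          rng: np.random.Generator) -> MatrixTrial:
    rows, cols = grid_for_span(config, state.span)
    if state.span > rows * cols:
        raise ConfigurationError(f"span {state.span} exceeds grid capacity {rows * cols}")
    flat = rng.choice(rows * cols, size=state.span, replace=False)
    cells = frozenset((int(i) // cols, int(i) % cols) for i in flat)
    return MatrixTrial(
        grid_dims=(rows, cols),
        target_cells=cells,
        exposure_s=config.exposure_s,
        response_window_s=config.response_window_s,
        pattern_preview_s=config.pattern_preview_s,
    )


def cells_token(cells) -> str:
    """Canonical response token for a set of grid cells."""
    return ";".join(f"{r},{c}" for r, c in sorted(cells))


def parse_cells_token(token: str) -> frozenset[tuple[int, int]]:
    if not token:
        return frozenset()
    out = set()
    for part in token.split(";"):
        r, c = part.split(",")
        out.add((int(r), int(c)))
    return frozenset(out)


# ===========================================================================
# Session runners


class _Budget:
    """Deterministic simulated-time budget: accumulates agent latencies
    plus the inter-trial interval. ``None`` seconds means unbounded."""

    def __init__(self, seconds: float | None, iti_ms: float) -> None:
        self.remaining = seconds
        self.iti_s = iti_ms / 1000.0

    def spend(self, latency_ms: float) -> None:
        if self.remaining is not None:
            self.remaining -= latency_ms / 1000.0 + self.iti_s

    @property
    def exhausted(self) -> bool:
        return self.remaining is not None and self.remaining <= 0


def _deadline(given: str | None, latency: float, deadline_ms: float | None):
    """Apply a response deadline: overrunning it is a timeout (incorrect,
    null response), logged at the deadline latency."""
    if deadline_ms is not None and latency > deadline_ms:
        return None, float(deadline_ms)
    return given, latency


@register_runner(TaskId.ABM)
def run_abm(config: ABMConfig, agent, seed: RunSeed, session_id: str) -> list[TrialEvent]:
    rng = seed.rng()
    practice, main = generate_abm_schedule(config, rng)
    budget = _Budget(config.time_budget_s, config.iti_ms)
    events: list[TrialEvent] = []
    idx = 0
    for phase, stims in ((PRACTICE, practice), (MAIN, main)):
        for stim in stims:
            if phase == MAIN and budget.exhausted:
                return events
            correct = abm_correct_response(stim)
            category = METH if stim.distractor_picture_category == METH else None
            given, latency = agent.respond(
                TaskId.ABM, stim.payload(), correct, (CONSISTENT, INCONSISTENT),
                rng, level=1, category=category)
            check_token(given, (CONSISTENT, INCONSISTENT), TaskId.ABM)
            given, latency = _deadline(given, latency, config.response_deadline_ms)
            events.append(make_event(TaskId.ABM, session_id, idx, phase,
                                     stim.payload(), correct, given, latency))
            budget.spend(latency)
            idx += 1
    return events


@register_runner(TaskId.ACT)
def run_act(config: ACTConfig, agent, seed: RunSeed, session_id: str) -> list[TrialEvent]:
    rng = seed.rng()
    schedule = generate_act_schedule(config, rng)
    budget = _Budget(config.time_budget_s, config.iti_ms)
    events: list[TrialEvent] = []
    for idx, stim in enumerate(schedule):
        if budget.exhausted:
            break
        correct = act_correct_response(stim)
        category = METH if METH in stim.picture_categories else None
        given, latency = agent.respond(TaskId.ACT, stim.payload(), correct, COLORS,
                                       rng, level=1, category=category)
        check_token(given, COLORS, TaskId.ACT)
        given, latency = _deadline(given, latency, config.response_deadline_ms)
        events.append(make_event(TaskId.ACT, session_id, idx, MAIN,
                                 stim.payload(), correct, given, latency))
        budget.spend(latency)
    return events


@register_runner(TaskId.NBACK)
def run_nback(config: NBackConfig, agent, seed: RunSeed, session_id: str) -> list[TrialEvent]:
    """Blocks are generated at the current level; warm-up positions
    (fewer than ``level`` predecessors) present stimuli but emit no
    scored trial. Level updates fire at block boundaries."""
    rng = seed.rng()
    lexicon = default_lexicon()
    state = NBackState(level=config.start_level, max_level=config.max_level)
    budget = _Budget(config.time_budget_s, config.iti_ms)
    events: list[TrialEvent] = []
    idx = 0
    for block in range(config.n_blocks):
        if budget.exhausted:
            break
        seq = generate_nback_block(config, state.level, rng, lexicon)
        history: list[NBackStimulus] = []
        n_correct = 0
        n_scored = 0
        for stim in seq:
            history.append(stim)
            correct = nback_correct_response(history, state.level)
            if correct is None:
                continue  # warm-up: stimulus shown, nothing scored
            given, latency = agent.respond(
                TaskId.NBACK, stim.payload(), correct, (YES, NO),
                rng, level=state.level, category=METH)
            check_token(given, (YES, NO), TaskId.NBACK)
            given, latency = _deadline(given, latency, config.response_deadline_ms)
            payload = dict(stim.payload(), level=state.level, block=block)
            ev = make_event(TaskId.NBACK, session_id, idx, MAIN,
                            payload, correct, given, latency)
            events.append(ev)
            budget.spend(latency)
            n_correct += ev.correct
            n_scored += 1
            idx += 1
        if n_scored:
            state = nback_update_level(
                state, n_correct / n_scored,
                threshold=config.accuracy_threshold,
                blocks_to_advance=config.blocks_to_advance)
    return events


@register_runner(TaskId.MATRIX)
def run_matrix(config: MatrixConfig, agent, seed: RunSeed, session_id: str) -> list[TrialEvent]:
    rng = seed.rng()
    state = MatrixState(span=config.start_span, span_min=config.span_min)
    budget = _Budget(config.time_budget_s, config.iti_ms)
    events: list[TrialEvent] = []
    for idx in range(config.n_main):
        if budget.exhausted:
            break
        trial = generate_matrix_trial(state, config, rng)
        correct = cells_token(trial.target_cells)

        def wrong_response(wrng: np.random.Generator, _trial=trial) -> str:
            # perturb one target cell into a random non-target cell
            rows, cols = _trial.grid_dims
            cells = sorted(_trial.target_cells)
            drop = int(wrng.integers(len(cells)))
            pool = [(r, c) for r in range(rows) for c in range(cols)
                    if (r, c) not in _trial.target_cells]
            add = pool[int(wrng.integers(len(pool)))]
            return cells_token([c for i, c in enumerate(cells) if i != drop] + [add])

        payload = {
            "rows": trial.grid_dims[0], "cols": trial.grid_dims[1],
            "target_cells": correct, "span": state.span,
            "exposure_s": trial.exposure_s,
            "response_window_s": trial.response_window_s,
            "pattern_preview_s": trial.pattern_preview_s,
        }
        given, latency = agent.respond(TaskId.MATRIX, payload, correct, wrong_response,
                                       rng, level=state.span, category=METH)
        given, latency = _deadline(given, latency, config.response_window_s * 1000.0)
        ev = make_event(TaskId.MATRIX, session_id, idx, MAIN,
                        payload, correct, given, latency)
        events.append(ev)
        budget.spend(latency)
        state = matrix_update_span(state, ev.correct, streak_len=config.streak_len)
    return events
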