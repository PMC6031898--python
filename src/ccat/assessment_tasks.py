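"""The four outcome assessments: schedule generators, run protocols,
and scoring.

* **DDT** — delay-discounting titration. The delayed reward A (1000
  currency units) is fixed; the immediate offer starts at 500 and moves
  by successively halved steps (a decreasing-adjustment staircase) until
  an indifference point V(D) is recorded for each delay D in
  {2, 7, 30, 90, 180, 360} days. The hyperbolic decay model
  V = A / (1 + kD) turns indifference points into a per-day discount
  rate k (and ln k); a global k is least-squares fit across delays.
* **IGT** — Iowa gambling task with the canonical four-deck payoff
  structure (A/B: large wins, larger losses, net -250 per 10 picks;
  C/D: small wins, net +250 per 10 picks). Outcome: net score
  (advantageous minus disadvantageous picks).
* **BART** — balloon analogue risk task: 100 balloons, explosion point
  drawn uniformly on {1..max_pumps}; scored as pumps per unexploded
  balloon (literal reading), with the standard adjusted variant exposed
  alongside.
* **STROOP** — drug-word Stroop: 8 drug-related + 8 neutral words, each
  shown 8 times balanced over 4 ink colours (128 trials); attention bias
  is mean correct RT on drug words minus mean correct RT on neutral
  words.

Offer arithmetic in the titration uses exact rationals so recorded
indifference points like 7.8125 are exact, never floating-point noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import optimize
from pydantic import Field, model_validator

from .lexicon import Lexicon, default_lexicon
from .session_core import (
    MAIN,
    ConfigurationError,
    ProtocolViolationError,
    RunSeed,
    TaskId,
    TrialEvent,
    UndefinedScoreError,
    check_token,
    make_event,
    register_runner,
)
from .training_tasks import COLORS, TaskConfigBase, exact_count

IMMEDIATE = "immediate"
DELAYED = "delayed"


def _frac(x) -> Fraction:
    """Exact rational from an int/float/str currency amount."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(x))


# ===========================================================================
# DDT


class DDTConfig(TaskConfigBase):
    task_id: Literal["DDT"] = "DDT"
    delayed_amount: float = 1000.0
    initial_immediate: float = 500.0
    delays_days: tuple[int, ...] = (2, 7, 30, 90, 180, 360)
    n_adjustments: int = Field(6, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "DDTConfig":
        if not self.initial_immediate < self.delayed_amount:
            raise ValueError("initial immediate offer must be below the delayed amount")
        if any(b <= a for a, b in zip(self.delays_days, self.delays_days[1:])):
            raise ValueError("delays must be strictly increasing")
        return self


@dataclass(frozen=True)
class TitrationState:
    """Snapshot of the staircase at one trial."""

    delay_days: int
    immediate: Fraction
    step: Fraction
    trials_done: int


@dataclass(frozen=True)
class DDTResult:
    indifference_points: dict[int, float]
    k_by_delay: dict[int, float]
    ln_k_by_delay: dict[int, float]
    k_global: float
    ln_k_global: float


def ddt_titrate(
    choice_fn: Callable[[float, float, int], str],
    cfg: DDTConfig,
    delay_days: int,
    on_trial: Callable[[TitrationState, str], None] | None = None,
) -> Fraction:
    """Run the decreasing-adjustment staircase for one delay.

    Trial 1 offers ``initial_immediate``; after each choice the offer is
    decreased (immediate chosen) or increased (delayed chosen) by the
    current step, which starts at half the initial offer and halves
    after every trial. After ``n_adjustments`` trials the final adjusted
    offer is the indifference point V(D).
    """
    immediate = _frac(cfg.initial_immediate)
    amount = _frac(cfg.delayed_amount)
    step = immediate / 2
    for t in range(cfg.n_adjustments):
        choice = choice_fn(float(immediate), float(amount), delay_days)
        if choice not in (IMMEDIATE, DELAYED):
            raise ProtocolViolationError(f"DDT: bad choice token {choice!r}")
        if on_trial is not None:
            on_trial(TitrationState(delay_days, immediate, step, t), choice)
        immediate = immediate - step if choice == IMMEDIATE else immediate + step
        step /= 2
    return immediate


def hyperbolic_k(V: float, A: float, D: float) -> float:
    """Discount rate implied by one indifference point under the
    hyperbolic decay model: the unique k with V = A / (1 + kD),
    i.e. k = (A - V) / (V * D). V = A means no discounting (k = 0)."""
    if D <= 0:
        raise ConfigurationError("delay must be positive")
    if V <= 0:
        raise UndefinedScoreError("indifference point <= 0: k undefined (not clamped)")
    if V > A:
        raise UndefinedScoreError("indifference point above the delayed amount")
    return (A - V) / (V * D)


def fit_global_k(indifference_points: Mapping[float, float], A: float) -> float:
    """Least-squares fit of V = A / (1 + kD) across delays (k >= 0).

    With a single point this reduces exactly to :func:`hyperbolic_k`.
    """
    if not indifference_points:
        raise ConfigurationError("need at least one indifference point")
    delays = np.array(sorted(indifference_points), dtype=float)
    values = np.array([indifference_points[d] for d in sorted(indifference_points)], dtype=float)
    if np.any(values <= 0) or np.any(values > A):
        raise UndefinedScoreError("indifference points must lie in (0, A]")
    if len(delays) == 1:
        return hyperbolic_k(values[0], A, delays[0])
    if np.allclose(values, A):
        return 0.0
    point_ks = (A - values) / (values * delays)
    x0 = max(float(np.median(point_ks)), 1e-12)

    def residuals(k):
        return values - A / (1.0 + k[0] * delays)

    sol = optimize.least_squares(residuals, x0=[x0], bounds=([0.0], [np.inf]),
                                 xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return float(sol.x[0])


@register_runner(TaskId.DDT)
def run_ddt(cfg: DDTConfig, agent, seed: RunSeed, session_id: str) -> list[TrialEvent]:
    """Titrate each delay in ascending order, logging one event per
    choice trial. Choice tasks have no normative answer, so events carry
    ``correct_response == given_response`` and no feedback."""
    rng = seed.rng()
    events: list[TrialEvent] = []
    idx = 0

    for delay in cfg.delays_days:
        def log_trial(state: TitrationState, choice: str) -> None:
            nonlocal idx
            payload = {
                "delay_days": state.delay_days,
                "immediate": float(state.immediate),
                "delayed_amount": float(cfg.delayed_amount),
                "step": float(state.step),
                "titration_trial": state.trials_done,
            }
            events.append(make_event(TaskId.DDT, session_id, idx, MAIN, payload,
                                     choice, choice, 0.0, training_feedback=False))
            idx += 1

        ddt_titrate(lambda imm, A, D: agent.ddt_choose(imm, A, D, rng),
                    cfg, delay, on_trial=log_trial)
    return events


def score_ddt(log: Sequence[TrialEvent], cfg: DDTConfig | None = None) -> DDTResult:
    """Re-score a DDT log by replaying the staircase from the recorded
    choices (the arithmetic is deterministic, so the logged offers are
    verified against the replay)."""
    cfg = cfg or DDTConfig()
    by_delay: dict[int, list[TrialEvent]] = {}
    for ev in log:
        if ev.task_id != TaskId.DDT.value:
            raise ConfigurationError("score_ddt expects a DDT log")
        by_delay.setdefault(int(ev.stimulus["delay_days"]), []).append(ev)

    amount = float(cfg.delayed_amount)
    points: dict[int, float] = {}
    for delay, evs in by_delay.items():
        evs = sorted(evs, key=lambda e: e.trial_index)
        if len(evs) != cfg.n_adjustments:
            raise UndefinedScoreError(
                f"delay {delay}: {len(evs)} trials, expected {cfg.n_adjustments}")
        immediate = _frac(cfg.initial_immediate)
        step = immediate / 2
        for ev in evs:
            if not math.isclose(ev.stimulus["immediate"], float(immediate), abs_tol=1e-9):
                raise UndefinedScoreError(
                    f"delay {delay}: logged offer {ev.stimulus['immediate']} "
                    f"inconsistent with staircase replay {float(immediate)}")
            immediate = immediate - step if ev.given_response == IMMEDIATE else immediate + step
            step /= 2
        points[delay] = float(immediate)

    k_by_delay = {d: hyperbolic_k(v, amount, d) for d, v in points.items()}
    ln_k = {d: (math.log(k) if k > 0 else float("-inf")) for d, k in k_by_delay.items()}
    k_global = fit_global_k(points, amount)
    return DDTResult(
        indifference_points=points,
        k_by_delay=k_by_delay,
        ln_k_by_delay=ln_k,
        k_global=k_global,
        ln_k_global=math.log(k_global) if k_global > 0 else float("-inf"),
    )


# ===========================================================================
# IGT


# Canonical per-10-pick loss magnitudes. High-win decks net -250 per 10
# picks, low-win decks net +250; one deck of each pair loses frequently
# in small amounts, the other rarely in one large amount.
_FREQUENT_HIGH = (150, 200, 250, 300, 350)
_RARE_HIGH = (1250,)
_FREQUENT_LOW = (25, 75, 50, 50, 50)
_RARE_LOW = (250,)


class IGTConfig(TaskConfigBase):
    task_id: Literal["IGT"] = "IGT"
    n_trials: int = Field(150, ge=1)
    win_high: int = 100
    win_low: int = 50
    advantageous: tuple[str, str] = ("C", "D")
    block: int = Field(10, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "IGTConfig":
        if not set(self.advantageous) <= {"A", "B", "C", "D"} or len(set(self.advantageous)) != 2:
            raise ValueError("advantageous must name two distinct decks among A-D")
        return self

    @property
    def decks(self) -> tuple[str, ...]:
        return ("A", "B", "C", "D")

    @property
    def disadvantageous(self) -> tuple[str, ...]:
        return tuple(d for d in self.decks if d not in self.advantageous)


@dataclass(frozen=True)
class IGTSchedule:
    """Per-deck payoff sequences, long enough that no deck can run dry."""

    decks: dict[str, list[tuple[int, int]]]   # deck -> [(win, loss), ...]
    n_trials: int


def generate_igt_schedule(cfg: IGTConfig, rng: np.random.Generator) -> IGTSchedule:
    """Canonical payoff structure: within every block of ``cfg.block``
    cards per deck, loss positions are shuffled under the seed while the
    block's win/loss totals are fixed by construction."""
    n_blocks = -(-cfg.n_trials // cfg.block)  # ceil
    dis = cfg.disadvantageous
    adv = cfg.advantageous
    profiles = {
        dis[0]: (cfg.win_high, _FREQUENT_HIGH),
        dis[1]: (cfg.win_high, _RARE_HIGH),
        adv[0]: (cfg.win_low, _FREQUENT_LOW),
        adv[1]: (cfg.win_low, _RARE_LOW),
    }
    decks: dict[str, list[tuple[int, int]]] = {}
    for deck in cfg.decks:
        win, losses = profiles[deck]
        if len(losses) > cfg.block:
            raise ConfigurationError("loss profile longer than the deck block")
        cards: list[tuple[int, int]] = []
        for _ in range(n_blocks):
            block_losses = [0] * cfg.block
            for pos, loss in zip(rng.choice(cfg.block, size=len(losses), replace=False), losses):
                block_losses[int(pos)] = loss
            cards.extend((win, l) for l in block_losses)
        decks[deck] = cards
    return IGTSchedule(decks=decks, n_trials=cfg.n_trials)


def igt_net_score(choices: Sequence[str], advantageous: Sequence[str] = ("C", "D")) -> int:
    """Net score: picks from the advantageous decks minus picks from the
    disadvantageous decks; positive means a tendency toward good
    decisions."""
    adv = set(advantageous)
    bad = {"A", "B", "C", "D"} - adv
    n_adv = n_dis = 0
    for c in choices:
        if c in adv:
            n_adv += 1
        elif c in bad:
            n_dis += 1
        else:
            raise ConfigurationError(f"unknown deck label {c!r}")
    return n_adv - n_dis


@register_runner(TaskId.IGT)
def run_igt(cfg: IGTConfig, agent, seed: RunSeed, session_id: str) -> list[TrialEvent]:
    rng = seed.rng()
    schedule = generate_igt_schedule(cfg, rng)
    chooser = agent.igt_session(rng)
    counters = {d: 0 for d in cfg.decks}
    events: list[TrialEvent] = []
    for idx in range(cfg.n_trials):
        deck = chooser.pick(rng)
        check_token(deck, cfg.decks, TaskId.IGT)
        if deck is None:
            raise ProtocolViolationError("IGT: agent may not time out")
        win, loss = schedule.decks[deck][counters[deck]]
        counters[deck] += 1
        chooser.observe(deck, win - loss)
        payload = {"trial": idx, "win": win, "loss": loss, "net": win - loss}
        events.append(make_event(TaskId.IGT, session_id, idx, MAIN, payload,
                                 deck, deck, 0.0, training_feedback=False))
    return events


def igt_choices_from_events(log: Sequence[TrialEvent]) -> list[str]:
    return [ev.given_response for ev in log if ev.task_id == TaskId.IGT.value]


# ===========================================================================
# BART


class BARTConfig(TaskConfigBase):
    task_id: Literal["BART"] = "BART"
    n_balloons: int = Field(100, ge=1)
    max_pumps: int = Field(128, ge=1)
    points_per_pump: int = Field(10, ge=0)


@dataclass(frozen=True)
class BARTSchedule:
    explosion_points: tuple[int, ...]
    max_pumps: int

    def __post_init__(self) -> None:
        for p in self.explosion_points:
            if not 1 <= p <= self.max_pumps:
                raise ConfigurationError("explosion point outside {1..max_pumps}")


def generate_bart_schedule(cfg: BARTConfig, rng: np.random.Generator) -> BARTSchedule:
    """Explosion point of each balloon drawn uniformly on
    {1..max_pumps}, fixed before the run."""
    points = rng.integers(1, cfg.max_pumps + 1, size=cfg.n_balloons)
    return BARTSchedule(tuple(int(p) for p in points), cfg.max_pumps)


@dataclass(frozen=True)
class BartScore:
    literal: float        # all pumps / unexploded balloons (primary)
    adjusted: float       # pumps on unexploded balloons / unexploded balloons
    points: int           # 10 * pumps banked on unexploded balloons
    n_exploded: int
    n_unexploded: int
    undefined: bool = False


def bart_score(balloons: Sequence[tuple[int, bool]], points_per_pump: int = 10) -> BartScore:
    """Score a run from per-balloon ``(pumps, exploded)`` records.

    The primary score divides *all* pumps by the number of unexploded
    balloons (the literal reading of the score formula); the ``adjusted``
    variant restricts the numerator to unexploded balloons, which is the
    conventional adjusted-pumps index. With zero unexploded balloons both
    are undefined and flagged rather than clamped.
    """
    n_expl = sum(1 for _, e in balloons if e)
    n_unexpl = len(balloons) - n_expl
    banked = sum(p for p, e in balloons if not e)
    total = sum(p for p, _ in balloons)
    points = points_per_pump * banked
    if n_unexpl == 0:
        return BartScore(float("nan"), float("nan"), points, n_expl, 0, undefined=True)
    return BartScore(total / n_unexpl, banked / n_unexpl, points, n_expl, n_unexpl)


@register_runner(TaskId.BART)
def run_bart(cfg: BARTConfig, agent, seed: RunSeed, session_id: str) -> list[TrialEvent]:
    rng = seed.rng()
    schedule = generate_bart_schedule(cfg, rng)
    events: list[TrialEvent] = []
    for idx, explosion in enumerate(schedule.explosion_points):
        intended = int(agent.bart_pumps(idx, rng))
        if intended < 0 or intended > cfg.max_pumps:
            raise ProtocolViolationError(
                f"BART: intended pumps {intended} outside 0..{cfg.max_pumps}")
        exploded = explosion <= intended
        pumps = explosion if exploded else intended
        payload = {"balloon": idx, "explosion_point": explosion,
                   "pumps": pumps, "exploded": bool(exploded),
                   "intended_pumps": intended}
        token = f"{pumps}:{'exploded' if exploded else 'banked'}"
        events.append(make_event(TaskId.BART, session_id, idx, MAIN, payload,
                                 token, token, 0.0, training_feedback=False))
    return events


def balloons_from_events(log: Sequence[TrialEvent]) -> list[tuple[int, bool]]:
    return [(int(ev.stimulus["pumps"]), bool(ev.stimulus["exploded"]))
            for ev in log if ev.task_id == TaskId.BART.value]


# ===========================================================================
# STROOP


class StroopConfig(TaskConfigBase):
    task_id: Literal["STROOP"] = "STROOP"
    n_words_per_category: int = Field(8, ge=1)
    presentations_per_word: int = Field(8, ge=4)
    exposure_ms: float = Field(3000.0, gt=0.0)
    max_run_length: int = Field(3, ge=1)
    iti_ms: float = Field(500.0, ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "StroopConfig":
        if self.presentations_per_word % len(COLORS):
            raise ValueError(
                "presentations_per_word must be a multiple of the 4 ink colours")
        return self


@dataclass(frozen=True)
class StroopItem:
    word_token: str
    category: str   # meth_word | neutral_word
    ink: str


def generate_stroop_schedule(
    cfg: StroopConfig, rng: np.random.Generator, lexicon: Lexicon | None = None
) -> list[StroopItem]:
    """Every word appears ``presentations_per_word`` times, balanced
    evenly over the four ink colours; the order is a seeded shuffle
    constrained to at most ``max_run_length`` consecutive trials of the
    same word category."""
    lexicon = lexicon or default_lexicon()
    per_color = cfg.presentations_per_word // len(COLORS)
    pools: dict[str, list[StroopItem]] = {}
    for category in ("meth_word", "neutral_word"):
        words = lexicon.pool(category)[: cfg.n_words_per_category]
        if len(words) < cfg.n_words_per_category:
            raise ConfigurationError(f"lexicon too small for {category}")
        items = [StroopItem(w, category, ink)
                 for w in words for ink in COLORS for _ in range(per_color)]
        order = rng.permutation(len(items))
        pools[category] = [items[i] for i in order]

    categories = list(pools)
    for _attempt in range(1000):
        remaining = {c: len(pools[c]) for c in categories}
        seq_cats: list[str] = []
        ok = True
        while any(remaining.values()):
            banned = None
            if len(seq_cats) >= cfg.max_run_length and \
                    len(set(seq_cats[-cfg.max_run_length:])) == 1:
                banned = seq_cats[-1]
            options = [c for c in categories if remaining[c] > 0 and c != banned]
            if not options:
                ok = False
                break
            weights = np.array([remaining[c] for c in options], dtype=float)
            choice = options[int(rng.choice(len(options), p=weights / weights.sum()))]
            seq_cats.append(choice)
            remaining[choice] -= 1
        if ok:
            iters = {c: iter(pools[c]) for c in categories}
            return [next(iters[c]) for c in seq_cats]
    raise ConfigurationError("could not build a run-constrained sequence")  # pragma: no cover


@register_runner(TaskId.STROOP)
def run_stroop(cfg: StroopConfig, agent, seed: RunSeed, session_id: str) -> list[TrialEvent]:
    rng = seed.rng()
    schedule = generate_stroop_schedule(cfg, rng)
    events: list[TrialEvent] = []
    for idx, item in enumerate(schedule):
        category = "meth" if item.category.startswith("meth") else "neutral"
        payload = {"word_token": item.word_token, "category": item.category, "ink": item.ink}
        given, latency = agent.respond(TaskId.STROOP, payload, item.ink, COLORS,
                                       rng, level=1, category=category)
        check_token(given, COLORS, TaskId.STROOP)
        if latency > cfg.exposure_ms:   # word leaves the screen: timeout
            given, latency = None, cfg.exposure_ms
        events.append(make_event(TaskId.STROOP, session_id, idx, MAIN, payload,
                                 item.ink, given, latency, training_feedback=False))
    return events


@dataclass(frozen=True)
class StroopResult:
    bias_ms: float
    mean_rt_meth: float
    mean_rt_neutral: float
    error_rate_meth: float
    error_rate_neutral: float
    undefined: bool = False


def stroop_bias(log: Sequence[TrialEvent]) -> StroopResult:
    """Attention bias: mean latency on correct drug-word trials minus
    mean latency on correct neutral-word trials, plus per-category error
    rates. A category with no correct trials leaves the bias undefined
    (flagged)."""
    rts: dict[str, list[float]] = {"meth": [], "neutral": []}
    n: dict[str, int] = {"meth": 0, "neutral": 0}
    errors: dict[str, int] = {"meth": 0, "neutral": 0}
    for ev in log:
        if ev.task_id != TaskId.STROOP.value:
            continue
        cat = "meth" if str(ev.stimulus.get("category", "")).startswith("meth") else "neutral"
        n[cat] += 1
        if ev.correct:
            rts[cat].append(ev.latency_ms)
        else:
            errors[cat] += 1
    if n["meth"] == 0 or n["neutral"] == 0:
        raise UndefinedScoreError("log must contain scored trials of both word categories")
    err = {c: errors[c] / n[c] for c in n}
    if not rts["meth"] or not rts["neutral"]:
        return StroopResult(float("nan"), float("nan"), float("nan"),
                            err["meth"], err["neutral"], undefined=True)
    m, u = float(np.mean(rts["meth"])), float(np.mean(rts["neutral"]))
    return StroopResult(m - u, m, u, err["meth"], err["neutral"])
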