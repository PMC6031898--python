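"""Parameterized simulated respondents with known ground truth.

These agents exist so every task in the battery can be exercised
end-to-end with behaviour whose generating parameters are known exactly:

* a hyperbolic discounter for the delay-discounting titration
  (threshold rule on V = A/(1+kD), optionally softened by a logistic
  choice rule);
* a single-parameter delta-rule learner with softmax choice for the
  gambling task (a test fixture, not a cognitive model);
* a fixed pump-threshold balloon agent;
* a generic accuracy/latency responder for the training tasks and the
  Stroop, with level-indexed accuracy and a lognormal latency model
  carrying an additive drug-category shift (the ground-truth attention
  bias).

All agents are deterministic given (parameters, seed): they draw only
from the generator the task runner hands them.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .session_core import ConfigurationError, TaskId

DECKS = ("A", "B", "C", "D")


# ---------------------------------------------------------------------------
# Parameter files


class _ParamsBase(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class DDTParams(_ParamsBase):
    k_true: float = Field(0.05, ge=0.0)        # per-day discount rate
    choice_noise: float = Field(0.0, ge=0.0)   # logistic temperature; 0 = threshold rule


class IGTParams(_ParamsBase):
    learning_rate: float = Field(0.2, ge=0.0, le=1.0)
    temperature: float = Field(10.0, gt=0.0)


class BARTParams(_ParamsBase):
    pump_threshold: int = Field(64, ge=0)


class ResponderParams(_ParamsBase):
    p_correct: dict[int, float] = Field(default_factory=lambda: {1: 0.95, 2: 0.90, 3: 0.85})
    p_correct_default: float = Field(0.90, ge=0.0, le=1.0)
    latency_mu_log: float = math.log(600.0)    # lognormal location (log-ms)
    latency_sigma_log: float = Field(0.3, gt=0.0)
    latency_floor_ms: float = Field(150.0, ge=0.0)
    category_effect_ms: float = 0.0            # additive shift on drug-category trials
    p_timeout: float = Field(0.0, ge=0.0, le=1.0)


class AgentParams(_ParamsBase):
    """One simulated respondent: parameters for every task family."""

    ddt: DDTParams = DDTParams()
    igt: IGTParams = IGTParams()
    bart: BARTParams = BARTParams()
    responder: ResponderParams = ResponderParams()


def load_agent_params(path: str | Path) -> AgentParams:
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return AgentParams.model_validate(data)


def dump_agent_params(params: AgentParams) -> str:
    return yaml.safe_dump(params.model_dump(mode="json"), sort_keys=True)


# ---------------------------------------------------------------------------
# DDT agent


class DDTAgent:
    """Hyperbolic discounter. Noiseless mode chooses the delayed reward
    iff its subjective value A/(1+kD) exceeds the immediate offer (ties
    go to the delayed reward); noisy mode is logistic in the subjective
    value difference."""

    def __init__(self, params: DDTParams) -> None:
        self.params = params

    def subjective_value(self, A: float, D: float) -> float:
        return A / (1.0 + self.params.k_true * D)

    def ddt_choose(self, immediate: float, A: float, D: float,
                   rng: np.random.Generator) -> str:
        v = self.subjective_value(A, D)
        if self.params.choice_noise == 0.0:
            return "delayed" if v >= immediate else "immediate"
        p_delayed = 1.0 / (1.0 + math.exp(-(v - immediate) / self.params.choice_noise))
        return "delayed" if rng.random() < p_delayed else "immediate"


# ---------------------------------------------------------------------------
# IGT agent


class IGTChooser:
    """Stateful deck chooser for one task run: delta-rule value updates
    on the chosen deck, softmax choice over deck values."""

    def __init__(self, params: IGTParams) -> None:
        self.params = params
        self.values = {d: 0.0 for d in DECKS}

    def pick(self, rng: np.random.Generator) -> str:
        v = np.array([self.values[d] for d in DECKS])
        tau = self.params.temperature
        if tau <= 1e-9:   # greedy limit
            best = np.flatnonzero(v == v.max())
            return DECKS[int(best[int(rng.integers(len(best)))])]
        z = v / tau
        z -= z.max()
        p = np.exp(z)
        p /= p.sum()
        return DECKS[int(rng.choice(len(DECKS), p=p))]

    def observe(self, deck: str, net_payoff: float) -> None:
        a = self.params.learning_rate
        self.values[deck] += a * (net_payoff - self.values[deck])


class IGTAgent:
    def __init__(self, params: IGTParams) -> None:
        self.params = params

    def igt_session(self, rng: np.random.Generator) -> IGTChooser:
        return IGTChooser(self.params)


# ---------------------------------------------------------------------------
# BART agent


class BARTAgent:
    """Pumps every balloon up to a fixed threshold T, then banks; the
    balloon bursts first whenever its explosion point is <= T."""

    def __init__(self, params: BARTParams) -> None:
        self.params = params

    def bart_pumps(self, balloon_index: int, rng: np.random.Generator) -> int:
        return self.params.pump_threshold


# ---------------------------------------------------------------------------
# Generic responder


class ResponderAgent:
    """Accuracy/latency responder for the training tasks and the Stroop.

    Answers correctly with probability ``p_correct[level]`` (falling
    back to ``p_correct_default``); otherwise returns a uniformly drawn
    wrong token (or a perturbed response when the task supplies a
    wrong-response generator). Latency is lognormal with a hard floor,
    plus ``category_effect_ms`` on drug-category trials — so the
    ground-truth Stroop bias equals ``category_effect_ms`` in
    expectation.
    """

    def __init__(self, params: ResponderParams) -> None:
        self.params = params

    def _p(self, level: int) -> float:
        return self.params.p_correct.get(level, self.params.p_correct_default)

    def _latency(self, rng: np.random.Generator, category: str | None) -> float:
        draw = rng.lognormal(self.params.latency_mu_log, self.params.latency_sigma_log)
        latency = max(draw, self.params.latency_floor_ms)
        if category == "meth":
            latency += self.params.category_effect_ms
        return latency

    def respond(
        self,
        task_id: TaskId,
        stimulus: dict,
        correct_response: str,
        alternatives: Sequence[str] | Callable[[np.random.Generator], str],
        rng: np.random.Generator,
        *,
        level: int = 1,
        category: str | None = None,
    ) -> tuple[str | None, float]:
        latency = self._latency(rng, category)
        if self.params.p_timeout > 0 and rng.random() < self.params.p_timeout:
            return None, latency
        if rng.random() < self._p(level):
            return correct_response, latency
        if callable(alternatives):
            return alternatives(rng), latency
        wrong = [a for a in alternatives if a != correct_response]
        if not wrong:
            return correct_response, latency
        return wrong[int(rng.integers(len(wrong)))], latency


# ---------------------------------------------------------------------------
# Full battery


class BatteryAgent:
    """A complete simulated respondent: delegates each task to the
    matching behavioural component."""

    def __init__(self, params: AgentParams) -> None:
        self.params = params
        self._ddt = DDTAgent(params.ddt)
        self._igt = IGTAgent(params.igt)
        self._bart = BARTAgent(params.bart)
        self._responder = ResponderAgent(params.responder)

    # response contracts, per task family
    def respond(self, *args, **kwargs):
        return self._responder.respond(*args, **kwargs)

    def ddt_choose(self, immediate, A, D, rng):
        return self._ddt.ddt_choose(immediate, A, D, rng)

    def igt_session(self, rng):
        return self._igt.igt_session(rng)

    def bart_pumps(self, balloon_index, rng):
        return self._bart.bart_pumps(balloon_index, rng)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BatteryAgent":
        return cls(load_agent_params(path))


def perfect_agent() -> BatteryAgent:
    """A deterministic, always-correct respondent (useful fixture)."""
    return BatteryAgent(AgentParams(
        responder=ResponderParams(p_correct={}, p_correct_default=1.0)))
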