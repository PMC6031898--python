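"""Study configuration: schema-validated YAML/JSON loading.

A :class:`StudyConfig` bundles the session plan, every per-task
configuration block, and the simulated-agent parameters per arm. All
defaults reproduce the study protocol constants: 20 sessions (5/week,
each training program twice per session), 240 attention-control trials,
150 gambling-task trials, 100 balloons, a 1000-unit delayed reward with
a 500-unit starting offer over delays {2, 7, 30, 90, 180, 360} days.
Unknown keys are rejected everywhere.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .assessment_tasks import BARTConfig, DDTConfig, IGTConfig, StroopConfig
from .session_core import ConfigurationError, SessionPlan, TaskId
from .synthetic_agents import AgentParams
from .training_tasks import ABMConfig, ACTConfig, MatrixConfig, NBackConfig

TASK_CONFIG_TYPES = {
    "ABM": ABMConfig,
    "ACT": ACTConfig,
    "NBACK": NBackConfig,
    "MATRIX": MatrixConfig,
    "DDT": DDTConfig,
    "IGT": IGTConfig,
    "BART": BARTConfig,
    "STROOP": StroopConfig,
}


class _CfgBase(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class SessionPlanConfig(_CfgBase):
    n_sessions: int = Field(20, ge=1)
    sessions_per_week: int = Field(5, ge=1)
    programs_per_session: dict[str, int] = Field(
        default_factory=lambda: {"ABM": 2, "ACT": 2, "NBACK": 2, "MATRIX": 2})

    def to_plan(self) -> SessionPlan:
        return SessionPlan(self.n_sessions, self.sessions_per_week,
                           dict(self.programs_per_session))


class TaskSuiteConfig(_CfgBase):
    abm: ABMConfig = ABMConfig()
    act: ACTConfig = ACTConfig()
    nback: NBackConfig = NBackConfig()
    matrix: MatrixConfig = MatrixConfig()
    ddt: DDTConfig = DDTConfig()
    igt: IGTConfig = IGTConfig()
    bart: BARTConfig = BARTConfig()
    stroop: StroopConfig = StroopConfig()

    def for_task(self, task_id: TaskId | str):
        return getattr(self, TaskId(task_id).value.lower())


class ArmAgentConfig(_CfgBase):
    """Agent parameters for one arm, before and after the training
    period. The pre-to-post shift is the simulated training effect (a
    modelling choice of the study replica, not an efficacy claim)."""

    pre: AgentParams = AgentParams()
    post: AgentParams = AgentParams()


class SubjectVariability(_CfgBase):
    """Between-subject heterogeneity applied once per simulated subject
    (to both their pre and post parameters, preserving within-subject
    correlation)."""

    k_sigma_log: float = Field(0.25, ge=0.0)        # lognormal jitter on k_true
    bart_threshold_sd: float = Field(6.0, ge=0.0)   # additive, rounded
    category_effect_sd_ms: float = Field(20.0, ge=0.0)


def _default_arms() -> dict[str, ArmAgentConfig]:
    from .synthetic_agents import BARTParams, DDTParams, IGTParams, ResponderParams

    baseline = AgentParams(
        ddt=DDTParams(k_true=0.08, choice_noise=25.0),
        igt=IGTParams(learning_rate=0.05, temperature=25.0),
        bart=BARTParams(pump_threshold=80),
        responder=ResponderParams(category_effect_ms=120.0),
    )
    improved = AgentParams(
        ddt=DDTParams(k_true=0.02, choice_noise=25.0),
        igt=IGTParams(learning_rate=0.25, temperature=10.0),
        bart=BARTParams(pump_threshold=55),
        responder=ResponderParams(category_effect_ms=120.0),
    )
    # training arm improves on the decision tasks post-training; the
    # word-category latency effect is left unshifted in both arms.
    return {
        "CCAT": ArmAgentConfig(pre=baseline, post=improved),
        "control": ArmAgentConfig(pre=baseline, post=baseline),
    }


class StudyConfig(_CfgBase):
    """Everything needed to run a simulated two-arm study end to end."""

    n_per_arm: int = Field(4, ge=1)
    seed: int = 0
    plan: SessionPlanConfig = SessionPlanConfig()
    tasks: TaskSuiteConfig = TaskSuiteConfig()
    arms: dict[str, ArmAgentConfig] = Field(default_factory=_default_arms)
    variability: SubjectVariability = SubjectVariability()
    battery: tuple[str, ...] = ("DDT", "IGT", "BART", "STROOP")


def load_study_config(path: str | Path) -> StudyConfig:
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return StudyConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def dump_study_config(cfg: StudyConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True)


def load_task_config(task_id: TaskId | str, block: dict | None):
    """Build one task's config from a (possibly absent) mapping block."""
    cls = TASK_CONFIG_TYPES[TaskId(task_id).value]
    try:
        return cls.model_validate(block or {})
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc
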