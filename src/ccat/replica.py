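"""End-to-end study replica: pre-assessment, training, post-assessment,
and the group x time analysis, for two simulated arms.

For every simulated subject the replica runs the assessment battery
before and after the training period; subjects in the training arm
additionally complete the full session plan (by default 20 sessions,
each training program twice per session). The simulated training effect
is expressed purely as the configured pre-to-post shift in agent
parameters — the replica makes no claim about real training efficacy.

All output lands under one directory:

    out/
      config.yaml          resolved configuration
      scores.csv           one row per (subject, time) with all task scores
      analysis.csv         mixed-ANOVA table per outcome
      logs/<arm>/<subject>/{pre,post}/<task>.jsonl
      logs/<arm>/<subject>/training/sess-XX/<program>-Y.jsonl

Runs are resumable: an existing, intact log is reused (streams are
scoped per task/session, so reuse cannot perturb other logs); a corrupt
log raises an integrity error instead of being silently overwritten.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .assessment_tasks import (
    balloons_from_events,
    bart_score,
    igt_choices_from_events,
    igt_net_score,
    score_ddt,
    stroop_bias,
)
from .config import StudyConfig, dump_study_config
from .session_core import RunSeed, TaskId, read_log, run_session, session_accuracy, write_log
from .stats_analysis import group_time_anova
from .synthetic_agents import AgentParams, BatteryAgent

OUTCOME_COLS = ("ln_k_global", "igt_net", "bart_literal", "bart_adjusted", "stroop_bias_ms")


@dataclass(frozen=True)
class ReplicaResult:
    out_dir: Path
    scores: pd.DataFrame
    analysis: pd.DataFrame


def _subject_shift(base: AgentParams, k_factor: float, bart_offset: int,
                   effect_shift: float) -> AgentParams:
    """Apply one subject's sampled heterogeneity to a parameter set."""
    d = base.model_dump()
    d["ddt"]["k_true"] = base.ddt.k_true * k_factor
    d["bart"]["pump_threshold"] = max(0, base.bart.pump_threshold + bart_offset)
    d["responder"]["category_effect_ms"] = base.responder.category_effect_ms + effect_shift
    return AgentParams.model_validate(d)


def _run_or_load(path: Path, task_cfg, agent, seed: RunSeed, session_id: str):
    if path.exists():
        return read_log(path)
    events = run_session(task_cfg, agent, seed, session_id)
    path.parent.mkdir(parents=True, exist_ok=True)
    write_log(events, path)
    return events


def _battery_row(cfg: StudyConfig, agent: BatteryAgent, seed: RunSeed,
                 subject: str, group: str, time: str, log_dir: Path) -> dict:
    row: dict = {"subject": subject, "group": group, "time": time}
    for task in cfg.battery:
        task = TaskId(task)
        task_cfg = cfg.tasks.for_task(task)
        sid = f"{subject}-{time}-{task.value.lower()}"
        log = _run_or_load(log_dir / f"{task.value.lower()}.jsonl",
                           task_cfg, agent, seed.child(task.value), sid)
        if task is TaskId.DDT:
            res = score_ddt(log, task_cfg)
            row["k_global"] = res.k_global
            row["ln_k_global"] = res.ln_k_global
            for d, v in sorted(res.indifference_points.items()):
                row[f"v_d{d}"] = v
            for d, k in sorted(res.k_by_delay.items()):
                row[f"k_d{d}"] = k
        elif task is TaskId.IGT:
            row["igt_net"] = igt_net_score(igt_choices_from_events(log),
                                           task_cfg.advantageous)
        elif task is TaskId.BART:
            s = bart_score(balloons_from_events(log), task_cfg.points_per_pump)
            row["bart_literal"] = s.literal
            row["bart_adjusted"] = s.adjusted
            row["bart_points"] = s.points
            row["bart_exploded"] = s.n_exploded
        elif task is TaskId.STROOP:
            s = stroop_bias(log)
            row["stroop_bias_ms"] = s.bias_ms
            row["stroop_err_meth"] = s.error_rate_meth
            row["stroop_err_neutral"] = s.error_rate_neutral
            row["stroop_accuracy"] = session_accuracy(log)
    return row


def run_study_replica(cfg: StudyConfig, out_dir: str | Path,
                      seed: int | None = None) -> ReplicaResult:
    """Run the full two-arm study and write logs, scores and analysis."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = RunSeed(cfg.seed if seed is None else seed, "replica")
    (out_dir / "config.yaml").write_text(dump_study_config(cfg), encoding="utf-8")

    plan = cfg.plan.to_plan()
    rows = []
    for group in sorted(cfg.arms):
        arm = cfg.arms[group]
        trained = group != "control"
        for i in range(cfg.n_per_arm):
            subject = f"{group}-{i:03d}"
            srng = master.child(f"{subject}/heterogeneity").rng()
            k_factor = float(np.exp(srng.normal(0.0, cfg.variability.k_sigma_log)))
            bart_offset = int(round(srng.normal(0.0, cfg.variability.bart_threshold_sd)))
            effect_shift = float(srng.normal(0.0, cfg.variability.category_effect_sd_ms))

            params = {
                "pre": _subject_shift(arm.pre, k_factor, bart_offset, effect_shift),
                "post": _subject_shift(arm.post, k_factor, bart_offset, effect_shift),
            }
            subj_dir = out_dir / "logs" / group / subject

            rows.append(_battery_row(cfg, BatteryAgent(params["pre"]),
                                     master.child(f"{subject}/pre"),
                                     subject, group, "pre", subj_dir / "pre"))
            if trained:
                agent = BatteryAgent(params["pre"])
                for sess in range(1, plan.n_sessions + 1):
                    sess_dir = subj_dir / "training" / f"sess-{sess:02d}"
                    for program, reps in plan.programs_per_session.items():
                        for rep in range(reps):
                            _run_or_load(
                                sess_dir / f"{program.lower()}-{rep}.jsonl",
                                cfg.tasks.for_task(program), agent,
                                master.child(f"{subject}/training/{sess}/{program}/{rep}"),
                                f"{subject}-s{sess:02d}-{program.lower()}-{rep}")
            rows.append(_battery_row(cfg, BatteryAgent(params["post"]),
                                     master.child(f"{subject}/post"),
                                     subject, group, "post", subj_dir / "post"))

    scores = pd.DataFrame(rows).sort_values(["group", "subject", "time"],
                                            ascending=[True, True, False])
    scores.to_csv(out_dir / "scores.csv", index=False, float_format="%.10g")

    analysis_rows = []
    for outcome in OUTCOME_COLS:
        if outcome not in scores.columns:
            continue
        panel = scores.rename(columns={outcome: "value"})[
            ["subject", "group", "time", "value"]]
        if panel["value"].isna().any() or not np.isfinite(panel["value"]).all():
            continue
        res = group_time_anova(panel)
        tab = res.to_frame()
        tab.insert(0, "outcome", outcome)
        analysis_rows.append(tab)
    analysis = pd.concat(analysis_rows, ignore_index=True) if analysis_rows else pd.DataFrame()
    analysis.to_csv(out_dir / "analysis.csv", index=False, float_format="%.10g")
    return ReplicaResult(out_dir=out_dir, scores=scores, analysis=analysis)
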