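"""Group-comparison statistics for a two-arm pre/post trial.

Three pieces mirror the analyses a small randomized trial reports:

* baseline comparisons computed from published summary statistics alone
  (a pooled-variance two-sample comparison reported as F with df
  (1, n1+n2-2), and a Pearson chi-square for categorical tables);
* a 2 (group, between) x 2 (time, within) mixed-model ANOVA for the
  pre/post outcomes, with Bonferroni-corrected paired contrasts within
  each group to resolve interactions;
* a synthetic two-arm trial generator under an explicit additive model
  (cell mean + subject intercept + residual), used for calibration and
  power checks.

For a balanced 2x2 design the interaction test here coincides with a
two-sample t test on the within-subject change scores, which is also
what an exchangeable-correlation GEE tests in this design; the ANOVA is
specified exactly so its sums of squares partition can be verified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from .session_core import ConfigurationError, RunSeed, UndefinedScoreError

PRE = "pre"
POST = "post"


# ---------------------------------------------------------------------------
# Summary-statistic tests


@dataclass(frozen=True)
class GroupSummary:
    """Published per-group summary: n, mean, SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("variance-based tests need n >= 2 per group")
        if self.sd < 0:
            raise ConfigurationError("sd must be non-negative")

    @classmethod
    def from_sample(cls, x: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(x, dtype=float)
        return cls(n=len(arr), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


@dataclass(frozen=True)
class FTestResult:
    f: float
    df1: int
    df2: int
    p: float
    infinite: bool = False


def summary_f_test(g1: GroupSummary, g2: GroupSummary) -> FTestResult:
    """Pooled-variance two-sample comparison from summaries alone.

    F equals the square of the pooled two-sample t statistic and is
    reported with df (1, n1+n2-2). Two degenerate cases are flagged
    rather than propagated as NaN: identical zero-variance groups give
    F = 0, differing zero-variance groups an infinite F.
    """
    df2 = g1.n + g2.n - 2
    pooled_var = ((g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2) / df2
    se2 = pooled_var * (1.0 / g1.n + 1.0 / g2.n)
    diff = g1.mean - g2.mean
    if se2 == 0.0:
        if diff == 0.0:
            return FTestResult(0.0, 1, df2, 1.0)
        return FTestResult(float("inf"), 1, df2, 0.0, infinite=True)
    f = diff ** 2 / se2
    return FTestResult(float(f), 1, df2, float(stats.f.sf(f, 1, df2)))


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if self.counts.ndim != 2:
            raise ConfigurationError("contingency table must be 2-dimensional")
        if np.any(self.counts < 0):
            raise ConfigurationError("counts must be non-negative")


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float
    expected: np.ndarray


def chi_square_test(table: ContingencyTable | np.ndarray) -> Chi2Result:
    """Pearson chi-square without continuity correction; degenerate
    tables (a zero row/column marginal) are rejected."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ConfigurationError("contingency table must be 2-dimensional")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise UndefinedScoreError("degenerate table: zero marginal")
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=False)
    return Chi2Result(float(chi2), int(df), float(p), expected)


# ---------------------------------------------------------------------------
# 2x2 mixed ANOVA


@dataclass(frozen=True)
class PosthocContrast:
    group: str
    mean_change: float
    t: float
    df: int
    p: float
    p_bonferroni: float


@dataclass(frozen=True)
class MixedAnovaResult:
    f_group: float
    f_time: float
    f_interaction: float
    df_between: tuple[int, int]     # (effect, error) for the group effect
    df_within: tuple[int, int]      # (effect, error) for time and interaction
    p_group: float
    p_time: float
    p_interaction: float
    ss: dict[str, float]
    posthoc: tuple[PosthocContrast, ...]
    n_subjects: int
    n_excluded: int
    infinite: bool = False          # zero residual variance with a nonzero effect

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("group", self.f_group, *self.df_between, self.p_group),
            ("time", self.f_time, *self.df_within, self.p_time),
            ("group_x_time", self.f_interaction, *self.df_within, self.p_interaction),
        ]
        return pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])


def _ratio(ss_num: float, df_num: int, ss_den: float, df_den: int) -> tuple[float, float, bool]:
    """F and p with explicit zero-variance flags."""
    if df_den <= 0:
        raise ConfigurationError("not enough subjects for an error term")
    ms_den = ss_den / df_den
    ms_num = ss_num / df_num
    if ms_den == 0.0:
        if ms_num == 0.0:
            return 0.0, 1.0, False
        return float("inf"), 0.0, True
    f = ms_num / ms_den
    return float(f), float(stats.f.sf(f, df_num, df_den)), False


def group_time_anova(
    panel: pd.DataFrame,
    *,
    value_col: str = "value",
    group_col: str = "group",
    time_col: str = "time",
    subject_col: str = "subject",
    bonferroni_factor: int | None = None,
) -> MixedAnovaResult:
    """2 (group) x 2 (time: pre/post) mixed ANOVA on a long-format panel.

    Subjects missing either time point are excluded (complete-case, with
    the count reported). The decomposition works on per-subject sums and
    differences, which makes the sums-of-squares partition

        SS_total = SS_group + SS_subject(group)
                 + SS_time + SS_interaction + SS_residual

    exact for any group sizes. Post hoc paired pre/post contrasts within
    each group are Bonferroni-corrected (by the number of contrasts, 2,
    unless overridden).
    """
    df = panel[[subject_col, group_col, time_col, value_col]].dropna()
    if set(df[time_col].unique()) - {PRE, POST}:
        raise ConfigurationError(f"time must be {{{PRE!r}, {POST!r}}}")
    wide = df.pivot_table(index=[subject_col, group_col], columns=time_col,
                          values=value_col, aggfunc="mean")
    n_seen = df[subject_col].nunique()
    wide = wide.dropna(subset=[c for c in (PRE, POST) if c in wide.columns])
    if PRE not in wide.columns or POST not in wide.columns or wide.empty:
        raise ConfigurationError("panel needs both pre and post observations")
    n_excluded = n_seen - len(wide)

    groups_of = wide.index.get_level_values(group_col)
    group_names = sorted(set(groups_of))
    if len(group_names) != 2:
        raise ConfigurationError(f"expected exactly 2 groups, got {group_names}")

    pre = wide[PRE].to_numpy(dtype=float)
    post = wide[POST].to_numpy(dtype=float)
    s = (pre + post) / 2.0          # subject means
    d = post - pre                  # within-subject change
    g = np.asarray(groups_of == group_names[1], dtype=int)
    n = len(s)
    n_g = np.array([(g == i).sum() for i in (0, 1)])
    if np.any(n_g < 1):
        raise ConfigurationError("each group needs at least one complete subject")

    grand = s.mean()
    s_g = np.array([s[g == i].mean() for i in (0, 1)])
    d_g = np.array([d[g == i].mean() for i in (0, 1)])
    d_bar = d.mean()

    ss_group = float(2 * np.sum(n_g * (s_g - grand) ** 2))
    ss_subject = float(2 * np.sum((s - s_g[g]) ** 2))
    ss_time = float(n * d_bar ** 2 / 2)
    ss_inter = float(np.sum(n_g * (d_g - d_bar) ** 2) / 2)
    ss_resid = float(np.sum((d - d_g[g]) ** 2) / 2)
    values = np.concatenate([pre, post])
    ss_total = float(np.sum((values - values.mean()) ** 2))

    df_err = n - 2
    f_group, p_group, inf_g = _ratio(ss_group, 1, ss_subject, df_err)
    f_time, p_time, inf_t = _ratio(ss_time, 1, ss_resid, df_err)
    f_inter, p_inter, inf_i = _ratio(ss_inter, 1, ss_resid, df_err)

    factor = 2 if bonferroni_factor is None else bonferroni_factor
    posthoc = []
    for i, name in enumerate(group_names):
        di = d[g == i]
        if len(di) >= 2 and np.std(di, ddof=1) > 0:
            t, p = stats.ttest_rel(post[g == i], pre[g == i])
            t, p = float(t), float(p)
        else:
            t, p = float("nan"), float("nan")
        posthoc.append(PosthocContrast(
            group=name, mean_change=float(di.mean()), t=t, df=len(di) - 1,
            p=p, p_bonferroni=min(1.0, p * factor) if np.isfinite(p) else p))

    return MixedAnovaResult(
        f_group=f_group, f_time=f_time, f_interaction=f_inter,
        df_between=(1, df_err), df_within=(1, df_err),
        p_group=p_group, p_time=p_time, p_interaction=p_inter,
        ss={"group": ss_group, "subject": ss_subject, "time": ss_time,
            "interaction": ss_inter, "residual": ss_resid, "total": ss_total},
        posthoc=tuple(posthoc),
        n_subjects=n, n_excluded=int(n_excluded),
        infinite=inf_g or inf_t or inf_i,
    )


# ---------------------------------------------------------------------------
# Synthetic two-arm trial generator


class ArmMeans(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    pre: float = 0.0
    post: float = 0.0


class TrialGenConfig(BaseModel):
    """Additive generative model for a two-arm pre/post outcome:

    value = mean(group, time) + subject_intercept + residual,
    subject_intercept ~ N(0, sd_subject^2), residual ~ N(0, sd_residual^2).

    Defaults mirror the trial shape: 20 subjects per arm, one outcome
    measured pre and post.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_per_arm: int = Field(20, ge=2)
    means: dict[str, ArmMeans] = Field(
        default_factory=lambda: {"CCAT": ArmMeans(), "control": ArmMeans()})
    sd_subject: float = Field(1.0, ge=0.0)
    sd_residual: float = Field(1.0, gt=0.0)
    outcome: str = "outcome"
    seed: int = 0


def simulate_trial(gen_cfg: TrialGenConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic trial panel (long format: subject, group,
    time, outcome, value), deterministic under the seed."""
    rng = RunSeed(gen_cfg.seed if seed is None else seed, "simulate-trial").rng()
    rows = []
    for group, means in sorted(gen_cfg.means.items()):
        intercepts = rng.normal(0.0, gen_cfg.sd_subject, size=gen_cfg.n_per_arm)
        eps = rng.normal(0.0, gen_cfg.sd_residual, size=(gen_cfg.n_per_arm, 2))
        for i in range(gen_cfg.n_per_arm):
            sid = f"{group}-{i:03d}"
            rows.append((sid, group, PRE, gen_cfg.outcome,
                         means.pre + intercepts[i] + eps[i, 0]))
            rows.append((sid, group, POST, gen_cfg.outcome,
                         means.post + intercepts[i] + eps[i, 1]))
    return pd.DataFrame(rows, columns=["subject", "group", "time", "outcome", "value"])


def analytic_interaction_power(delta: float, sd_residual: float,
                               n_per_arm: int, alpha: float = 0.05) -> float:
    """Exact power of the group x time interaction test under the
    generator above: the test is a two-sample t on change scores whose
    per-subject SD is sqrt(2) * sd_residual, so power follows the
    noncentral t with df 2n-2 and noncentrality
    delta / (sqrt(2) * sd_residual * sqrt(2/n))."""
    df = 2 * n_per_arm - 2
    sd_change = math.sqrt(2.0) * sd_residual
    ncp = delta / (sd_change * math.sqrt(2.0 / n_per_arm))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
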