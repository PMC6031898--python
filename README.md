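# ccat-engine

A headless, fully seedable engine for a **computerized cognitive addiction
therapy (CCAT)** task battery, aimed at researchers in computational
psychiatry who need drug-cue cognitive tasks as reproducible state machines
rather than as touchscreen apps: simulated trials, re-scorable logs, and the
trial-level statistics of a two-arm pre/post study.

The battery contains:

* **Four adaptive training tasks** — methamphetamine attention bias
  modification (judge whether the colour *named* by the left word matches the
  ink of the right item, ignoring drug-related distractors), attention control
  training (name the border colour of the neutral picture; 240 trials),
  adaptive n-back on shape+colour figures (1- to 3-back, level up after two
  consecutive blocks at ≥90% accuracy), and a memory-matrix span task
  (three successes in a row raise the span, three failures lower it).
* **Four scored assessments** — delay-discounting titration (DDT), the Iowa
  Gambling Task (IGT), the Balloon Analogue Risk Task (BART), and a drug-word
  Stroop.
* **Simulated respondents** with known ground truth for every task, and
* **the statistics**: baseline comparisons from summary statistics alone
  (pooled-variance *F*, Pearson χ²) and a 2 (group) × 2 (time, within) mixed
  ANOVA with Bonferroni-corrected post hoc contrasts, plus a synthetic
  two-arm trial generator.

Drug-related words and pictures are abstract, category-tagged tokens — no
image assets, no rendering.

## The models at the core

**Delay discounting.** The delayed reward A = 1000 currency units is compared
against an immediate offer over delays D ∈ {2, 7, 30, 90, 180, 360} days. The
offer starts at 500 and follows a decreasing-adjustment staircase: it moves
down after an "immediate" choice and up after a "delayed" choice, by a step
that starts at 250 and halves every trial. After six adjustments the offer is
the indifference point V(D), exact to A·2⁻⁷ (offer arithmetic is done in
exact rationals, so the floor of an always-immediate chooser is exactly
7.8125). The hyperbolic decay model

    V(D) = A / (1 + k·D)

gives the per-day discount rate k = (A − V)/(V·D) per delay, and a global k
is least-squares fit across delays; higher k (and ln k) means steeper
devaluation of delayed rewards, i.e. more impulsive choice.

**IGT.** Canonical four-deck payoffs: decks A/B win 100 per pick but lose
1250 per 10-pick block (net −250); decks C/D win 50 and lose 250 (net +250).
Net score = (#C + #D) − (#A + #B); positive scores indicate advantageous
decision making.

**BART.** 100 balloons, explosion point uniform on {1..128}. The primary
score divides total pumps by the number of unexploded balloons; the
conventional adjusted score (pumps on unexploded balloons only) is always
reported alongside.

**Stroop bias.** 8 drug-related + 8 neutral words × 8 presentations balanced
over 4 ink colours (128 trials); bias = mean correct RT(drug words) − mean
correct RT(neutral words), in ms.

**Group × time ANOVA.** The pre/post analysis decomposes each subject into a
sum and a difference, which makes the partition SS_total = SS_group +
SS_subject(group) + SS_time + SS_interaction + SS_residual exact for any
group sizes; the interaction F with df (1, n−2) is the test of a
differential pre-to-post change between arms.

## Worked example

```python
from ccat import (AgentParams, BatteryAgent, DDTConfig, IGTConfig, RunSeed,
                  run_session, score_ddt, igt_net_score)
from ccat.assessment_tasks import igt_choices_from_events
from ccat.synthetic_agents import DDTParams, IGTParams

agent = BatteryAgent(AgentParams(ddt=DDTParams(k_true=0.05),
                                 igt=IGTParams(learning_rate=0.2, temperature=10.0)))

log = run_session(DDTConfig(), agent, RunSeed(7, "DDT/demo"), "demo")
res = score_ddt(log)
print("indifference points:", res.indifference_points)
print(f"fitted k = {res.k_global:.6f} per day, ln k = {res.ln_k_global:.3f}")

igt_log = run_session(IGTConfig(), agent, RunSeed(7, "IGT/demo"), "demo")
print("IGT net score:", igt_net_score(igt_choices_from_events(igt_log)))
```

prints

```
indifference points: {2: 914.0625, 7: 742.1875, 30: 398.4375, 90: 179.6875, 180: 101.5625, 360: 54.6875}
fitted k = 0.049911 per day, ln k = -2.998
IGT net score: 126
```

The agent was built with a true discount rate of k = 0.05/day; every
indifference point lands within the staircase resolution (±7.8125) of
A/(1+kD) — e.g. 398.4375 against a true 400 at D = 30 — and the fitted
global k recovers 0.0499. The positive net score (126 of a possible 150)
shows the delta-rule learner migrating to the advantageous decks.

The same runs from the shell, byte-identical under a fixed seed:

```bash
ccat run --task nback --seed 5 --out nb.jsonl
ccat accuracy nb.jsonl                     # 0.912500
ccat assess --seed 5 --out battery/       # DDT+IGT+BART+Stroop logs + scores.json
ccat replica --seed 5 --out study/        # full two-arm pre/post study replica
ccat analyze prepost study/scores.csv     # (or read study/analysis.csv)
```

`ccat replica` runs each simulated subject through a pre-assessment battery,
20 training sessions (each program twice, training arm only) and a
post-assessment, then fits the group × time ANOVA per outcome. Simulated
"training" is nothing more than the configured pre-to-post shift in agent
parameters.

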