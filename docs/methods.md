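# Methods

This note documents the models, default parameters, numerical choices and
known limitations of the engine. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Trial and session framework

Every task is a pure function of `(config, agent, seed)`. Randomness comes
from one numpy PCG64 generator per `(seed, stream_id)` pair; the stream id
(task/session scoped) is hashed with SHA-256 into extra entropy words for
`SeedSequence`, so streams are mutually independent and stable: adding,
removing or reordering tasks in a battery never perturbs another task's
schedule. With a deterministic agent the full serialized JSONL log is
byte-identical across reruns.

A `TrialEvent` records stimulus payload, correct response, given response,
latency, correctness and feedback. Invariants enforced at construction:
`correct ⇔ given == correct_response and given is not null`; training tasks
give green-check/red-cross feedback, assessments none; timeouts are logged
as incorrect with a null response at the deadline latency. Choice tasks
without a normative answer (DDT, IGT, BART) log the choice as both
`correct_response` and `given_response` so the schema invariants hold and
accuracy is trivially defined on those logs.

**Session budgets.** The protocol specifies durations (about 8 minutes for
the bias-modification task, 10 for n-back and matrix) rather than trial
counts. The engine uses trial-count surrogates by default — ABM 20 practice
+ 120 main trials, attention control 240, n-back 4 blocks of 20 scored
trials, matrix 40 — so runs are deterministic and tests exact. A budget mode
exists that accumulates *simulated* time (agent latency + inter-trial
interval, default 500 ms) and stops when the budget is spent; it is
deterministic too, unlike a wall-clock mode, which is why no wall-clock mode
is provided.

## Training tasks

* **ABM.** The rule compares the colour *named* by the left word with the
  ink of the right item; the left word's own ink and the drug-picture
  distractor are irrelevant by design (they exist to capture attention).
  Colours are restricted to {red, yellow, blue, green}. Practice trials
  (20) carry no drug content. Defaults: consistent:inconsistent 1:1 and
  drug-distractor presence 100% in the main phase — both unstated by the
  protocol, both exact-count balanced and configurable. Responses are
  2-alternative (consistent/inconsistent), following the "judge whether
  consistent" wording rather than a colour-naming reading.
* **ACT.** One picture (report its border colour) or a drug/neutral pair
  (report the neutral picture's border). 240 trials, 1-picture:2-picture
  mix 1:1 (unstated; configurable); single-picture trials split evenly
  between drug and neutral content; paired borders are drawn distinct.
* **N-back.** Figures are shape × colour conjunctions (3 shapes × 4
  colours); a target repeats the figure *n* back in both attributes. The
  "90% accuracy twice in succession" rule needs an accuracy window, which
  the protocol does not define; the engine scores non-overlapping blocks of
  20 trials, small enough that a strong responder can climb from 1-back to
  3-back within one session (a perfect responder does so in exactly 4
  blocks). The level never decreases and is capped at 3. Warm-up positions
  (fewer than *n* predecessors) present stimuli but emit no scored trial.
  Target rate 0.3 per block, exact by construction.
* **Matrix.** Span starts at 3; three consecutive successes raise it, three
  consecutive failures lower it (symmetric reading of the three-times
  threshold), floored at span 2. A trial succeeds only on an exact match of
  the highlighted cell set within the 3 s response window. The grid is 5×5,
  growing to 6×6 once span exceeds 8 so patterns stay feasible — grid size
  is unstated in the protocol and configurable.

Drug-related words/pictures are opaque tokens from a category-tagged
lexicon CSV; a synthetic placeholder lexicon ships with the package.

## Assessments

* **DDT.** Delayed amount 1000, first offer 500, delays
  {2, 7, 30, 90, 180, 360} days, six adjustments with steps 250, 125, …
  halving each trial; the final adjusted offer is V(D). This is the
  standard decreasing-adjustment implementation consistent with a 500-of-
  1000 starting offer; the protocol names only the algorithm family. Offer
  arithmetic uses `fractions.Fraction`, so indifference points are exact
  decimals (always-immediate floor: 7.8125; ceiling: 992.1875). For any
  deterministic threshold chooser the staircase brackets the true
  indifference point within 500/2⁶ = 7.8125. `hyperbolic_k` inverts
  V = A/(1+kD) in closed form (V = A ⇒ k = 0 exactly; V ≤ 0 raises an
  undefined-score error rather than clamping); `fit_global_k` runs a
  bounded least-squares fit over delays, seeded at the median pointwise k,
  and reduces to the closed form for a single point. Delay order is
  ascending (configurable). Six adjustments rather than a convergence
  criterion is a fixed design choice (configurable).
* **IGT.** Canonical payoff magnitudes — wins 100 (A/B) vs 50 (C/D);
  per-10-block losses A {150,200,250,300,350}, B {1250}, C {25,75,50,50,50},
  D {250} — giving block nets of −250 vs +250. Loss positions are shuffled
  within each block under the seed; block totals are invariant. The deck
  labelling (which pair is advantageous) is configurable because published
  descriptions of the task disagree internally; the default follows the
  methods-text convention (C/D advantageous).
* **BART.** Explosion points are uniform on {1..128}, drawn before the run.
  The score formula "total inflations / unexploded balloons" is ambiguous;
  the engine computes the literal reading as primary and the conventional
  adjusted score (banked pumps / unexploded) alongside. Literal ≥ adjusted
  always, with equality iff nothing exploded. Points = 10 × banked pumps.
* **Stroop.** "Each of the 16 words presented eight times in four colours"
  is read as 8 total presentations per word (2 per colour; 128 trials); the
  32-per-word reading (512 trials) is available via
  `presentations_per_word=32`. The sequence is a seeded shuffle constrained
  to at most 3 consecutive trials of the same word category, built by
  constrained sequential sampling with restart. Words stay on screen
  3000 ms; a slower response is a timeout. Bias uses correct trials only;
  per-category error rates are always reported, and a category with no
  correct trials flags the bias undefined.

## Simulated respondents

* **Discounter:** threshold rule on V = A/(1+kD) (tie → delayed); optional
  logistic choice noise in the value difference (temperature in currency
  units). Noiseless recovery of k through titration + fit is exact to the
  staircase resolution for k ∈ [0.002, 0.25] (verified in tests).
* **Gambler:** delta-rule learner, V_d ← V_d + α(net − V_d) on the chosen
  deck, softmax(V/τ) choice. With α = 0.2, τ = 10 the mean net score over
  seeded 150-trial runs is strongly positive. This is a single-parameter
  test fixture, not a cognitive-process claim (no full expectancy-valence
  model).
* **Pumper:** fixed intended pump count T; with uniform explosions on
  {1..128} and T = 64 half the balloons burst in expectation.
* **Responder:** correct with probability p(level) (level = n-back level or
  matrix span; other tasks use level 1), otherwise a uniform wrong token
  (or a one-cell perturbation of the matrix pattern). Latency is lognormal
  (default median 600 ms, σ_log 0.3) with a 150 ms floor — chosen for
  realistic positive skew; the protocol specifies no latency model — plus
  an additive shift on drug-category trials, so the generating shift *is*
  the expected Stroop bias.

## Statistics

`summary_f_test` computes the pooled-variance two-sample statistic from
(n, mean, SD) alone and reports F = t² with df (1, n1+n2−2). On the
published baseline table (n = 20 per arm) it reproduces the printed values
for age (1.200), education (0.525) and age of onset (0.084) to printed
rounding. Two printed rows do **not** recompute from their own summaries —
abstinence (printed 0.224, recomputed 0.290) and the frequency χ² (printed
2.4, recomputed 2.0 without continuity correction, 1.21 with) — so those
rows are documented as discrepancies and not used as checks. χ² is Pearson
without continuity correction.

The original analysis fit GEEs in SPSS. This module substitutes an exactly
specified 2×2 mixed ANOVA: for two time points it decomposes each subject
into a sum (between-subject part: group and subject-within-group SS) and a
difference (within-subject part: time, interaction, residual SS), making
the five-way partition of SS_total exact for arbitrary group sizes — in a
balanced 2×2 design the interaction test is the two-sample t on change
scores, which is also what an exchangeable-correlation GEE tests there. The
implementation is cross-checked against `pingouin.mixed_anova` in the test
suite. Zero-variance denominators are flagged (F = 0 when the numerator is
also zero, infinite-F flag otherwise) instead of returning NaN. Post hoc
paired contrasts within each group are Bonferroni-corrected by the family
size 2 (the protocol names Bonferroni without a family size).

The trial generator draws value = μ(group, time) + subject intercept +
residual, all normal. Under this model the interaction test is exactly
calibrated (type-I ≈ 0.05, verified over 1000 replicates at n = 20/arm) and
its power has a closed noncentral-t form (`analytic_interaction_power`),
which the simulated power matches.

## Study replica

`run_study_replica` runs each simulated subject through pre-assessment,
training (training arm only: default 20 sessions, each program twice) and
post-assessment, writes all logs, a per-subject score table and the ANOVA
per outcome. Between-subject heterogeneity (lognormal jitter on k, additive
jitter on pump threshold and latency shift) is sampled once per subject and
applied to both their pre and post parameters, preserving within-subject
correlation. The default "training effect" is a configured parameter shift
(k 0.08 → 0.02, learning rate 0.05 → 0.25, pump threshold 80 → 55, Stroop
latency shift unchanged) chosen so the demo reproduces the qualitative
pattern of interest — the training arm improves on the decision tasks while
attention bias shows no differential change; it is a demonstration setting,
not an efficacy claim. Deterministic agent components (e.g. a fixed pump
threshold) produce zero within-subject variance on some scores; the ANOVA
reports these honestly as infinite-F flags, and the replica's analysis
table skips outcomes with non-finite values. Replica runs are resumable:
intact logs are reused (safe because streams are scoped per task/session),
corrupt logs raise an integrity error.

## Problem sizes and determinism

Defaults used throughout tests and the acceptance script: 240/150/100/128
trials for ACT/IGT/BART/Stroop, 140 ABM trials, 4 n-back blocks, 40 matrix
trials; simulation-based checks use 100–2000 runs and the null calibration
1000 replicates at n = 20/arm. These sizes make every stochastic assertion
stable under its fixed seeds while keeping a full run in the tens of
seconds. All randomness flows from explicit seeds; reruns are
byte-identical.

## What the synthetic data does and does not show

The simulated respondents exercise the machinery — schedules, staircases,
titration, scoring, the ANOVA — with known ground truth, so passing tests
demonstrate that the engine measures what its inputs generate (parameter
recovery, calibration, exact scoring). They do not model real human
behaviour: no fatigue, learning transfer between tasks, sequential
dependencies, lapses beyond a constant timeout rate, or realistic
RT-accuracy trade-offs; the delta-rule gambler is deliberately minimal; and
nothing here constitutes evidence about the efficacy of cognitive training
in any clinical population. The proprietary cognitive-battery assessments
used alongside this battery in clinical work (verbal list learning, paired
associate learning, maze learning, social-emotional cognition) are out of
scope; their scores would enter only as outcome columns in the ANOVA.
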