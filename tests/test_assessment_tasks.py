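"""Titration, discounting fits, gambling/balloon/Stroop scoring."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ccat import (
    BARTConfig,
    DDTConfig,
    IGTConfig,
    RunSeed,
    StroopConfig,
    UndefinedScoreError,
    bart_score,
    ddt_titrate,
    fit_global_k,
    generate_bart_schedule,
    generate_igt_schedule,
    generate_stroop_schedule,
    hyperbolic_k,
    igt_net_score,
    run_session,
    score_ddt,
    stroop_bias,
)
from ccat.assessment_tasks import balloons_from_events, igt_choices_from_events
from ccat.session_core import MAIN, TaskId, make_event
from ccat.synthetic_agents import DDTAgent, DDTParams


class TestTitration:
    def test_always_immediate_descends_to_7_8125(self):
        v = ddt_titrate(lambda imm, A, D: "immediate", DDTConfig(), 30)
        assert v == Fraction(500) - Fraction("492.1875")
        assert float(v) == 7.8125

    def test_always_delayed_ascends_to_992_1875(self):
        v = ddt_titrate(lambda imm, A, D: "delayed", DDTConfig(), 30)
        assert float(v) == 992.1875

    def test_noiseless_hyperbolic_agent_brackets_true_value(self):
        agent = DDTAgent(DDTParams(k_true=0.05))
        rng = np.random.default_rng(0)
        v = ddt_titrate(lambda imm, A, D: agent.ddt_choose(imm, A, D, rng),
                        DDTConfig(), 30)
        assert abs(float(v) - 400.0) <= 500 / 2 ** 6

    @pytest.mark.parametrize("k", [0.002, 0.01, 0.05, 0.25])
    def test_bracket_property_all_delays(self, k):
        cfg = DDTConfig()
        agent = DDTAgent(DDTParams(k_true=k))
        rng = np.random.default_rng(1)
        for delay in cfg.delays_days:
            v = ddt_titrate(lambda imm, A, D: agent.ddt_choose(imm, A, D, rng),
                            cfg, delay)
            v_true = cfg.delayed_amount / (1 + k * delay)
            assert abs(float(v) - v_true) <= cfg.initial_immediate / 2 ** cfg.n_adjustments


class TestHyperbolicK:
    def test_no_discounting_gives_zero(self):
        assert hyperbolic_k(1000, 1000, 30) == 0.0

    def test_half_value_at_delay_d_means_kd_equals_one(self):
        assert hyperbolic_k(500, 1000, 30) == pytest.approx(1 / 30)

    def test_inverts_the_decay_model(self):
        assert hyperbolic_k(400, 1000, 30) == pytest.approx(0.05)

    def test_nonpositive_value_flagged_not_clamped(self):
        with pytest.raises(UndefinedScoreError):
            hyperbolic_k(0.0, 1000, 30)
        with pytest.raises(UndefinedScoreError):
            hyperbolic_k(1001, 1000, 30)

    @given(st.floats(min_value=0, max_value=5),
           st.integers(min_value=1, max_value=720))
    def test_round_trip(self, k, d):
        v = 1000 / (1 + k * d)
        assert hyperbolic_k(v, 1000, d) == pytest.approx(k, abs=1e-9, rel=1e-9)


class TestGlobalKFit:
    def test_noiseless_points_recovered_exactly(self):
        cfg = DDTConfig()
        points = {d: 1000 / (1 + 0.02 * d) for d in cfg.delays_days}
        assert fit_global_k(points, 1000) == pytest.approx(0.02, abs=1e-6)

    def test_single_point_reduces_to_closed_form(self):
        assert fit_global_k({30: 500}, 1000) == pytest.approx(1 / 30)

    def test_no_discounting_anywhere_gives_zero(self):
        assert fit_global_k({d: 1000.0 for d in (2, 30, 360)}, 1000) == 0.0

    def test_robust_to_multiplicative_noise(self, rng):
        # median over replicates within 20% of the generating rate
        cfg = DDTConfig()
        errors = []
        for _ in range(100):
            noise = rng.uniform(0.95, 1.05, size=len(cfg.delays_days))
            points = {d: min(1000.0, 1000 / (1 + 0.02 * d) * x)
                      for d, x in zip(cfg.delays_days, noise)}
            errors.append(abs(fit_global_k(points, 1000) - 0.02) / 0.02)
        assert np.median(errors) < 0.20


class TestDDTSessionScoring:
    def test_run_and_rescore_recovers_k(self, agent):
        cfg = DDTConfig()
        events = run_session(cfg, agent, RunSeed(5, "DDT/x"), "x")
        assert len(events) == len(cfg.delays_days) * cfg.n_adjustments
        res = score_ddt(events, cfg)
        # default agent discounts at k=0.05 noiselessly
        assert res.k_global == pytest.approx(0.05, rel=0.05)
        for d, v in res.indifference_points.items():
            assert abs(v - 1000 / (1 + 0.05 * d)) <= 7.8125

    def test_tampered_log_detected(self, agent):
        cfg = DDTConfig()
        events = run_session(cfg, agent, RunSeed(5, "DDT/x"), "x")
        bad = list(events)
        stim = dict(bad[3].stimulus, immediate=123.0)
        bad[3] = make_event(TaskId.DDT, "x", 3, MAIN, stim,
                            bad[3].correct_response, bad[3].given_response, 0.0,
                            training_feedback=False)
        with pytest.raises(UndefinedScoreError):
            score_ddt(bad, cfg)


class TestIGT:
    def test_net_score_examples(self):
        assert igt_net_score(["C", "D"] * 75) == 150
        assert igt_net_score(["A"] * 75 + ["C"] * 75) == 0
        assert igt_net_score(["A"] * 40 + ["B"] * 35 + ["C"] * 45 + ["D"] * 30) == 0

    def test_conservation_identity(self, rng):
        for _ in range(20):
            choices = [("A", "B", "C", "D")[i] for i in rng.integers(4, size=150)]
            n_dis = sum(c in ("A", "B") for c in choices)
            assert igt_net_score(choices) + 2 * n_dis == len(choices)

    def test_canonical_block_nets(self, rng):
        cfg = IGTConfig()
        sched = generate_igt_schedule(cfg, rng)
        for deck, cards in sched.decks.items():
            assert len(cards) >= cfg.n_trials
            for b in range(len(cards) // 10):
                net = sum(w - l for w, l in cards[10 * b:10 * b + 10])
                assert net == (250 if deck in ("C", "D") else -250)

    def test_label_convention_configurable(self, rng):
        cfg = IGTConfig(advantageous=("A", "B"))
        sched = generate_igt_schedule(cfg, rng)
        net_a = sum(w - l for w, l in sched.decks["A"][:10])
        assert net_a == 250
        assert igt_net_score(["A"] * 10, advantageous=("A", "B")) == 10

    def test_session_emits_150_trials(self, agent):
        events = run_session(IGTConfig(), agent, RunSeed(0, "IGT/x"), "x")
        assert len(events) == 150
        assert set(igt_choices_from_events(events)) <= {"A", "B", "C", "D"}


class TestBART:
    def test_literal_and_adjusted_examples(self):
        s = bart_score([(5, False), (3, False)])
        assert (s.literal, s.adjusted) == (4.0, 4.0)
        s = bart_score([(10, True), (4, False), (6, False)])
        assert (s.literal, s.adjusted) == (10.0, 5.0)
        assert s.points == 100
        s = bart_score([(0, False)] * 3)
        assert s.literal == 0.0 and s.points == 0

    def test_all_exploded_is_undefined(self):
        s = bart_score([(10, True), (20, True)])
        assert s.undefined and math.isnan(s.literal)

    def test_literal_dominates_adjusted(self, rng):
        for _ in range(50):
            balloons = [(int(p), bool(e)) for p, e in
                        zip(rng.integers(0, 50, size=30), rng.integers(2, size=30))]
            if all(e for _, e in balloons):
                continue
            s = bart_score(balloons)
            assert s.literal >= s.adjusted
            if not any(e for _, e in balloons):
                assert s.literal == s.adjusted

    def test_schedule_uniform_explosion_points(self, rng):
        cfg = BARTConfig(n_balloons=100_000)
        sched = generate_bart_schedule(cfg, rng)
        pts = np.array(sched.explosion_points)
        assert pts.min() >= 1 and pts.max() <= 128
        assert abs(pts.mean() - 64.5) / 64.5 < 0.01

    def test_session_has_100_balloons(self, agent):
        events = run_session(BARTConfig(), agent, RunSeed(0, "BART/x"), "x")
        assert len(events) == 100
        balloons = balloons_from_events(events)
        # threshold agent: banked balloons show exactly T pumps
        assert all(p == 64 for p, e in balloons if not e)


class TestStroop:
    def test_schedule_counts_and_balance(self, rng):
        sched = generate_stroop_schedule(StroopConfig(), rng)
        assert len(sched) == 128
        by_word = {}
        for item in sched:
            by_word.setdefault(item.word_token, []).append(item.ink)
        assert len(by_word) == 16
        for inks in by_word.values():
            assert len(inks) == 8
            assert all(inks.count(c) == 2 for c in ("red", "green", "yellow", "blue"))
        cats = [item.category for item in sched]
        assert sum(c == "meth_word" for c in cats) == 64
        runs = max(len(list(g)) for _, g in __import__("itertools").groupby(cats))
        assert runs <= 3

    def test_wide_reading_available_via_config(self, rng):
        sched = generate_stroop_schedule(StroopConfig(presentations_per_word=32), rng)
        assert len(sched) == 512

    def test_bias_arithmetic(self):
        def ev(i, cat, latency, correct=True):
            return make_event(TaskId.STROOP, "s", i, MAIN,
                              {"category": cat, "ink": "red"}, "red",
                              "red" if correct else "blue", latency,
                              training_feedback=False)
        log = [ev(0, "meth_word", 800), ev(1, "meth_word", 800),
               ev(2, "neutral_word", 650), ev(3, "neutral_word", 650)]
        res = stroop_bias(log)
        assert res.bias_ms == pytest.approx(150.0)
        log = [ev(0, "meth_word", 700), ev(1, "neutral_word", 700)]
        assert stroop_bias(log).bias_ms == 0.0

    def test_category_without_correct_trials_flagged(self):
        def ev(i, cat, correct):
            return make_event(TaskId.STROOP, "s", i, MAIN,
                              {"category": cat}, "red",
                              "red" if correct else "blue", 500.0,
                              training_feedback=False)
        res = stroop_bias([ev(0, "meth_word", False), ev(1, "neutral_word", True)])
        assert res.undefined and math.isnan(res.bias_ms)
        assert res.error_rate_meth == 1.0 and res.error_rate_neutral == 0.0
        with pytest.raises(UndefinedScoreError):
            stroop_bias([ev(0, "meth_word", True)])

    def test_unbiased_agent_bias_concentrates_near_zero(self, agent):
        biases = [stroop_bias(run_session(StroopConfig(), agent,
                                          RunSeed(s, "STROOP/cal"), "c")).bias_ms
                  for s in range(40)]
        # default agent has no category effect; CLT keeps |bias| small
        assert abs(np.mean(biases)) < 15.0
        assert np.mean(np.abs(np.array(biases)) < 100.0) > 0.95
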