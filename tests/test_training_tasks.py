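"""Training-task rules, schedules and adaptive staircases."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ccat import (
    ABMConfig,
    ABMStimulus,
    ACTConfig,
    ACTStimulus,
    ConfigurationError,
    MatrixConfig,
    MatrixState,
    NBackConfig,
    NBackState,
    NBackStimulus,
    RunSeed,
    abm_correct_response,
    act_correct_response,
    generate_abm_schedule,
    generate_act_schedule,
    generate_matrix_trial,
    generate_nback_block,
    matrix_update_span,
    nback_block_trajectory,
    nback_correct_response,
    nback_update_level,
    run_session,
)
from ccat.session_core import InvalidStimulusError, MAIN, PRACTICE
from ccat.training_tasks import (
    COLORS,
    CONSISTENT,
    INCONSISTENT,
    NO,
    YES,
    cells_token,
    parse_cells_token,
    grid_for_span,
)


def _abm(meaning, right_ink, *, left_ink="green", meth=True):
    return ABMStimulus(
        left_word_meaning=meaning, left_word_ink=left_ink,
        right_item_text_category="meth_word" if meth else "neutral_word",
        right_item_ink=right_ink,
        distractor_picture_category="meth" if meth else "none")


class TestABMRule:
    @pytest.mark.parametrize("meaning,right_ink,expected", [
        ("red", "red", CONSISTENT),       # word meaning 'red' printed green on left
        ("blue", "blue", CONSISTENT),     # distractor present but irrelevant
        ("yellow", "green", INCONSISTENT),
    ])
    def test_rule_examples(self, meaning, right_ink, expected):
        assert abm_correct_response(_abm(meaning, right_ink)) == expected

    def test_left_ink_and_distractor_are_ignored(self, rng):
        for _ in range(50):
            meaning, left_ink, right_ink = (COLORS[i] for i in rng.integers(4, size=3))
            meth = bool(rng.integers(2))
            got = abm_correct_response(_abm(meaning, right_ink, left_ink=left_ink, meth=meth))
            assert got == (CONSISTENT if meaning == right_ink else INCONSISTENT)

    def test_colour_alphabet_enforced(self):
        with pytest.raises(InvalidStimulusError):
            _abm("purple", "red")


class TestABMSchedule:
    def test_practice_has_no_meth_and_main_is_balanced(self, rng):
        cfg = ABMConfig()
        practice, main = generate_abm_schedule(cfg, rng)
        assert len(practice) == 20 and len(main) == 120
        assert all(s.distractor_picture_category == "none" and
                   s.right_item_text_category == "neutral_word" for s in practice)
        assert all(s.distractor_picture_category == "meth" for s in main)
        n_cons = sum(abm_correct_response(s) == CONSISTENT for s in main)
        assert n_cons == 60
        assert sum(abm_correct_response(s) == CONSISTENT for s in practice) == 10

    def test_infeasible_balance_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            generate_abm_schedule(ABMConfig(n_main=10, consistent_ratio=0.33), rng)


class TestACT:
    def test_single_picture_answer_is_its_border(self):
        s = ACTStimulus(1, ("meth",), ("red",))
        assert act_correct_response(s) == "red"
        assert act_correct_response(ACTStimulus(1, ("neutral",), ("green",))) == "green"

    def test_pair_answer_is_neutral_border(self):
        s = ACTStimulus(2, ("meth", "neutral"), ("blue", "yellow"))
        assert act_correct_response(s) == "yellow"
        s = ACTStimulus(2, ("neutral", "meth"), ("blue", "yellow"))
        assert act_correct_response(s) == "blue"

    def test_same_category_pair_is_invalid(self):
        with pytest.raises(InvalidStimulusError):
            act_correct_response(ACTStimulus(2, ("meth", "meth"), ("blue", "yellow")))

    def test_default_schedule_has_240_balanced_trials(self, rng):
        sched = generate_act_schedule(ACTConfig(), rng)
        assert len(sched) == 240
        assert sum(s.n_pictures == 2 for s in sched) == 120
        pairs = [s for s in sched if s.n_pictures == 2]
        assert all(set(s.picture_categories) == {"meth", "neutral"} for s in pairs)

    def test_rules_match_bruteforce_on_generated_trials(self, rng):
        for s in generate_act_schedule(ACTConfig(n_main=60), rng):
            if s.n_pictures == 1:
                expected = s.border_colors[0]
            else:
                expected = [b for b, c in zip(s.border_colors, s.picture_categories)
                            if c == "neutral"][0]
            assert act_correct_response(s) == expected


class TestNBackRule:
    def test_examples(self):
        rc = NBackStimulus("circle", "red")
        bt = NBackStimulus("triangle", "blue")
        rt = NBackStimulus("triangle", "red")
        assert nback_correct_response([rc, bt, rc], 2) == YES
        assert nback_correct_response([rc, rt], 1) == NO  # shape differs, colour same
        assert nback_correct_response([rc, bt, rt], 3) is None  # warm-up

    def test_conjunction_of_shape_and_colour(self, rng):
        block = generate_nback_block(NBackConfig(), 2, rng)
        history = []
        for stim in block:
            history.append(stim)
            got = nback_correct_response(history, 2)
            if len(history) <= 2:
                assert got is None
            else:
                ref = history[-3]
                assert got == (YES if (stim.figure_shape, stim.figure_color) ==
                               (ref.figure_shape, ref.figure_color) else NO)


class TestNBackStaircase:
    @pytest.mark.parametrize("accs,expected_level,expected_streak", [
        ([0.92, 0.95], 2, 0),            # two qualifying blocks advance
        ([0.92, 0.85, 0.95], 1, 1),      # failure resets the streak
        ([0.89], 1, 0),                  # strictly-below-threshold block
        ([0.90, 0.90], 2, 0),            # threshold is inclusive
        ([1.0, 1.0, 1.0, 1.0], 3, 0),
        ([1.0, 1.0, 1.0, 1.0, 1.0, 1.0], 3, 0),  # capped at 3
    ])
    def test_hand_simulated_traces(self, accs, expected_level, expected_streak):
        state = NBackState()
        for acc in accs:
            state = nback_update_level(state, acc)
        assert (state.level, state.success_streak) == (expected_level, expected_streak)

    @given(st.lists(st.floats(min_value=0, max_value=1), max_size=30))
    def test_level_monotone_and_bounded(self, accs):
        state = NBackState()
        levels = []
        for acc in accs:
            state = nback_update_level(state, acc)
            levels.append(state.level)
        assert all(1 <= l <= 3 for l in levels)
        assert levels == sorted(levels)

    def test_block_target_count_exact(self, rng):
        cfg = NBackConfig(target_rate=0.3, block_size=20)
        for level in (1, 2, 3):
            block = generate_nback_block(cfg, level, rng)
            assert len(block) == 20 + level
            history, targets = [], 0
            for stim in block:
                history.append(stim)
                targets += nback_correct_response(history, level) == YES
            assert targets == 6

    def test_perfect_agent_reaches_level3_in_exactly_4_blocks(self, perfect):
        events = run_session(NBackConfig(), perfect, RunSeed(11, "NBACK/x"), "x")
        levels, accs, final = nback_block_trajectory(events)
        assert levels == [1, 1, 2, 2]
        assert accs == [1.0] * 4
        assert final.level == 3

    def test_coin_flip_agent_stays_at_level1(self, sloppy):
        # P(>=90% of 20 at p=.5) ~ 2e-5: never qualifies over these seeds
        from ccat import AgentParams, BatteryAgent
        from ccat.synthetic_agents import ResponderParams
        coin = BatteryAgent(AgentParams(responder=ResponderParams(
            p_correct={}, p_correct_default=0.5)))
        for s in range(5):
            events = run_session(NBackConfig(), coin, RunSeed(s, "NBACK/coin"), "c")
            levels, _, final = nback_block_trajectory(events)
            assert set(levels) == {1} and final.level == 1


class TestMatrixStaircase:
    def test_three_successes_raise_three_failures_lower(self):
        state = MatrixState(span=3)
        for _ in range(3):
            state = matrix_update_span(state, True)
        assert state.span == 4 and state.success_streak == 0
        state = MatrixState(span=3)
        for _ in range(3):
            state = matrix_update_span(state, False)
        assert state.span == 2 and state.failure_streak == 0

    def test_interrupted_streak_resets(self):
        state = MatrixState(span=3)
        for ok in (True, True, False, True):
            state = matrix_update_span(state, ok)
        assert state.span == 3 and state.success_streak == 1 and state.failure_streak == 0

    def test_span_floored_at_minimum(self):
        state = MatrixState(span=2, span_min=2)
        for _ in range(9):
            state = matrix_update_span(state, False)
        assert state.span == 2

    @given(st.lists(st.booleans(), max_size=60))
    def test_span_moves_by_at_most_one_and_streaks_exclusive(self, outcomes):
        state = MatrixState(span=3)
        for ok in outcomes:
            nxt = matrix_update_span(state, ok)
            assert abs(nxt.span - state.span) <= 1
            assert nxt.span >= state.span_min
            assert not (nxt.success_streak > 0 and nxt.failure_streak > 0)
            state = nxt

    def test_trial_cells_distinct_within_grid(self, rng):
        cfg = MatrixConfig()
        trial = generate_matrix_trial(MatrixState(span=5), cfg, rng)
        assert len(trial.target_cells) == 5
        assert trial.grid_dims == (5, 5)
        big = generate_matrix_trial(MatrixState(span=9), cfg, rng)
        assert big.grid_dims == (6, 6)
        assert grid_for_span(cfg, 9) == (6, 6)

    def test_cells_token_round_trip(self, rng):
        cells = frozenset({(0, 1), (3, 2), (4, 4)})
        assert parse_cells_token(cells_token(cells)) == cells

    def test_session_span_trajectory_matches_replay(self, perfect):
        events = run_session(MatrixConfig(n_main=12), perfect, RunSeed(2, "MATRIX/x"), "x")
        spans = [ev.stimulus["span"] for ev in events]
        # replay the staircase from logged outcomes
        state = MatrixState(span=3)
        expected = []
        for ev in events:
            expected.append(state.span)
            state = matrix_update_span(state, ev.correct)
        assert spans == expected
        assert spans == [3, 3, 3, 4, 4, 4, 5, 5, 5, 6, 6, 6]
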