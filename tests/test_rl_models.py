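import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nkbandit import (
    ModelParams,
    TaskConfig,
    choice_probabilities,
    init_beliefs,
    negative_log_likelihood,
    option_values,
    simulate_agent,
    update_beliefs,
)
from nkbandit.task_design import GameSpec, TaskSchedule


class TestBeliefUpdates:
    def test_initial_state(self):
        s = init_beliefs(50)
        assert np.allclose(s.q, 50) and s.count.sum() == 0 and s.novel.all()
        # zero counts: knowledge term contributes nothing for any k
        p = ModelParams(model_id="kRL", k=5.0)
        assert np.allclose(option_values(s, p), s.q)

    def test_delta_rule_arithmetic(self):
        s = init_beliefs(50)
        p = ModelParams(alpha=0.5)
        s2 = update_beliefs(s, 1, 70, p)
        assert s2.q[1] == 60 and s2.q[0] == 50 and s2.q[2] == 50
        assert s2.count[1] == 1 and not s2.novel[1] and s2.novel[0]

    def test_alpha_limits(self):
        s = init_beliefs(50)
        full = update_beliefs(s, 0, 93, ModelParams(alpha=1.0))
        assert full.q[0] == 93
        frozen = update_beliefs(s, 0, 93, ModelParams(alpha=0.0))
        assert frozen.q[0] == 50
        # information tracking is independent of reward learning
        assert frozen.count[0] == 1 and not frozen.novel[0]

    @given(
        rewards=st.lists(st.integers(1, 100), min_size=1, max_size=12),
        choices=st.lists(st.integers(0, 2), min_size=12, max_size=12),
        alpha=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_q_stays_in_convex_hull_of_q0_and_rewards(self, rewards, choices, alpha):
        p = ModelParams(alpha=alpha)
        s = init_beliefs(50)
        for c, r in zip(choices, rewards * 12):
            s = update_beliefs(s, c, r, p)
        lo, hi = min(50, min(rewards)), max(50, max(rewards))
        assert np.all(s.q >= lo - 1e-9) and np.all(s.q <= hi + 1e-9)


class TestOptionValues:
    def test_knowledge_term_with_group_mean_k(self):
        s = init_beliefs(50)
        s.q[:] = 40.0
        s.count[:] = 3
        s.novel[:] = False
        p = ModelParams(model_id="nkRL", k=1.38, nu=99.0)
        assert option_values(s, p)[0] == pytest.approx(40 + 3 * 1.38)  # 44.14

    def test_novelty_bonus_on_unseen_deck(self):
        s = init_beliefs(50)
        p = ModelParams(model_id="nkRL", k=123.0, nu=12.43)
        assert option_values(s, p)[2] == pytest.approx(62.43)

    def test_nkrl_with_zero_bonuses_is_srl(self):
        rng = np.random.default_rng(0)
        s = init_beliefs(50)
        for _ in range(8):
            s = update_beliefs(s, int(rng.integers(3)), int(rng.integers(1, 101)),
                               ModelParams(alpha=0.4))
        nk = ModelParams(model_id="nkRL", alpha=0.4, k=0.0, nu=0.0)
        srl = ModelParams(model_id="sRL", alpha=0.4)
        assert np.allclose(option_values(s, nk), option_values(s, srl))

    def test_gamma_one_and_leak_one_reduce_to_nkrl(self):
        s = init_beliefs(50)
        for c, r in [(0, 60), (1, 20), (0, 80), (2, 44)]:
            s = update_beliefs(s, c, r, ModelParams(model_id="leaky_nkRL", leak=1.0))
        base = ModelParams(model_id="nkRL", k=1.5, nu=7.0)
        g1 = ModelParams(model_id="gnkRL", k=1.5, nu=7.0, gamma=1.0)
        l1 = ModelParams(model_id="leaky_nkRL", k=1.5, nu=7.0, leak=1.0)
        v = option_values(s, base)
        assert np.allclose(option_values(s, g1), v)
        assert np.allclose(option_values(s, l1), v)

    def test_novelty_fires_at_most_once_per_deck(self):
        p = ModelParams(model_id="nkRL", nu=10.0)
        s = init_beliefs(50)
        v_before = option_values(s, p)
        s = update_beliefs(s, 1, 50, ModelParams(alpha=0.0))
        v_after = option_values(s, p)
        assert v_before[1] - v_after[1] == pytest.approx(10.0)
        s = update_beliefs(s, 1, 50, ModelParams(alpha=0.0))
        assert option_values(s, p)[1] == v_after[1] + 0.0  # bonus gone for good


class TestChoiceProbabilities:
    def test_zero_beta_is_uniform(self):
        assert np.allclose(choice_probabilities(np.array([90.0, 10.0, 5.0]), 0.0), 1 / 3)

    def test_equal_values_are_uniform_for_any_beta(self):
        assert np.allclose(choice_probabilities(np.array([42.0] * 3), 5.0), 1 / 3)

    def test_argmax_limit(self):
        p = choice_probabilities(np.array([100.0, 0.0, 0.0]), 10.0)
        assert p[0] > 1 - 1e-6

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            choice_probabilities(np.array([np.inf, 0.0, 0.0]), 1.0)

    @given(
        v=st.lists(st.floats(-500, 500), min_size=3, max_size=3),
        beta=st.floats(0, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_simplex_and_value_monotonicity(self, v, beta):
        p = choice_probabilities(np.array(v), beta)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)  # extreme beta*value gaps may underflow to 0.0
        order = np.argsort(v)
        assert p[order[0]] <= p[order[2]] + 1e-12


class TestSimulation:
    def test_determinism(self, default_schedule, hc_like_params):
        a = simulate_agent(default_schedule, hc_like_params, seed=5)
        b = simulate_agent(default_schedule, hc_like_params, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_forced_phase_follows_script(self, simulated_log, default_schedule):
        forced = simulated_log[simulated_log.phase == "forced"]
        assert (forced.choice == forced.forced_deck).all()
        for g in default_schedule.games[:20]:
            rows = simulated_log[simulated_log.game_index == g.game_index]
            assert tuple(rows[rows.phase == "forced"].choice) == g.forced_sequence
            assert (rows.phase == "free").sum() == g.free_horizon

    def test_greedy_limit_picks_best_deck(self):
        game = GameSpec(
            game_index=0,
            deck_means=(70, 10, 10),
            reward_condition="LOW_REWARD",
            info_condition="EQUAL_INFO",
            forced_sequence=(0, 1, 2, 0, 1, 2),
            free_horizon=6,
        )
        sched = TaskSchedule(
            games=(game,) * 30, config=TaskConfig(outcome_sd=0), seed=0
        )
        greedy = ModelParams(model_id="nkRL", alpha=0.5, beta=100.0, k=0.0, nu=0.0)
        log = simulate_agent(sched, greedy, seed=1)
        assert (log[log.phase == "free"].choice == 0).all()

    def test_beta_zero_choices_are_uniform(self, default_schedule):
        p = ModelParams(model_id="nkRL", alpha=0.3, beta=0.0, k=3.0, nu=20.0)
        log = simulate_agent(default_schedule, p, seed=3)
        freqs = log[log.phase == "free"].choice.value_counts(normalize=True)
        assert freqs.max() < 0.4 and len(freqs) == 3

    def test_likelihood_nesting_identities_on_simulated_data(self, simulated_log):
        # nkRL collapses exactly onto its nested relatives on any log
        a, b, k = 0.37, 0.22, 1.1
        nll = negative_log_likelihood
        assert nll(
            simulated_log, ModelParams(model_id="nkRL", alpha=a, beta=b, k=0, nu=0)
        ) == pytest.approx(
            nll(simulated_log, ModelParams(model_id="sRL", alpha=a, beta=b)), abs=1e-12
        )
        assert nll(
            simulated_log, ModelParams(model_id="nkRL", alpha=a, beta=b, k=k, nu=0)
        ) == pytest.approx(
            nll(simulated_log, ModelParams(model_id="kRL", alpha=a, beta=b, k=k)),
            abs=1e-12,
        )


def test_invalid_model_and_parameter_ranges_rejected():
    with pytest.raises(ValueError, match="model_id"):
        ModelParams(model_id="qRL")
    with pytest.raises(ValueError, match="alpha"):
        ModelParams(alpha=1.5)
    with pytest.raises(ValueError, match="gamma"):
        ModelParams(gamma=0.0)
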