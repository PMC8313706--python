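import math

import numpy as np
import pandas as pd
import pytest

from nkbandit import (
    TaskConfig,
    choice_type_frequencies,
    classify_first_free_choice,
    novelty_familiarity_shift,
    parameter_distance,
    performance,
    performance_correlations,
    performance_landscape,
    predict_group,
    predict_severity,
    summarize_subject,
)
from nkbandit.behavioral_metrics import classify_trial_log, find_local_maxima


def make_game(
    info_condition,
    forced_choices,
    forced_rewards,
    free_choices,
    free_rewards=None,
    game_index=0,
    subject_id="s",
):
    free_rewards = free_rewards or [50] * len(free_choices)
    rows = []
    for t, (c, r) in enumerate(zip(forced_choices, forced_rewards)):
        rows.append(
            dict(subject_id=subject_id, game_index=game_index, trial_index=t,
                 phase="forced", info_condition=info_condition,
                 reward_condition="EQUAL_REWARD", choice=c, reward=r, forced_deck=c)
        )
    for i, (c, r) in enumerate(zip(free_choices, free_rewards)):
        rows.append(
            dict(subject_id=subject_id, game_index=game_index, trial_index=6 + i,
                 phase="free", info_condition=info_condition,
                 reward_condition="EQUAL_REWARD", choice=c, reward=r, forced_deck=None)
        )
    return pd.DataFrame(rows)


# forced phase sampling deck0 four times, deck1 twice, deck2 never
UNEQ = dict(
    info_condition="UNEQUAL_INFO",
    forced_choices=[0, 0, 1, 0, 1, 0],
)


class TestClassification:
    def test_novel_deck_choice_is_novelty_seeking(self):
        g = make_game(forced_rewards=[50, 50, 40, 50, 40, 50], free_choices=[2], **UNEQ)
        assert classify_first_free_choice(g) == "NOVELTY_SEEKING"

    def test_twice_sampled_lower_mean_deck_is_general_info_seeking(self):
        g = make_game(forced_rewards=[50, 50, 40, 50, 40, 50], free_choices=[1], **UNEQ)
        assert classify_first_free_choice(g) == "GENERAL_INFO_SEEKING"

    def test_higher_empirical_mean_deck_is_reward_seeking_even_if_sampled_twice(self):
        g = make_game(forced_rewards=[30, 30, 60, 30, 60, 30], free_choices=[1], **UNEQ)
        assert classify_first_free_choice(g) == "REWARD_SEEKING"

    def test_most_sampled_lower_mean_deck_is_familiar(self):
        g = make_game(forced_rewards=[30, 30, 60, 30, 60, 30], free_choices=[0], **UNEQ)
        assert classify_first_free_choice(g) == "FAMILIAR"

    def test_empirical_mean_tie_is_unclassified(self):
        g = make_game(forced_rewards=[50, 50, 50, 50, 50, 50], free_choices=[1], **UNEQ)
        assert classify_first_free_choice(g) == "UNCLASSIFIED"

    @pytest.mark.parametrize(
        "choice,expected",
        [(0, "UNDIRECTED_EXPLORATION"), (1, "UNCLASSIFIED"), (2, "REWARD_SEEKING")],
    )
    def test_equal_info_games_split_on_empirical_mean(self, choice, expected):
        g = make_game(
            info_condition="EQUAL_INFO",
            forced_choices=[0, 1, 2, 0, 1, 2],
            forced_rewards=[20, 40, 60, 20, 40, 60],
            free_choices=[choice],
        )
        assert classify_first_free_choice(g) == expected

    def test_malformed_forced_history_rejected(self):
        g = make_game(
            info_condition="EQUAL_INFO",
            forced_choices=[0, 1, 2, 0, 1],
            forced_rewards=[20, 40, 60, 20, 40],
            free_choices=[0],
        )
        with pytest.raises(ValueError, match="forced trials"):
            classify_first_free_choice(g)

    def test_classification_partitions_first_free_trials(self, simulated_log):
        cl = classify_trial_log(simulated_log)
        n_games_with_free = simulated_log.groupby("game_index")["phase"].apply(
            lambda p: (p == "free").any()
        ).sum()
        assert len(cl) == n_games_with_free
        assert set(cl.choice_class) <= {
            "NOVELTY_SEEKING", "GENERAL_INFO_SEEKING", "REWARD_SEEKING",
            "FAMILIAR", "UNDIRECTED_EXPLORATION", "UNCLASSIFIED",
        }


class TestFrequencies:
    def test_ratio_arithmetic_and_shared_denominator(self):
        games = []
        rewards_low1 = [50, 50, 40, 50, 40, 50]  # deck1 lower mean
        for i in range(1):
            games.append(make_game(forced_rewards=rewards_low1, free_choices=[2],
                                   game_index=i, **UNEQ))
        for i in range(1, 4):
            games.append(make_game(forced_rewards=[30, 30, 60, 30, 60, 30],
                                   free_choices=[1], game_index=i, **UNEQ))
        log = pd.concat(games, ignore_index=True)
        f = choice_type_frequencies(log)
        assert f["freq_novelty_vs_reward"] == pytest.approx(0.25)
        assert f["freq_reward_vs_novelty"] == pytest.approx(0.75)
        assert f["denom_novelty_reward"] == 4
        assert f["freq_novelty_vs_reward"] + f["freq_reward_vs_novelty"] == 1.0

    def test_empty_denominator_is_nan_not_zero(self):
        g = make_game(
            info_condition="EQUAL_INFO",
            forced_choices=[0, 1, 2, 0, 1, 2],
            forced_rewards=[20, 40, 60, 20, 40, 60],
            free_choices=[2],
        )
        f = choice_type_frequencies(g)
        assert math.isnan(f["freq_novelty_vs_reward"])
        assert f["denom_novelty_reward"] == 0
        assert f["freq_reward_vs_undirected"] == 1.0


class TestShiftAndPerformance:
    def test_always_least_sampled_policy_has_zero_shift(self):
        games = [
            make_game(forced_rewards=[50, 50, 40, 50, 40, 50],
                      free_choices=[2, 2, 2], game_index=i, **UNEQ)
            for i in range(3)
        ]
        s = novelty_familiarity_shift(pd.concat(games, ignore_index=True))
        assert s["first_informative"] == 1.0
        assert s["last_informative"] == 1.0
        assert s["shift"] == 0.0

    def test_informative_to_familiar_switch_gives_positive_shift(self):
        g = make_game(forced_rewards=[50, 50, 40, 50, 40, 50],
                      free_choices=[2, 0, 0], **UNEQ)
        s = novelty_familiarity_shift(g)
        assert s["first_informative"] == 1.0 and s["last_informative"] == 0.0
        assert s["shift"] == 1.0

    def test_performance_sums_free_rewards_only(self):
        g = make_game(forced_rewards=[99, 99, 99, 99, 99, 99],
                      free_choices=[0, 1, 2], free_rewards=[50, 60, 70], **UNEQ)
        assert performance(g) == 180
        g2 = g.copy()
        g2.loc[g2.phase == "forced", "reward"] = 1
        assert performance(g2) == 180  # invariant to forced rewards
        assert performance(g[g.phase == "forced"]) == 0

    def test_parameter_distance(self):
        assert parameter_distance(12.43, 0.43) == pytest.approx(12.0)
        assert parameter_distance(3.3, 3.3) == 0.0
        assert parameter_distance(2.0, 5.0) == parameter_distance(5.0, 2.0)
        with pytest.raises(ValueError):
            parameter_distance(float("nan"), 1.0)

    def test_subject_summary_includes_distance(self, simulated_log):
        row = summarize_subject(simulated_log, nu=12.43, k=0.43)
        assert row["d_vk"] == pytest.approx(12.0)
        assert row["pi"] == performance(simulated_log)


class TestRegressions:
    @staticmethod
    def _table(seed=0, n=60):
        rng = np.random.default_rng(seed)
        grp = np.array(["PG"] * (n // 2) + ["HC"] * (n // 2))
        k = np.where(grp == "PG", 1.4, 0.4) + rng.normal(0, 1.2, n)
        nu = np.where(grp == "PG", 5.6, 12.4) + rng.normal(0, 6.0, n)
        pi = 30_000 + 40 * nu + 300 * k + rng.normal(0, 500, n)
        sev = np.where(grp == "PG", 9.0, 0.0) + rng.normal(0, 1, n) * (grp == "PG")
        return pd.DataFrame({"group": grp, "k": k, "nu": nu, "pi": pi, "severity": sev})

    def test_group_logit_signs_on_separated_table(self):
        res = predict_group(self._table())
        coef = res["coefficients"]
        assert coef.loc["k", "coef"] > 0
        assert coef.loc["nu", "coef"] < 0

    def test_single_group_rejected(self):
        t = self._table()
        with pytest.raises(ValueError, match="two groups"):
            predict_group(t[t.group == "PG"])

    def test_severity_regression_runs(self):
        res = predict_severity(self._table())
        assert set(res["coefficients"].index) == {"const", "k", "nu"}

    def test_performance_correlations_are_fdr_corrected(self):
        out = performance_correlations(self._table())
        assert list(out["param"]) == ["nu", "k"]
        assert (out["p_fdr"] >= out["p"] - 1e-15).all()
        assert (out["r"] > 0).all()


class TestLandscape:
    def test_surface_reproducible_and_flat_under_uniform_policy(self):
        nu = np.linspace(0, 10, 3)
        k = np.linspace(0, 4, 3)
        cfg = TaskConfig(n_games=20)
        a = performance_landscape(nu, k, beta=0.0, n_reps=2, task_config=cfg, seed=3)
        b = performance_landscape(nu, k, beta=0.0, n_reps=2, task_config=cfg, seed=3)
        assert np.array_equal(a.mean_pi, b.mean_pi)
        # beta = 0 ignores values entirely; common random numbers make the
        # surface exactly constant, not merely statistically flat
        assert np.ptp(a.mean_pi) == 0.0

    def test_local_maxima_on_synthetic_two_bump_surface(self):
        nu = np.arange(5.0)
        k = np.arange(5.0)
        surf = np.zeros((5, 5))
        surf[1, 1] = 10.0
        surf[3, 3] = 12.0
        mx = find_local_maxima(surf, nu, k)
        peaks = {(row.nu, row.k) for row in mx.itertuples()}
        assert {(3.0, 3.0), (1.0, 1.0)} <= peaks

    def test_plateau_merges_into_single_mode(self):
        surf = np.ones((4, 4))
        mx = find_local_maxima(surf, np.arange(4.0), np.arange(4.0))
        assert len(mx) == 1 and mx.n_cells.iloc[0] == 16

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            performance_landscape([], [1.0], n_reps=1)
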