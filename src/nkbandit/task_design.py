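"""Forced/free-choice three-armed bandit task: design, schedule and outcomes.

The task is organised in games. Each game uses three decks of cards whose
payoffs are drawn from truncated Gaussians with fixed generative means
(stable within a game, redrawn across games). A game opens with six scripted
*forced* choices that control how often each deck has been sampled, followed
by a *free* horizon of 1-6 trials in which the player chooses and earns
points.

Two crossed manipulations define the conditions:

* reward condition — all three generative means equal (``EQUAL_REWARD``), or
  two decks share a mean that is higher (``HIGH_REWARD``) or lower
  (``LOW_REWARD``) than the third;
* information condition — the forced phase samples each deck twice
  (``EQUAL_INFO``) or samples the decks 4, 2 and 0 times (``UNEQUAL_INFO``),
  leaving one deck entirely novel at the start of free play.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REWARD_CONDITIONS = ("EQUAL_REWARD", "HIGH_REWARD", "LOW_REWARD")
INFO_CONDITIONS = ("EQUAL_INFO", "UNEQUAL_INFO")

N_DECKS = 3
N_FORCED = 6


@dataclass(frozen=True)
class TaskConfig:
    """Tunable design parameters of the task.

    Defaults give the standard design: 162 games, generative means built from
    a base of 30 or 50 points shifted by +/- {0, 4, 12, 20} points (support
    10..70), outcomes ~ round(truncGauss(mean, 8)) in [1, 100], and a free
    horizon of 1-6 trials with weights proportional to exp(0.5 * h) so that a
    6-trial horizon is the most frequent.
    """

    n_games: int = 162
    base_means: tuple[int, ...] = (30, 50)
    adjustments: tuple[int, ...] = (0, 4, 12, 20)
    outcome_sd: float = 8.0
    outcome_bounds: tuple[int, int] = (1, 100)
    horizon_lambda: float = 0.5
    horizon_weights: tuple[float, ...] | None = None
    p_unequal_info: float = 0.5
    p_equal_reward: float = 0.5
    p_high_given_unequal_reward: float = 0.25

    def resolved_horizon_weights(self) -> np.ndarray:
        if self.horizon_weights is not None:
            w = np.asarray(self.horizon_weights, dtype=float)
        else:
            w = np.exp(self.horizon_lambda * np.arange(1, 7))
        if w.shape != (6,) or np.any(w < 0):
            raise ValueError("horizon_weights must be 6 non-negative values")
        total = w.sum()
        if total <= 0:
            raise ValueError("horizon_weights must have positive mass")
        return w / total


@dataclass(frozen=True)
class GameSpec:
    """Design of a single game."""

    game_index: int
    deck_means: tuple[int, int, int]
    reward_condition: str
    info_condition: str
    forced_sequence: tuple[int, ...]
    free_horizon: int


@dataclass(frozen=True)
class TaskSchedule:
    """An ordered realisation of the full experimental design."""

    games: tuple[GameSpec, ...]
    config: TaskConfig
    seed: int

    def __len__(self) -> int:
        return len(self.games)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "game_index": g.game_index,
                "mean_deck0": g.deck_means[0],
                "mean_deck1": g.deck_means[1],
                "mean_deck2": g.deck_means[2],
                "reward_condition": g.reward_condition,
                "info_condition": g.info_condition,
                "forced_sequence": ";".join(str(d) for d in g.forced_sequence),
                "free_horizon": g.free_horizon,
                "seed": self.seed,
            }
            for g in self.games
        ]
        return pd.DataFrame(rows)


def schedule_from_frame(df: pd.DataFrame, config: TaskConfig | None = None) -> TaskSchedule:
    """Rebuild a :class:`TaskSchedule` from its serialized table."""
    games = tuple(
        GameSpec(
            game_index=int(r.game_index),
            deck_means=(int(r.mean_deck0), int(r.mean_deck1), int(r.mean_deck2)),
            reward_condition=str(r.reward_condition),
            info_condition=str(r.info_condition),
            forced_sequence=tuple(int(x) for x in str(r.forced_sequence).split(";")),
            free_horizon=int(r.free_horizon),
        )
        for r in df.itertuples()
    )
    seed = int(df["seed"].iloc[0]) if "seed" in df.columns and len(df) else 0
    return TaskSchedule(games=games, config=config or TaskConfig(), seed=seed)


def generative_mean_support(config: TaskConfig | None = None) -> list[int]:
    """Enumerate every generative mean the design can produce."""
    config = config or TaskConfig()
    support = {
        b + s * a
        for b, a in itertools.product(config.base_means, config.adjustments)
        for s in (-1, 1)
    }
    return sorted(support)


def _draw_mean(rng: np.random.Generator, config: TaskConfig) -> int:
    base = int(rng.choice(config.base_means))
    adj = int(rng.choice(config.adjustments))
    sign = int(rng.choice((-1, 1)))
    return base + sign * adj


def assign_generative_means(
    reward_condition: str,
    rng: np.random.Generator,
    config: TaskConfig | None = None,
) -> tuple[int, int, int]:
    """Draw the three deck means for a game, unordered (pair listed first).

    ``EQUAL_REWARD`` games share one mean; ``HIGH_REWARD``/``LOW_REWARD``
    games have two decks sharing a mean that is higher/lower than the third.
    Which physical decks receive which mean is decided later, when the means
    are laid onto the forced sequence.
    """
    config = config or TaskConfig()
    if reward_condition not in REWARD_CONDITIONS:
        raise ValueError(f"unknown reward condition {reward_condition!r}")
    if reward_condition == "EQUAL_REWARD":
        m = _draw_mean(rng, config)
        return (m, m, m)
    # draw two distinct means around a common base
    while True:
        base = int(rng.choice(config.base_means))
        a1, a2 = (
            int(rng.choice(config.adjustments)) * int(rng.choice((-1, 1)))
            for _ in range(2)
        )
        m1, m2 = base + a1, base + a2
        if m1 != m2:
            break
    hi, lo = max(m1, m2), min(m1, m2)
    if reward_condition == "HIGH_REWARD":
        return (hi, hi, lo)
    return (lo, lo, hi)


def build_forced_sequence(
    info_condition: str, rng: np.random.Generator
) -> tuple[int, ...]:
    """Randomly ordered six-trial forced sequence.

    ``EQUAL_INFO`` samples each deck twice; ``UNEQUAL_INFO`` samples the decks
    4, 2 and 0 times, with the (4, 2, 0) assignment randomised across decks.
    """
    if info_condition not in INFO_CONDITIONS:
        raise ValueError(f"unknown info condition {info_condition!r}")
    if info_condition == "EQUAL_INFO":
        counts = np.array([2, 2, 2])
    else:
        counts = np.zeros(3, dtype=int)
        decks = rng.permutation(3)
        counts[decks[0]], counts[decks[1]], counts[decks[2]] = 4, 2, 0
    seq = np.repeat(np.arange(3), counts)
    rng.shuffle(seq)
    return tuple(int(d) for d in seq)


def draw_free_horizon(
    rng: np.random.Generator, horizon_weights: np.ndarray | None = None
) -> int:
    """Sample the number of free-choice trials (1-6)."""
    if horizon_weights is None:
        horizon_weights = TaskConfig().resolved_horizon_weights()
    w = np.asarray(horizon_weights, dtype=float)
    if w.shape != (6,):
        raise ValueError("horizon weights must have length 6")
    if not math.isclose(float(w.sum()), 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError("horizon weights must sum to 1")
    return int(rng.choice(np.arange(1, 7), p=w))


def sample_outcome(
    mean: float, config: TaskConfig, rng: np.random.Generator
) -> int:
    """One card outcome: Gaussian(mean, sd), redrawn into bounds, rounded."""
    lo, hi = config.outcome_bounds
    if config.outcome_sd == 0:
        return int(round(mean))
    while True:
        x = rng.normal(mean, config.outcome_sd)
        if lo <= x <= hi:
            return int(np.rint(x))


def sample_outcomes(
    means: np.ndarray, config: TaskConfig, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised :func:`sample_outcome` for an array of generative means."""
    means = np.asarray(means, dtype=float)
    lo, hi = config.outcome_bounds
    if config.outcome_sd == 0:
        return np.rint(means).astype(int)
    x = rng.normal(means, config.outcome_sd)
    bad = (x < lo) | (x > hi)
    while np.any(bad):
        x[bad] = rng.normal(means[bad], config.outcome_sd)
        bad = (x < lo) | (x > hi)
    return np.rint(x).astype(int)


def largest_remainder_counts(n: int, proportions: list[float]) -> list[int]:
    """Allocate n items to categories by the largest-remainder rule."""
    quotas = [n * p for p in proportions]
    counts = [int(math.floor(q)) for q in quotas]
    short = n - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def _lay_means_on_decks(
    means: tuple[int, int, int],
    reward_condition: str,
    forced_sequence: tuple[int, ...],
    info_condition: str,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """Assign the drawn means to physical decks.

    In Unequal-Information x Unequal-Reward games the twice-sampled deck is
    given a mean lower or higher than the remaining decks with equal
    probability (stratified assignment that balances the payoff of the
    partially-informative option across games); everywhere else the
    assignment is a uniform random permutation.
    """
    if reward_condition == "EQUAL_REWARD" or info_condition == "EQUAL_INFO":
        perm = rng.permutation(3)
        return tuple(int(means[perm[d]]) for d in range(3))
    # means = (pair, pair, odd); decide where the 2-times deck sits
    counts = [forced_sequence.count(d) for d in range(3)]
    deck2 = counts.index(2)
    others = [d for d in range(3) if d != deck2]
    rng.shuffle(others)
    pair, odd = means[0], means[2]
    want_lower = bool(rng.random() < 0.5)
    # pair is higher than odd in HIGH_REWARD, lower in LOW_REWARD
    pair_is_lower = pair < odd
    out = [0, 0, 0]
    if want_lower == pair_is_lower:
        out[deck2] = pair
        out[others[0]] = pair
        out[others[1]] = odd
    else:
        out[deck2] = odd
        out[others[0]] = pair
        out[others[1]] = pair
    return tuple(int(x) for x in out)


def build_schedule(config: TaskConfig | None = None, seed: int = 0) -> TaskSchedule:
    """Build the full randomized schedule for one subject/session.

    Condition counts follow the configured proportions exactly (largest-
    remainder rounding when ``n_games`` does not divide evenly, logged);
    condition order, mean draws, forced orders and horizons are randomized
    by ``seed``.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    n = config.n_games
    n_unequal_info, _ = largest_remainder_counts(
        n, [config.p_unequal_info, 1 - config.p_unequal_info]
    )
    p_eq = config.p_equal_reward
    p_hi = (1 - p_eq) * config.p_high_given_unequal_reward
    p_lo = (1 - p_eq) * (1 - config.p_high_given_unequal_reward)
    n_eq, n_hi, n_lo = largest_remainder_counts(n, [p_eq, p_hi, p_lo])
    if n * p_eq != n_eq or n * p_hi != n_hi:
        logger.info(
            "n_games=%d not divisible by condition proportions; "
            "largest-remainder allocation: equal=%d high=%d low=%d",
            n, n_eq, n_hi, n_lo,
        )

    reward_labels = (
        ["EQUAL_REWARD"] * n_eq + ["HIGH_REWARD"] * n_hi + ["LOW_REWARD"] * n_lo
    )
    info_labels = ["UNEQUAL_INFO"] * n_unequal_info + ["EQUAL_INFO"] * (
        n - n_unequal_info
    )
    rng.shuffle(reward_labels)
    rng.shuffle(info_labels)

    weights = config.resolved_horizon_weights()
    games = []
    for i in range(n):
        rc, ic = reward_labels[i], info_labels[i]
        means = assign_generative_means(rc, rng, config)
        forced = build_forced_sequence(ic, rng)
        deck_means = _lay_means_on_decks(means, rc, forced, ic, rng)
        horizon = draw_free_horizon(rng, weights)
        games.append(
            GameSpec(
                game_index=i,
                deck_means=deck_means,
                reward_condition=rc,
                info_condition=ic,
                forced_sequence=forced,
                free_horizon=horizon,
            )
        )
    return TaskSchedule(games=tuple(games), config=config, seed=seed)


def points_to_euros(points: int) -> float:
    """Convert accumulated points to the monetary payoff (60 pts = 0.01 EUR)."""
    return math.floor(points / 60) * 0.01
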