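"""Novelty-knowledge reinforcement-learning models of bandit choice.

The centrepiece is the nkRL value function.  Within a game, each deck ``c``
carries a reward expectation ``Q(c)`` learned by a delta rule, and its choice
value decomposes experienced reward from two information motives::

    V(c) = Q(c) + n_samples(c) * k + 1_novel(c) * nu

``n_samples(c)`` is the number of times the deck has been sampled so far in
the game, weighted by the *knowledge* parameter ``k`` (a drive to keep
accumulating evidence about already-encountered options).  ``1_novel(c)`` is
1 while the deck has never been sampled this game, so ``nu`` acts as a
one-shot novelty bonus — an optimistic boost that vanishes after the first
draw.  Choices are a softmax over the V's with inverse temperature ``beta``.

Four comparison models bracket nkRL:

* ``sRL``       — reward only (k = nu = 0), 2 free parameters;
* ``kRL``       — reward + knowledge, no novelty term, 3 parameters;
* ``leaky_nkRL``— knowledge accumulates leakily (multiplied by ``leak`` each
  trial before the chosen deck gains +1), 5 parameters;
* ``gnkRL``     — knowledge counted sub/super-linearly, ``count ** gamma``,
  5 parameters.

Beliefs reset at every game start; forced trials update beliefs but are never
themselves modelled as choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_design import TaskConfig, TaskSchedule, sample_outcomes

MODEL_IDS = ("sRL", "kRL", "nkRL", "leaky_nkRL", "gnkRL")

#: free parameters per model, in fitting order
MODEL_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "sRL": ("alpha", "beta"),
    "kRL": ("alpha", "beta", "k"),
    "nkRL": ("alpha", "beta", "k", "nu"),
    "leaky_nkRL": ("alpha", "beta", "k", "nu", "leak"),
    "gnkRL": ("alpha", "beta", "k", "nu", "gamma"),
}

#: parameter count used in the BIC penalty
MODEL_N_PARAMS = {m: len(v) for m, v in MODEL_FREE_PARAMS.items()}

TRIAL_LOG_COLUMNS = (
    "subject_id",
    "game_index",
    "trial_index",
    "phase",
    "info_condition",
    "reward_condition",
    "choice",
    "reward",
    "forced_deck",
)


@dataclass(frozen=True)
class ModelParams:
    """A parameter vector tagged with its model identifier.

    Parameters a model does not use are ignored by that model (``sRL``
    ignores ``k`` and ``nu``; ``nkRL`` ignores ``leak`` and ``gamma``).
    ``q0`` is the initial reward expectation, defaulting to the midpoint of
    the 1-100 outcome range.
    """

    model_id: str = "nkRL"
    alpha: float = 0.3
    beta: float = 0.3
    k: float = 0.0
    nu: float = 0.0
    leak: float = 1.0
    gamma: float = 1.0
    q0: float = 50.0

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not 0.0 <= self.leak <= 1.0:
            raise ValueError("leak must lie in [0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def free_values(self) -> tuple[float, ...]:
        return tuple(getattr(self, p) for p in MODEL_FREE_PARAMS[self.model_id])

    @classmethod
    def from_vector(
        cls, model_id: str, values, q0: float = 50.0
    ) -> "ModelParams":
        names = MODEL_FREE_PARAMS[model_id]
        if len(values) != len(names):
            raise ValueError(f"{model_id} expects {len(names)} values")
        return cls(model_id=model_id, q0=q0, **dict(zip(names, map(float, values))))


@dataclass
class BeliefState:
    """Within-game learner state: Q estimates, sample counts, novelty flags.

    ``info`` is the (possibly leaky) knowledge accumulator; for non-leaky
    models it coincides with ``count``.
    """

    q: np.ndarray
    count: np.ndarray
    info: np.ndarray
    novel: np.ndarray


def init_beliefs(q0: float = 50.0) -> BeliefState:
    """Fresh per-game state: Q = q0 everywhere, nothing sampled, all novel."""
    return BeliefState(
        q=np.full(3, float(q0)),
        count=np.zeros(3, dtype=int),
        info=np.zeros(3, dtype=float),
        novel=np.ones(3, dtype=bool),
    )


def update_beliefs(
    state: BeliefState, choice: int, reward: float, params: ModelParams
) -> BeliefState:
    """Delta-rule update after observing ``reward`` from deck ``choice``.

    Applies on forced and free trials alike.  Reward learning (alpha) and
    information tracking (counts, novelty) are separate: alpha = 0 freezes Q
    but counts and novelty flags still advance.
    """
    if choice not in (0, 1, 2):
        raise ValueError("choice must be a deck index 0..2")
    q = state.q.copy()
    count = state.count.copy()
    info = state.info.copy()
    novel = state.novel.copy()
    q[choice] += params.alpha * (reward - q[choice])
    if params.model_id == "leaky_nkRL":
        info *= params.leak
    info[choice] += 1.0
    count[choice] += 1
    novel[choice] = False
    return BeliefState(q=q, count=count, info=info, novel=novel)


def option_values(state: BeliefState, params: ModelParams) -> np.ndarray:
    """Combine reward, knowledge and novelty into the three choice values."""
    m = params.model_id
    if m == "sRL":
        return state.q.copy()
    if m == "kRL":
        return state.q + state.count * params.k
    if m == "nkRL":
        return state.q + state.count * params.k + state.novel * params.nu
    if m == "leaky_nkRL":
        return state.q + state.info * params.k + state.novel * params.nu
    if m == "gnkRL":
        knowledge = np.power(state.count.astype(float), params.gamma)
        return state.q + knowledge * params.k + state.novel * params.nu
    raise ValueError(f"unknown model_id {m!r}")


def choice_probabilities(values: np.ndarray, beta: float) -> np.ndarray:
    """Softmax over option values with inverse temperature ``beta``."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("option values must be finite")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    z = beta * values
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# vectorised engine: games are independent given the parameters, so belief
# propagation runs in lockstep across games (padded to the longest game)
# ---------------------------------------------------------------------------


def compile_schedule(schedule: TaskSchedule) -> dict:
    """Turn a schedule into flat arrays consumed by the simulation engine."""
    g = schedule.games
    return {
        "means": np.array([gs.deck_means for gs in g], dtype=float),
        "forced": np.array([gs.forced_sequence for gs in g], dtype=int),
        "horizon": np.array([gs.free_horizon for gs in g], dtype=int),
        "game_index": np.array([gs.game_index for gs in g], dtype=int),
        "info_condition": np.array([gs.info_condition for gs in g]),
        "reward_condition": np.array([gs.reward_condition for gs in g]),
        "config": schedule.config,
    }


def _knowledge_term(count, info, params: ModelParams):
    m = params.model_id
    if m == "sRL":
        return 0.0
    if m in ("kRL", "nkRL"):
        return count * params.k
    if m == "leaky_nkRL":
        return info * params.k
    return np.power(count, params.gamma) * params.k


def _novelty_term(novel, params: ModelParams):
    if params.model_id in ("sRL", "kRL"):
        return 0.0
    return novel * params.nu


def _play_games(
    means: np.ndarray,
    forced: np.ndarray,
    horizon: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
    config: TaskConfig,
):
    """Simulate a batch of independent games under one parameter set.

    Returns padded ``choices``, ``rewards`` (int) and ``valid`` masks of
    shape (n_games, 6 + max_horizon); free trials start at column 6.
    """
    n, _ = means.shape
    t_max = 6 + int(horizon.max())
    choices = np.zeros((n, t_max), dtype=int)
    rewards = np.zeros((n, t_max), dtype=int)
    valid = np.zeros((n, t_max), dtype=bool)

    q = np.full((n, 3), params.q0, dtype=float)
    count = np.zeros((n, 3), dtype=float)
    info = np.zeros((n, 3), dtype=float)
    novel = np.ones((n, 3), dtype=float)
    rows = np.arange(n)

    for t in range(t_max):
        if t < 6:
            act = rows
            c = forced[:, t]
        else:
            act = rows[horizon > (t - 6)]
            if act.size == 0:
                break
            v = q[act] + _knowledge_term(count[act], info[act], params)
            v = v + _novelty_term(novel[act], params)
            z = params.beta * v
            z -= z.max(axis=1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(act.size)
            c = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
            c = np.minimum(c, 2)
        r = sample_outcomes(means[act, c], config, rng)
        choices[act, t] = c
        rewards[act, t] = r
        valid[act, t] = True
        if params.model_id == "leaky_nkRL":
            info[act] *= params.leak
        info[act, c] += 1.0
        count[act, c] += 1.0
        novel[act, c] = 0.0
        q[act, c] += params.alpha * (r - q[act, c])

    return choices, rewards, valid


def simulate_agent(
    schedule: TaskSchedule,
    params: ModelParams,
    seed: int,
    subject_id: str = "sim",
) -> pd.DataFrame:
    """Play the whole schedule generatively and return a tidy trial log.

    Forced trials follow each game's forced sequence; free choices are
    sampled from the softmax policy; outcomes come from the task's truncated
    Gaussian decks.  Deterministic given ``(schedule, params, seed)``.
    """
    comp = compile_schedule(schedule)
    rng = np.random.default_rng(seed)
    choices, rewards, valid = _play_games(
        comp["means"], comp["forced"], comp["horizon"], params, rng, comp["config"]
    )
    n, t_max = choices.shape
    recs = []
    for i in range(n):
        for t in range(t_max):
            if not valid[i, t]:
                continue
            phase = "forced" if t < 6 else "free"
            recs.append(
                (
                    subject_id,
                    int(comp["game_index"][i]),
                    t,
                    phase,
                    comp["info_condition"][i],
                    comp["reward_condition"][i],
                    int(choices[i, t]),
                    int(rewards[i, t]),
                    int(comp["forced"][i, t]) if t < 6 else pd.NA,
                )
            )
    return pd.DataFrame.from_records(recs, columns=TRIAL_LOG_COLUMNS)


def free_points_by_game(
    schedules_compiled: dict,
    params: ModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Points earned on free trials, per game, over a compiled batch."""
    choices, rewards, valid = _play_games(
        schedules_compiled["means"],
        schedules_compiled["forced"],
        schedules_compiled["horizon"],
        params,
        rng,
        schedules_compiled["config"],
    )
    free = valid.copy()
    free[:, :6] = False
    return (rewards * free).sum(axis=1)


def free_points_total(
    schedules_compiled: dict,
    params: ModelParams,
    rng: np.random.Generator,
) -> int:
    """Total points earned on free trials over one compiled schedule batch."""
    return int(free_points_by_game(schedules_compiled, params, rng).sum())
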