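"""Model-free choice statistics and model-derived summaries.

Classifies first free choices into motivational categories (novelty-seeking,
general information-seeking, reward-seeking, familiar, undirected
exploration), computes the derived relative frequencies and the
novelty-familiarity shift, task performance, the nu-k parameter distance,
group-prediction regressions, and the performance landscape over the
(nu, k) parameter plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from ._seeds import derive_seed
from .rl_models import ModelParams, compile_schedule, free_points_by_game
from .task_design import TaskConfig, build_schedule

CHOICE_CLASSES = (
    "NOVELTY_SEEKING",
    "GENERAL_INFO_SEEKING",
    "REWARD_SEEKING",
    "FAMILIAR",
    "UNDIRECTED_EXPLORATION",
    "UNCLASSIFIED",
)


def _forced_history(game_rows: pd.DataFrame):
    forced = game_rows[game_rows["phase"] == "forced"].sort_values("trial_index")
    if len(forced) != 6:
        raise ValueError(
            f"game {game_rows['game_index'].iloc[0]} has {len(forced)} forced trials"
        )
    counts = np.zeros(3, dtype=int)
    sums = np.zeros(3, dtype=float)
    for c, r in zip(forced["choice"].astype(int), forced["reward"].astype(float)):
        counts[c] += 1
        sums[c] += r
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return counts, means


def classify_first_free_choice(game_rows: pd.DataFrame) -> str:
    """Motivational category of the first free choice of one game.

    Unequal-information games: the never-sampled deck is NOVELTY_SEEKING;
    among the two experienced decks, the strictly higher empirical mean is
    REWARD_SEEKING and the lower one is GENERAL_INFO_SEEKING (twice-sampled)
    or FAMILIAR (four-times-sampled).  Equal-information games: strictly
    highest empirical mean is REWARD_SEEKING, strictly lowest is
    UNDIRECTED_EXPLORATION.  Empirical-mean ties are UNCLASSIFIED and drop
    out of every denominator.
    """
    counts, means = _forced_history(game_rows)
    free = game_rows[game_rows["phase"] == "free"].sort_values("trial_index")
    if free.empty:
        raise ValueError("game has no free trials")
    chosen = int(free["choice"].iloc[0])
    info_condition = str(game_rows["info_condition"].iloc[0])

    if info_condition == "UNEQUAL_INFO":
        if counts[chosen] == 0:
            return "NOVELTY_SEEKING"
        experienced = [d for d in range(3) if counts[d] > 0]
        other = [d for d in experienced if d != chosen][0]
        if means[chosen] == means[other]:
            return "UNCLASSIFIED"
        if means[chosen] > means[other]:
            return "REWARD_SEEKING"
        return "GENERAL_INFO_SEEKING" if counts[chosen] == 2 else "FAMILIAR"

    others = [d for d in range(3) if d != chosen]
    if means[chosen] > max(means[o] for o in others):
        return "REWARD_SEEKING"
    if means[chosen] < min(means[o] for o in others):
        return "UNDIRECTED_EXPLORATION"
    return "UNCLASSIFIED"


def classify_trial_log(trial_log: pd.DataFrame) -> pd.DataFrame:
    """Per-game classification of the first free choice (games with free trials)."""
    recs = []
    for gi, rows in trial_log.groupby("game_index"):
        if not (rows["phase"] == "free").any():
            continue
        recs.append(
            {
                "game_index": gi,
                "info_condition": rows["info_condition"].iloc[0],
                "reward_condition": rows["reward_condition"].iloc[0],
                "choice_class": classify_first_free_choice(rows),
            }
        )
    return pd.DataFrame(recs)


def choice_type_frequencies(trial_log: pd.DataFrame) -> dict:
    """The three relative-frequency summaries of first free choices.

    * novelty vs reward          (unequal-info games; denominator N + R)
    * novelty vs general info    (unequal-info games; denominator N + G)
    * reward vs undirected       (equal-info games;   denominator R + U)

    Empty denominators yield ``nan`` frequencies (flagged via the reported
    denominator), never silent zeros.
    """
    cl = classify_trial_log(trial_log)
    uneq = cl[cl["info_condition"] == "UNEQUAL_INFO"]["choice_class"]
    eq = cl[cl["info_condition"] == "EQUAL_INFO"]["choice_class"]
    n_nov = int((uneq == "NOVELTY_SEEKING").sum())
    n_gen = int((uneq == "GENERAL_INFO_SEEKING").sum())
    n_rew = int((uneq == "REWARD_SEEKING").sum())
    n_rew_eq = int((eq == "REWARD_SEEKING").sum())
    n_und = int((eq == "UNDIRECTED_EXPLORATION").sum())

    def ratio(a, b):
        return a / (a + b) if (a + b) > 0 else float("nan")

    return {
        "freq_novelty_vs_reward": ratio(n_nov, n_rew),
        "freq_reward_vs_novelty": ratio(n_rew, n_nov),
        "denom_novelty_reward": n_nov + n_rew,
        "freq_novelty_vs_info": ratio(n_nov, n_gen),
        "freq_info_vs_novelty": ratio(n_gen, n_nov),
        "denom_novelty_info": n_nov + n_gen,
        "freq_reward_vs_undirected": ratio(n_rew_eq, n_und),
        "freq_undirected_vs_reward": ratio(n_und, n_rew_eq),
        "denom_equal_info": n_rew_eq + n_und,
    }


def novelty_familiarity_shift(trial_log: pd.DataFrame) -> dict:
    """First- vs last-trial preference for the least-sampled deck.

    Over unequal-information games with at least two free trials, computes
    the frequency of choosing the currently least-sampled ("informative")
    deck on the first and on the last free trial; ``shift`` = first - last.
    Positions where all decks are equally sampled are excluded.
    """
    first_hits, last_hits = [], []
    for _, rows in trial_log.groupby("game_index"):
        if str(rows["info_condition"].iloc[0]) != "UNEQUAL_INFO":
            continue
        free = rows[rows["phase"] == "free"].sort_values("trial_index")
        if len(free) < 2:
            continue
        counts, _ = _forced_history(rows)
        counts = counts.astype(int).copy()
        free_choices = free["choice"].astype(int).to_list()
        # first free trial
        if counts.min() < counts.max():
            first_hits.append(counts[free_choices[0]] == counts.min())
        for c in free_choices[:-1]:
            counts[c] += 1
        if counts.min() < counts.max():
            last_hits.append(counts[free_choices[-1]] == counts.min())
    first = float(np.mean(first_hits)) if first_hits else float("nan")
    last = float(np.mean(last_hits)) if last_hits else float("nan")
    return {
        "first_informative": first,
        "last_informative": last,
        "shift": first - last,
        "n_first": len(first_hits),
        "n_last": len(last_hits),
    }


def performance(trial_log: pd.DataFrame) -> float:
    """Task performance Pi: points earned on free trials, summed over games."""
    free = trial_log[trial_log["phase"] == "free"]
    return float(free["reward"].sum())


def parameter_distance(nu: float, k: float) -> float:
    """Distance |nu - k| between the novelty and knowledge parameters."""
    if not (np.isfinite(nu) and np.isfinite(k)):
        raise ValueError("nu and k must be finite")
    return float(abs(nu - k))


def summarize_subject(
    trial_log: pd.DataFrame, nu: float | None = None, k: float | None = None
) -> dict:
    """One subject's full metric row (frequencies, shift, Pi, d_vk)."""
    out = {"subject_id": str(trial_log["subject_id"].iloc[0])}
    out.update(choice_type_frequencies(trial_log))
    out.update(novelty_familiarity_shift(trial_log))
    out["pi"] = performance(trial_log)
    if nu is not None and k is not None:
        out["nu"], out["k"] = float(nu), float(k)
        out["d_vk"] = parameter_distance(nu, k)
    return out


# ---------------------------------------------------------------------------
# regressions and correlations
# ---------------------------------------------------------------------------


def predict_group(
    summary_table: pd.DataFrame,
    group_col: str = "group",
    positive_label: str = "PG",
    predictors: tuple[str, ...] = ("k", "nu"),
) -> dict:
    """Logistic regression of group membership on the fitted k and nu.

    Returns the coefficient table (coef, se, z, p per predictor) and flags
    degenerate designs (single group, separation).
    """
    groups = summary_table[group_col].unique()
    if len(groups) < 2:
        raise ValueError("summary table must contain two groups")
    y = (summary_table[group_col] == positive_label).astype(float)
    X = sm.add_constant(summary_table[list(predictors)].astype(float))
    flags = []
    try:
        res = sm.Logit(y, X).fit(disp=0)
        coef = pd.DataFrame(
            {"coef": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues}
        )
        converged = bool(res.mle_retvals.get("converged", True))
        if not converged:
            flags.append("optimizer did not converge")
    except Exception as err:  # perfect separation raises inside statsmodels
        flags.append(f"degenerate fit: {err}")
        coef = pd.DataFrame(
            np.nan, index=["const", *predictors], columns=["coef", "se", "z", "p"]
        )
    return {"coefficients": coef, "flags": flags}


def predict_severity(
    summary_table: pd.DataFrame,
    severity_col: str = "severity",
    predictors: tuple[str, ...] = ("k", "nu"),
) -> dict:
    """Linear regression of a severity score on fitted k and nu (off-the-shelf OLS)."""
    y = summary_table[severity_col].astype(float)
    X = sm.add_constant(summary_table[list(predictors)].astype(float))
    res = sm.OLS(y, X).fit()
    coef = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues}
    )
    return {"coefficients": coef, "flags": []}


def performance_correlations(
    summary_table: pd.DataFrame,
    param_cols: tuple[str, ...] = ("nu", "k"),
    pi_col: str = "pi",
) -> pd.DataFrame:
    """Pearson correlations of model parameters with Pi, FDR-corrected
    (Benjamini-Hochberg) across the tested pairs."""
    rows = []
    for p in param_cols:
        r, pval = stats.pearsonr(
            summary_table[p].astype(float), summary_table[pi_col].astype(float)
        )
        rows.append({"param": p, "r": float(r), "p": float(pval)})
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# (nu, k) performance landscape
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandscapeResult:
    """Mean performance surface over a (nu, k) grid."""

    nu_grid: np.ndarray
    k_grid: np.ndarray
    mean_pi: np.ndarray  # shape (len(nu_grid), len(k_grid))
    sd_pi: np.ndarray
    n_reps: int

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, nu in enumerate(self.nu_grid):
            for j, k in enumerate(self.k_grid):
                recs.append(
                    {
                        "nu": float(nu),
                        "k": float(k),
                        "mean_pi": float(self.mean_pi[i, j]),
                        "sd_pi": float(self.sd_pi[i, j]),
                        "n_reps": self.n_reps,
                    }
                )
        return pd.DataFrame(recs)

    def local_maxima(self) -> pd.DataFrame:
        return find_local_maxima(self.mean_pi, self.nu_grid, self.k_grid)


def find_local_maxima(
    surface: np.ndarray, nu_grid: np.ndarray, k_grid: np.ndarray
) -> pd.DataFrame:
    """Cells dominating their 8-neighborhood; equal-valued adjacent plateau
    cells are merged into a single mode (its highest cell is reported)."""
    filt = ndimage.maximum_filter(surface, size=3, mode="constant", cval=-np.inf)
    mask = surface >= filt
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    recs = []
    for lab in range(1, n + 1):
        cells = np.argwhere(labels == lab)
        best = cells[np.argmax([surface[i, j] for i, j in cells])]
        i, j = int(best[0]), int(best[1])
        recs.append(
            {
                "nu": float(nu_grid[i]),
                "k": float(k_grid[j]),
                "mean_pi": float(surface[i, j]),
                "n_cells": int(len(cells)),
            }
        )
    return pd.DataFrame(recs).sort_values("mean_pi", ascending=False).reset_index(
        drop=True
    )


def performance_landscape(
    nu_grid,
    k_grid,
    alpha: float = 0.3,
    beta: float = 0.3,
    n_reps: int = 50,
    task_config: TaskConfig | None = None,
    seed: int = 0,
) -> LandscapeResult:
    """Mean Pi of simulated nkRL agents at every (nu, k) grid point.

    alpha and beta are held fixed across the grid.  Every cell replays the
    same ``n_reps`` schedules with the same outcome RNG seed (common random
    numbers), so cell-to-cell differences reflect the parameters rather than
    Monte-Carlo noise; the surface is bit-reproducible for a fixed seed.
    """
    task_config = task_config or TaskConfig()
    nu_grid = np.asarray(nu_grid, dtype=float)
    k_grid = np.asarray(k_grid, dtype=float)
    if nu_grid.size == 0 or k_grid.size == 0 or n_reps < 1:
        raise ValueError("grids must be non-empty and n_reps >= 1")

    comps = [
        compile_schedule(build_schedule(task_config, derive_seed(seed, "sched", r)))
        for r in range(n_reps)
    ]
    batch = {
        "means": np.concatenate([c["means"] for c in comps]),
        "forced": np.concatenate([c["forced"] for c in comps]),
        "horizon": np.concatenate([c["horizon"] for c in comps]),
        "config": task_config,
    }
    rep_id = np.concatenate(
        [np.full(len(c["horizon"]), r) for r, c in enumerate(comps)]
    )
    play_seed = derive_seed(seed, "play")

    mean_pi = np.zeros((nu_grid.size, k_grid.size))
    sd_pi = np.zeros_like(mean_pi)
    for i, nu in enumerate(nu_grid):
        for j, k in enumerate(k_grid):
            params = ModelParams(
                model_id="nkRL", alpha=alpha, beta=beta, k=float(k), nu=float(nu)
            )
            rng = np.random.default_rng(play_seed)
            per_game = free_points_by_game(batch, params, rng)
            per_rep = np.bincount(rep_id, weights=per_game, minlength=n_reps)
            mean_pi[i, j] = per_rep.mean()
            sd_pi[i, j] = per_rep.std(ddof=1) if n_reps > 1 else 0.0
    return LandscapeResult(
        nu_grid=nu_grid, k_grid=k_grid, mean_pi=mean_pi, sd_pi=sd_pi, n_reps=n_reps
    )
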