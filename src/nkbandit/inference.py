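"""Maximum-likelihood fitting, BIC model comparison and parameter recovery.

Only *free* choices enter the likelihood: forced trials steer beliefs (Q
values, sample counts, novelty flags) but are scripted, so they carry no
information about the decision policy.  Games are independent — beliefs reset
at each game start — which lets the likelihood recursion run in lockstep
across games.

The fitting surface is :class:`ModelEstimator`, a scikit-learn style
estimator: construct with hyper-parameters, ``fit`` a trial log, read the
fitted parameters off trailing-underscore attributes.  ``fit_subject``,
``compare_models`` and ``parameter_recovery`` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from ._seeds import derive_seed
from .rl_models import (
    MODEL_FREE_PARAMS,
    MODEL_N_PARAMS,
    ModelParams,
    simulate_agent,
)
from .task_design import TaskConfig, build_schedule

_LOG_FLOOR = np.log(1e-300)

#: default box constraints for the optimizer (value scale is tens of points,
#: so beta well above ~2 already saturates the softmax)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.001, 1.0),
    "beta": (0.001, 2.0),
    "k": (-10.0, 10.0),
    "nu": (-50.0, 50.0),
    "leak": (0.0, 1.0),
    "gamma": (0.1, 3.0),
}


@dataclass(frozen=True)
class FitConfig:
    """Settings of the multi-start bounded MLE."""

    n_starts: int = 10
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    tol: float = 1e-8
    seed: int = 0
    q0: float = 50.0


@dataclass(frozen=True)
class FitResult:
    """One subject x model fit."""

    subject_id: str
    model_id: str
    params: ModelParams
    nll: float
    n_obs: int
    bic: float
    n_starts: int
    converged: bool


#: generating/fit box of the standard parameter-recovery study: the ranges
#: the recovered human estimates plausibly live in
RECOVERY_RANGES: dict[str, tuple[float, float]] = {
    "alpha": (0.05, 0.95),
    "beta": (0.05, 0.5),
    "k": (-2.0, 4.0),
    "nu": (-5.0, 30.0),
}


@dataclass(frozen=True)
class RecoveryReport:
    """Per-parameter Pearson correlations of a simulate-and-refit study."""

    correlations: dict
    n_subjects: int
    table: pd.DataFrame

    def min_r(self) -> float:
        vals = [v for v in self.correlations.values() if np.isfinite(v)]
        return float(min(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def compile_trial_log(trial_log: pd.DataFrame) -> dict:
    """Pad one subject's trial log into (game x trial) arrays for the NLL.

    Trials are ordered by ``trial_index`` within each game; the free-trial
    mask marks which cells contribute log-probability terms.
    """
    df = trial_log.sort_values(["game_index", "trial_index"])
    games = [g for _, g in df.groupby("game_index", sort=True)]
    n = len(games)
    t_max = max(len(g) for g in games)
    choices = np.zeros((n, t_max), dtype=int)
    rewards = np.zeros((n, t_max), dtype=float)
    free = np.zeros((n, t_max), dtype=bool)
    valid = np.zeros((n, t_max), dtype=bool)
    for i, g in enumerate(games):
        m = len(g)
        choices[i, :m] = g["choice"].to_numpy(dtype=int)
        rewards[i, :m] = g["reward"].to_numpy(dtype=float)
        free[i, :m] = (g["phase"] == "free").to_numpy()
        valid[i, :m] = True
    return {
        "choices": choices,
        "rewards": rewards,
        "free": free,
        "valid": valid,
        "n_free": int(free.sum()),
    }


def _nll_compiled(x: np.ndarray, model_id: str, comp: dict, q0: float) -> float:
    params = ModelParams.from_vector(model_id, x, q0=q0)
    choices, rewards = comp["choices"], comp["rewards"]
    free, valid = comp["free"], comp["valid"]
    n, t_max = choices.shape

    q = np.full((n, 3), params.q0, dtype=float)
    count = np.zeros((n, 3), dtype=float)
    info = np.zeros((n, 3), dtype=float)
    novel = np.ones((n, 3), dtype=float)
    rows = np.arange(n)
    nll = 0.0

    for t in range(t_max):
        act = rows[valid[:, t]]
        if act.size == 0:
            break
        fr = rows[free[:, t]]
        if fr.size:
            v = q[fr].copy()
            if params.model_id != "sRL":
                if params.model_id == "leaky_nkRL":
                    v += info[fr] * params.k
                elif params.model_id == "gnkRL":
                    v += np.power(count[fr], params.gamma) * params.k
                else:
                    v += count[fr] * params.k
                if params.model_id != "kRL":
                    v += novel[fr] * params.nu
            z = params.beta * v
            zmax = z.max(axis=1, keepdims=True)
            lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
            lp = z[np.arange(fr.size), choices[fr, t]] - lse
            nll -= float(np.maximum(lp, _LOG_FLOOR).sum())
        c = choices[act, t]
        r = rewards[act, t]
        if params.model_id == "leaky_nkRL":
            info[act] *= params.leak
        info[act, c] += 1.0
        count[act, c] += 1.0
        novel[act, c] = 0.0
        q[act, c] += params.alpha * (r - q[act, c])
    return nll


def negative_log_likelihood(trial_log: pd.DataFrame, params: ModelParams) -> float:
    """Negative log-likelihood (nats) of the free choices in ``trial_log``."""
    comp = compile_trial_log(trial_log)
    return _nll_compiled(np.asarray(params.free_values()), params.model_id, comp, params.q0)


def bic(nll: float, n_params: int, n_obs: int) -> float:
    """Bayesian Information Criterion, ``2*nll + p*ln(n)``; lower is better."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return 2.0 * nll + n_params * np.log(n_obs)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class ModelEstimator(BaseEstimator):
    """Multi-start bounded MLE for one choice model, sklearn-style.

    Parameters
    ----------
    model_id : str
        One of ``sRL``, ``kRL``, ``nkRL``, ``leaky_nkRL``, ``gnkRL``.
    n_starts : int
        Number of random initial points (drawn uniformly within the bounds).
    bounds : dict or None
        Per-parameter ``(low, high)`` boxes; ``None`` uses
        :data:`DEFAULT_BOUNDS`.
    tol : float
        Function tolerance passed to the optimizer.
    seed : int
        Seeds the start-point sampler (independent of any simulation RNG).
    q0 : float
        Initial reward expectation of the learner.

    Attributes (after ``fit``)
    --------------------------
    params_ : ModelParams         fitted parameter vector
    nll_ : float                  negative log-likelihood at the optimum
    n_obs_ : int                  number of free-choice trials
    bic_ : float                  ``2*nll_ + p*ln(n_obs_)``
    converged_ : bool             whether any start converged
    start_nlls_ : ndarray         NLL at each start's initial point
    """

    def __init__(
        self,
        model_id: str = "nkRL",
        n_starts: int = 10,
        bounds: dict | None = None,
        tol: float = 1e-8,
        seed: int = 0,
        q0: float = 50.0,
    ):
        self.model_id = model_id
        self.n_starts = n_starts
        self.bounds = bounds
        self.tol = tol
        self.seed = seed
        self.q0 = q0

    def _resolved_bounds(self) -> list[tuple[float, float]]:
        table = dict(DEFAULT_BOUNDS)
        if self.bounds:
            table.update(self.bounds)
        return [table[p] for p in MODEL_FREE_PARAMS[self.model_id]]

    def fit(self, X: pd.DataFrame, y=None, extra_starts=None):
        """Fit the model to one subject's trial log ``X``."""
        if self.model_id not in MODEL_FREE_PARAMS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        comp = compile_trial_log(X)
        if comp["n_free"] < 1:
            raise ValueError("trial log contains no free-choice trials")
        bounds = self._resolved_bounds()
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        d = len(bounds)
        # uniform starts drawn sequentially from one stream: the start set for
        # n_starts = m is a prefix of the set for any n > m, so the returned
        # best-of-starts NLL is monotone non-increasing in n_starts
        rng = np.random.default_rng(self.seed)
        starts = [lo + (hi - lo) * u for u in rng.random((self.n_starts, d))]
        if extra_starts is not None:
            starts += [np.clip(np.asarray(s, dtype=float), lo, hi) for s in extra_starts]

        fun = lambda x: _nll_compiled(x, self.model_id, comp, self.q0)
        self.start_nlls_ = np.array([fun(s) for s in starts])
        best = None
        converged = False
        for s in starts:
            res = optimize.minimize(
                fun,
                s,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": self.tol, "maxiter": 500},
            )
            converged = converged or bool(res.success)
            if best is None or res.fun < best.fun - 0.0:
                best = res
        # best-of-starts can never be worse than the best initial point
        if best.fun > self.start_nlls_.min():
            i = int(np.argmin(self.start_nlls_))
            best_x, best_f = starts[i], float(self.start_nlls_[i])
        else:
            best_x, best_f = best.x, float(best.fun)
        self.params_ = ModelParams.from_vector(self.model_id, best_x, q0=self.q0)
        self.nll_ = best_f
        self.n_obs_ = comp["n_free"]
        self.bic_ = bic(self.nll_, MODEL_N_PARAMS[self.model_id], self.n_obs_)
        self.converged_ = converged
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Per-free-trial choice probabilities under the fitted parameters."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        return predict_choice_probabilities(X, self.params_)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean log-likelihood per free choice (higher is better)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        comp = compile_trial_log(X)
        nll = _nll_compiled(
            np.asarray(self.params_.free_values()), self.model_id, comp, self.q0
        )
        return -nll / comp["n_free"]


def predict_choice_probabilities(
    trial_log: pd.DataFrame, params: ModelParams
) -> np.ndarray:
    """(n_free, 3) softmax probabilities at each free trial of the log."""
    comp = compile_trial_log(trial_log)
    choices, rewards = comp["choices"], comp["rewards"]
    free, valid = comp["free"], comp["valid"]
    n, t_max = choices.shape
    q = np.full((n, 3), params.q0, dtype=float)
    count = np.zeros((n, 3), dtype=float)
    info = np.zeros((n, 3), dtype=float)
    novel = np.ones((n, 3), dtype=float)
    rows = np.arange(n)
    out = np.full((n, t_max, 3), np.nan)
    for t in range(t_max):
        act = rows[valid[:, t]]
        if act.size == 0:
            break
        fr = rows[free[:, t]]
        if fr.size:
            v = q[fr].copy()
            if params.model_id != "sRL":
                if params.model_id == "leaky_nkRL":
                    v += info[fr] * params.k
                elif params.model_id == "gnkRL":
                    v += np.power(count[fr], params.gamma) * params.k
                else:
                    v += count[fr] * params.k
                if params.model_id != "kRL":
                    v += novel[fr] * params.nu
            z = params.beta * v
            z -= z.max(axis=1, keepdims=True)
            p = np.exp(z)
            out[fr, t] = p / p.sum(axis=1, keepdims=True)
        c = choices[act, t]
        if params.model_id == "leaky_nkRL":
            info[act] *= params.leak
        info[act, c] += 1.0
        count[act, c] += 1.0
        novel[act, c] = 0.0
        q[act, c] += params.alpha * (rewards[act, t] - q[act, c])
    mask = free & valid
    return out[mask]


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_subject(
    trial_log: pd.DataFrame,
    model_id: str,
    fit_config: FitConfig | None = None,
    subject_id: str | None = None,
    extra_starts=None,
) -> FitResult:
    """Fit one model to one subject's log and package the result."""
    cfg = fit_config or FitConfig()
    if subject_id is None:
        subject_id = str(trial_log["subject_id"].iloc[0])
    est = ModelEstimator(
        model_id=model_id,
        n_starts=cfg.n_starts,
        bounds=cfg.bounds,
        tol=cfg.tol,
        seed=derive_seed(cfg.seed, subject_id, model_id),
        q0=cfg.q0,
    ).fit(trial_log, extra_starts=extra_starts)
    return FitResult(
        subject_id=subject_id,
        model_id=model_id,
        params=est.params_,
        nll=est.nll_,
        n_obs=est.n_obs_,
        bic=est.bic_,
        n_starts=cfg.n_starts,
        converged=est.converged_,
    )


#: warm-start embeddings along the nesting chain; each entry maps a fitted
#: donor model's vector into the recipient's parameter space
_NESTED_DONORS = {
    "kRL": [("sRL", lambda v: [v[0], v[1], 0.0])],
    "nkRL": [
        ("kRL", lambda v: [v[0], v[1], v[2], 0.0]),
        ("sRL", lambda v: [v[0], v[1], 0.0, 0.0]),
    ],
    "leaky_nkRL": [("nkRL", lambda v: [v[0], v[1], v[2], v[3], 1.0])],
    "gnkRL": [("nkRL", lambda v: [v[0], v[1], v[2], v[3], 1.0])],
}


def compare_models(
    trial_logs,
    model_ids=("sRL", "kRL", "nkRL", "leaky_nkRL", "gnkRL"),
    fit_config: FitConfig | None = None,
):
    """Fit several models per subject and tabulate summed BIC and winners.

    Models are fitted in nesting order and each richer model receives the
    embedded optimum of its fitted nested relatives as extra warm starts, so
    the fitted NLLs respect the analytic nesting inequalities up to optimizer
    tolerance.

    ``trial_logs`` is an iterable of per-subject trial-log frames (or a dict
    subject_id -> frame).  Returns a dict with keys ``fits`` (DataFrame),
    ``summed_bic`` (Series) and ``winner_counts`` (Series).
    """
    cfg = fit_config or FitConfig()
    if isinstance(trial_logs, dict):
        items = list(trial_logs.items())
    else:
        items = [(str(df["subject_id"].iloc[0]), df) for df in trial_logs]

    order = [m for m in ("sRL", "kRL", "nkRL", "leaky_nkRL", "gnkRL") if m in model_ids]
    rows = []
    for sid, df in items:
        fitted: dict[str, FitResult] = {}
        for m in order:
            extra = [
                emb(fitted[donor].params.free_values())
                for donor, emb in _NESTED_DONORS.get(m, [])
                if donor in fitted
            ]
            fr = fit_subject(df, m, cfg, subject_id=sid, extra_starts=extra or None)
            fitted[m] = fr
            row = {
                "subject_id": sid,
                "model_id": m,
                "nll": fr.nll,
                "n_obs": fr.n_obs,
                "bic": fr.bic,
                "converged": fr.converged,
            }
            for p in MODEL_FREE_PARAMS[m]:
                row[p] = getattr(fr.params, p)
            rows.append(row)
    fits = pd.DataFrame(rows)
    summed = fits.groupby("model_id")["bic"].sum().reindex(order)
    winners = (
        fits.loc[fits.groupby("subject_id")["bic"].idxmin(), "model_id"]
        .value_counts()
        .reindex(order, fill_value=0)
    )
    return {"fits": fits, "summed_bic": summed, "winner_counts": winners}


def parameter_recovery(
    generating_params: pd.DataFrame,
    task_config: TaskConfig | None = None,
    fit_config: FitConfig | None = None,
    seed: int = 0,
    model_id: str = "nkRL",
) -> RecoveryReport:
    """Simulate-and-refit study: can the pipeline recover known parameters?

    Each row of ``generating_params`` (columns = the model's free parameters)
    is played on an independently seeded fresh schedule, the log is refitted,
    and the per-parameter Pearson r between generating and recovered values
    is reported.  Zero-variance generating parameters yield ``nan`` r.
    """
    task_config = task_config or TaskConfig()
    cfg = fit_config or FitConfig()
    names = MODEL_FREE_PARAMS[model_id]
    recs = []
    for i, row in enumerate(generating_params.itertuples(index=False)):
        true = ModelParams.from_vector(
            model_id, [getattr(row, p) for p in names], q0=cfg.q0
        )
        sched = build_schedule(task_config, seed=derive_seed(seed, "schedule", i))
        log = simulate_agent(
            sched, true, seed=derive_seed(seed, "sim", i), subject_id=f"rec{i:03d}"
        )
        fr = fit_subject(log, model_id, cfg, subject_id=f"rec{i:03d}")
        rec = {"subject": i}
        for p in names:
            rec[f"true_{p}"] = getattr(true, p)
            rec[f"est_{p}"] = getattr(fr.params, p)
        recs.append(rec)
    table = pd.DataFrame(recs)
    corr = {}
    for p in names:
        t, e = table[f"true_{p}"], table[f"est_{p}"]
        if t.std() == 0 or e.std() == 0:
            corr[p] = float("nan")
        else:
            corr[p] = float(stats.pearsonr(t, e).statistic)
    return RecoveryReport(correlations=corr, n_subjects=len(table), table=table)


def recovery_study(
    n_subjects: int = 62,
    n_games: int = 162,
    n_starts: int = 10,
    seed: int = 0,
    ranges: dict | None = None,
) -> RecoveryReport:
    """The standard simulate-and-refit recovery study at task scale.

    Draws ``n_subjects`` nkRL parameter sets uniformly within ``ranges``
    (default :data:`RECOVERY_RANGES`), plays each on a fresh ``n_games``
    schedule, and refits by multi-start MLE *within the same box* — the
    conventional design in which generating and fitting supports coincide.
    """
    ranges = dict(ranges or RECOVERY_RANGES)
    rng = np.random.default_rng(derive_seed(seed, "gen"))
    gen = pd.DataFrame(
        {p: rng.uniform(lo, hi, n_subjects) for p, (lo, hi) in ranges.items()}
    )
    cfg = FitConfig(n_starts=n_starts, bounds=ranges, seed=derive_seed(seed, "fit"))
    return parameter_recovery(
        gen,
        TaskConfig(n_games=n_games),
        cfg,
        seed=derive_seed(seed, "recovery"),
        model_id="nkRL",
    )
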