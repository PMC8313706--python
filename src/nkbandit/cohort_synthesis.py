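"""Synthetic cohorts: sample per-subject nkRL parameters from group-level
distributions and play the task, replacing the (unavailable) human sample.

Defaults emulate a 62-subject study — 40 problem-gambler-like (PG) and 22
healthy-control-like (HC) subjects — with group means/SDs of the novelty
bonus nu and knowledge weight k taken from the fitted group statistics
(nu: HC 12.43 +/- 12.91 vs PG 5.58 +/- 12.11; k: HC 0.43 +/- 1.04 vs
PG 1.38 +/- 2.01).  Learning rate and inverse temperature share one
distribution across groups (the groups did not differ on either), and PG
subjects carry a gambling-severity score emulating the CPGI distribution
(PG 8.8 +/- 6.1, HC fixed at 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .rl_models import ModelParams, simulate_agent
from .task_design import TaskConfig, build_schedule

#: (mean, sd, low, high) truncation boxes, consistent with the fit bounds
_SHARED_DISTS = {
    "alpha": (0.3, 0.15, 0.01, 1.0),
    "beta": (0.3, 0.15, 0.01, 2.0),
}


@dataclass(frozen=True)
class GroupSpec:
    """One group's size and parameter distributions.

    ``param_dists`` maps parameter name -> (mean, sd, low, high); draws are
    truncated normal (by rejection — exact at this scale).  ``severity_dist``
    is the same 4-tuple for the gambling-severity score, or ``None`` for a
    group pinned at zero severity.
    """

    label: str
    n_subjects: int
    param_dists: dict = field(default_factory=dict)
    severity_dist: tuple | None = None


def default_group_specs() -> list[GroupSpec]:
    """The default 40 PG-like / 22 HC-like study conditions."""
    return [
        GroupSpec(
            label="PG",
            n_subjects=40,
            param_dists={
                **_SHARED_DISTS,
                "nu": (5.58, 12.11, -50.0, 50.0),
                "k": (1.38, 2.01, -10.0, 10.0),
            },
            severity_dist=(8.8, 6.1, 1.0, 27.0),
        ),
        GroupSpec(
            label="HC",
            n_subjects=22,
            param_dists={
                **_SHARED_DISTS,
                "nu": (12.43, 12.91, -50.0, 50.0),
                "k": (0.43, 1.04, -10.0, 10.0),
            },
            severity_dist=None,
        ),
    ]


def _trunc_normal(mean, sd, lo, hi, size, rng: np.random.Generator) -> np.ndarray:
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError("point-mass mean outside truncation bounds")
        return np.full(size, float(mean))
    if mean < lo - 5 * sd or mean > hi + 5 * sd:
        raise ValueError("truncation bounds exclude the mean by more than 5 SD")
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def sample_cohort(
    group_specs: list[GroupSpec] | None = None, seed: int = 0
) -> pd.DataFrame:
    """One parameter row per synthetic subject, with group label and severity."""
    specs = group_specs if group_specs is not None else default_group_specs()
    rng = np.random.default_rng(seed)
    frames = []
    for spec in specs:
        n = spec.n_subjects
        cols = {"subject_id": [f"{spec.label}_{i:03d}" for i in range(n)],
                "group": [spec.label] * n}
        for p, (m, s, lo, hi) in spec.param_dists.items():
            cols[p] = _trunc_normal(m, s, lo, hi, n, rng)
        if spec.severity_dist is None:
            cols["severity"] = np.zeros(n)
        else:
            m, s, lo, hi = spec.severity_dist
            cols["severity"] = _trunc_normal(m, s, lo, hi, n, rng)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def generate_dataset(
    parameter_table: pd.DataFrame,
    task_config: TaskConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Play the task once per subject and return trial logs plus a manifest.

    Every subject gets an independently seeded schedule and simulation
    stream, derived deterministically from ``seed``; the manifest records
    each derived seed and the generating parameters, so the whole dataset —
    and a closed-loop parameter recovery — is reproducible from the manifest
    alone.
    """
    task_config = task_config or TaskConfig()
    logs: dict[str, pd.DataFrame] = {}
    manifest: dict = {
        "master_seed": int(seed),
        "seed_scheme": "derive_seed(master, stage, subject_index)",
        "task_config": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(task_config).items()},
        "subjects": [],
    }
    for i, row in enumerate(parameter_table.to_dict("records")):
        sid = str(row.get("subject_id", f"S{i:03d}"))
        sched_seed = derive_seed(seed, "schedule", i)
        sim_seed = derive_seed(seed, "sim", i)
        params = ModelParams(
            model_id="nkRL",
            alpha=float(row["alpha"]),
            beta=float(row["beta"]),
            k=float(row["k"]),
            nu=float(row["nu"]),
        )
        schedule = build_schedule(task_config, seed=sched_seed)
        logs[sid] = simulate_agent(schedule, params, seed=sim_seed, subject_id=sid)
        manifest["subjects"].append(
            {
                "subject_id": sid,
                "schedule_seed": sched_seed,
                "simulation_seed": sim_seed,
                "group": row.get("group"),
                "severity": float(row.get("severity", float("nan"))),
                "params": {p: getattr(params, p) for p in ("alpha", "beta", "k", "nu")},
            }
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, df in logs.items():
            df.to_csv(out / f"{sid}.csv", index=False)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return logs, manifest
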