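"""Delimited-text serialization and validation of the pipeline's tables.

A trial log — one row per trial with subject, game, phase, condition labels,
choice and reward — is the single contract between simulation, fitting and
metrics.  Everything is plain CSV with a header row and 0-based deck indices.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .rl_models import TRIAL_LOG_COLUMNS
from .task_design import TaskConfig, TaskSchedule, schedule_from_frame


def write_task_config(config: TaskConfig, path) -> None:
    """Write a task configuration as a flat key/value (YAML) file."""
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_task_config(path) -> TaskConfig:
    """Read a flat key/value task-configuration file; keys mirror TaskConfig
    fields and any subset may be given (the rest keep their defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    fields = set(TaskConfig.__dataclass_fields__)
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown task-config keys: {sorted(unknown)}")
    data = {k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()}
    return TaskConfig(**data)


def write_trial_log(trial_log: pd.DataFrame, path) -> None:
    trial_log.to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"forced_deck": "Int64"})
    missing = set(TRIAL_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    return df


def write_schedule(schedule: TaskSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_schedule(path, config: TaskConfig | None = None) -> TaskSchedule:
    return schedule_from_frame(pd.read_csv(path), config=config)


def validate_trial_log(source) -> list[str]:
    """Check a trial log (path or frame) against the task's structural rules.

    Returns a list of human-readable violations (empty when valid): schema,
    per-game phase ordering (6 forced rows then 1-6 free rows), forced rows
    matching their scripted deck, deck indices in 0..2, rewards in 1..100.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source)
    else:
        df = source
    problems: list[str] = []
    missing = set(TRIAL_LOG_COLUMNS) - set(df.columns)
    if missing:
        return [f"missing columns: {sorted(missing)}"]

    bad_phase = ~df["phase"].isin(["forced", "free"])
    for idx in df.index[bad_phase]:
        problems.append(f"row {idx}: invalid phase {df.loc[idx, 'phase']!r}")
    bad_choice = ~df["choice"].isin([0, 1, 2])
    for idx in df.index[bad_choice]:
        problems.append(f"row {idx}: choice {df.loc[idx, 'choice']} not a deck index")
    bad_reward = (df["reward"] < 1) | (df["reward"] > 100)
    for idx in df.index[bad_reward]:
        problems.append(f"row {idx}: reward {df.loc[idx, 'reward']} outside 1..100")

    for (sid, gi), rows in df.groupby(["subject_id", "game_index"]):
        rows = rows.sort_values("trial_index")
        phases = rows["phase"].to_list()
        n_forced = sum(p == "forced" for p in phases)
        n_free = sum(p == "free" for p in phases)
        where = f"subject {sid} game {gi}"
        if n_forced != 6:
            problems.append(f"{where}: {n_forced} forced trials (expected 6)")
        if not 1 <= n_free <= 6:
            problems.append(f"{where}: {n_free} free trials (expected 1-6)")
        if phases != ["forced"] * n_forced + ["free"] * n_free:
            problems.append(f"{where}: free trial precedes a forced trial")
        forced = rows[rows["phase"] == "forced"]
        mismatch = forced["choice"].astype("Int64") != forced["forced_deck"].astype("Int64")
        if mismatch.any():
            problems.append(f"{where}: forced choice differs from forced_deck")
    return problems
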