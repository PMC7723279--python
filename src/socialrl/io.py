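"""Trial-log CSV and task-config YAML round-tripping, plus run manifests.

Trial logs are plain CSVs with the column order of
:data:`socialrl.task.TRIAL_COLUMNS`; missing demonstration/choice/outcome
values are written as empty fields, never sentinel numbers.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import TRIAL_COLUMNS, TaskConfig

__all__ = [
    "write_trials",
    "read_trials",
    "split_subjects",
    "write_task_config",
    "read_task_config",
    "RunManifest",
]

_REQUIRED = set(TRIAL_COLUMNS)


def write_trials(trials: pd.DataFrame, path) -> None:
    df = trials.copy()
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"trial log missing column {col!r}")
    df[TRIAL_COLUMNS].to_csv(path, index=False, na_rep="")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV, chronologically sorted per subject.

    Schema violations raise with the offending row and column named.
    """
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "condition": str, "trial_type": str,
               "option_a": str, "option_b": str, "demonstration": "object",
               "choice": "object"},
    )
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    df = df.sort_values(
        ["subject_id", "session", "block", "trial_index"], kind="stable"
    ).reset_index(drop=True)
    for i, row in enumerate(df.itertuples(index=False)):
        if row.trial_type not in ("private", "observational"):
            raise ValueError(f"row {i}: invalid trial_type {row.trial_type!r}")
        if row.trial_type == "observational":
            if pd.isna(row.demonstration):
                raise ValueError(f"row {i}: observational trial missing 'demonstration'")
            if row.demonstration not in (row.option_a, row.option_b):
                raise ValueError(f"row {i}: 'demonstration' is not one of the options")
        if pd.notna(row.choice) and row.choice not in (row.option_a, row.option_b):
            raise ValueError(f"row {i}: 'choice' is not one of the options")
        if pd.notna(row.outcome) and float(row.outcome) not in (1.0, -1.0):
            raise ValueError(f"row {i}: 'outcome' must be +1 or -1")
    return df


def split_subjects(trials: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-subject datasets, order preserved."""
    return {
        str(subj): g.reset_index(drop=True)
        for subj, g in trials.groupby("subject_id", sort=False)
    }


def write_task_config(config: TaskConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_task_config(path) -> TaskConfig:
    with open(path) as fh:
        return TaskConfig.from_dict(yaml.safe_load(fh))


class RunManifest:
    """Traceability record for one pipeline stage: seeds, config, outputs."""

    def __init__(self, command: str, seed, config: dict | None = None):
        self.payload = {
            "command": command,
            "package": "socialrl",
            "version": _package_version(),
            "master_seed": seed,
            "stage_seeds": {},
            "config": config or {},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {},
        }

    def child_seed(self, stage: str) -> int:
        seed = int(
            np.random.SeedSequence(
                entropy=self.payload["master_seed"],
                spawn_key=(len(self.payload["stage_seeds"]),),
            ).generate_state(1)[0]
            % 2**31
        )
        self.payload["stage_seeds"][stage] = seed
        return seed

    def register_output(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.payload["outputs"][path.name] = {"sha256": digest, "bytes": path.stat().st_size}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.payload, fh, indent=2, default=str)


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("socialrl")
    except Exception:  # pragma: no cover
        return "unknown"
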