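"""File formats: the trial CSV schema, YAML configs and checkpoints.

The trial table is the exchange format for reference datasets: one row per
delivered stimulus with the subject covariates, the (PA, PW) pair and the
reported sensation.  Header order and enum spellings are fixed so files
round-trip bit-exactly:

``subject_id,gender,weight_kg,nerve,neuropathic,pa_mA,pw_us,intensity,stype,location,se``

with ``gender`` in {M, F}, ``nerve`` in {peroneal, tibial, sural},
``intensity`` in {NP, LOW, HIGH, TOOHIGH}, ``stype`` in {UNC, COM},
``location`` in {NSOM, SOM} and ``se`` an integer 0-10.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import pandas as pd
import yaml

from .subjects import TRIAL_COLUMNS, NERVES

__all__ = [
    "TRIAL_COLUMNS",
    "validate_trials",
    "read_trials",
    "write_trials",
    "load_config",
    "save_checkpoint",
    "load_checkpoint",
]

_ENUMS = {
    "gender": {"M", "F"},
    "nerve": set(NERVES),
    "intensity": {"NP", "LOW", "HIGH", "TOOHIGH"},
    "stype": {"UNC", "COM"},
    "location": {"NSOM", "SOM"},
}


def validate_trials(df: pd.DataFrame) -> list[str]:
    """Schema check; returns human-readable problems ('' header line is 1,
    first data row is line 2, matching the CSV layout)."""
    problems: list[str] = []
    if list(df.columns) != TRIAL_COLUMNS:
        problems.append(
            f"header mismatch: expected {TRIAL_COLUMNS}, got {list(df.columns)}"
        )
        return problems
    for col, allowed in _ENUMS.items():
        bad = ~df[col].isin(allowed)
        for idx in df.index[bad]:
            problems.append(
                f"line {idx + 2}: column {col!r} has invalid value {df.at[idx, col]!r}"
            )
    se = pd.to_numeric(df["se"], errors="coerce")
    bad_se = se.isna() | (se < 0) | (se > 10) | (se != se.round())
    for idx in df.index[bad_se]:
        problems.append(f"line {idx + 2}: column 'se' must be an integer in 0..10")
    for col in ("pa_mA", "pw_us", "weight_kg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[vals.isna() | (vals <= 0)]:
            problems.append(f"line {idx + 2}: column {col!r} must be a positive number")
    bad_np = ~df["neuropathic"].isin([0, 1])
    for idx in df.index[bad_np]:
        problems.append(f"line {idx + 2}: column 'neuropathic' must be 0 or 1")
    return problems


def write_trials(df: pd.DataFrame, path) -> None:
    problems = validate_trials(df)
    if problems:
        raise ValueError("refusing to write invalid trial table:\n" + "\n".join(problems))
    df.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems = validate_trials(df)
    if problems:
        raise ValueError(f"invalid trial table {path}:\n" + "\n".join(problems))
    return df


_CONFIG_KEYS = {
    "grid", "hyperparams", "cohort", "environment", "limits",
    "reward_tables", "seed", "outputs", "episodes",
}


def load_config(path) -> dict:
    """Load a YAML run config, rejecting unknown top-level keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def save_checkpoint(obj, path, kind: str) -> None:
    """Versioned container for fitted models / trained agents."""
    payload = {"format": f"tenscalib-{kind}-1", "payload": obj}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path, kind: str):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    expected = f"tenscalib-{kind}-1"
    if payload.get("format") != expected:
        raise ValueError(
            f"{path}: expected checkpoint format {expected}, got {payload.get('format')!r}"
        )
    return payload["payload"]
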