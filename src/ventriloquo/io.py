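"""Tidy-table and config input/output.

Trial tables are tab-separated text, one row per trial, with the columns
``participant, group, block, trial_index, modality, s_A, s_V, resp_A,
resp_V, response_order``; fields that do not apply to a trial's modality
are left empty.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

__all__ = ["TRIAL_COLUMNS", "read_trial_table", "write_trial_table", "load_config"]

TRIAL_COLUMNS = [
    "participant",
    "group",
    "block",
    "trial_index",
    "modality",
    "s_A",
    "s_V",
    "resp_A",
    "resp_V",
    "response_order",
]


def write_trial_table(frame: pd.DataFrame, path) -> None:
    frame = frame[TRIAL_COLUMNS]
    frame.to_csv(path, sep="\t", index=False, na_rep="")


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a tidy trial table; malformed rows raise with diagnostics."""
    frame = pd.read_csv(path, sep="\t", dtype={"participant": str, "group": str})
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial table {path}: missing columns {missing}")
    problems = []
    for i, row in frame.iterrows():
        mod = row["modality"]
        if mod not in ("A", "V", "AV"):
            problems.append(f"row {i}: bad modality {mod!r}")
            continue
        if mod in ("A", "AV") and pd.isna(row["s_A"]):
            problems.append(f"row {i}: {mod} trial missing s_A")
        if mod in ("V", "AV") and pd.isna(row["s_V"]):
            problems.append(f"row {i}: {mod} trial missing s_V")
        if int(row["block"]) not in (1, 2):
            problems.append(f"row {i}: bad block {row['block']!r}")
    if problems:
        head = "; ".join(problems[:10])
        raise ValueError(f"trial table {path}: {len(problems)} malformed rows ({head} ...)")
    for col in ("resp_A", "resp_V"):
        frame[col] = frame[col].astype("Float64")
    return frame


def load_config(path) -> dict:
    """Load a YAML (or JSON; YAML is a superset) config file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
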