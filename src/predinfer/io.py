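"""Reading and writing the canonical trial-log and metadata CSVs."""

from __future__ import annotations

import pandas as pd

from .cohort import TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "read_metadata", "write_metadata"]

REQUIRED_TRIAL_COLUMNS = [
    "subject_id", "block", "trial", "outcome", "bucket", "confidence", "hit",
]


def _validate_trials(df: pd.DataFrame, path="<table>") -> pd.DataFrame:
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("outcome", "bucket"):
        bad = df.index[(df[col] < 0) | (df[col] >= 360)]
        if len(bad):
            raise ValueError(f"{path}: {col} out of [0, 360) at row {bad[0]}")
    bad = df.index[(df["confidence"] < 1) | (df["confidence"] > 100)]
    if len(bad):
        raise ValueError(f"{path}: confidence out of [1, 100] at row {bad[0]}")
    return df


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV."""
    return _validate_trials(pd.read_csv(path), path)


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial-log CSV (validates first; lossless round trip)."""
    _validate_trials(df, path)
    cols = [c for c in TRIAL_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False, float_format="%.12g")


def read_metadata(path) -> pd.DataFrame:
    """Read a subject-metadata CSV (subject_id, group, medication, covariates)."""
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")
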