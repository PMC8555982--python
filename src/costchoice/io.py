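"""CSV readers and writers for the pipeline's tabular interfaces.

All interchange formats are plain CSV: trial tables (one row per completed
trial), long rate tables (one row per neuron x trial x window), behavior
fit tables (one row per session), and ground-truth tables from the
simulator.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .task import TRIAL_COLUMNS, validate_trials

RATE_COLUMNS = ["neuron_id", "trial_index", "window_id", "rate"]


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_trials(df)
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    trials[cols].to_csv(path, index=False)


def read_rates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rate table missing columns: {missing}")
    if (df["rate"] < 0).any():
        raise ValueError("rates must be non-negative")
    return df


def write_rates(rates: pd.DataFrame, path: str | Path) -> None:
    rates.to_csv(path, index=False)


def read_behavior_fits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_behavior_fits(fits: pd.DataFrame, path: str | Path) -> None:
    fits.to_csv(path, index=False)
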