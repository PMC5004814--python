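"""Session I/O: canonical on-disk formats and schema validation.

A session directory holds ``trials.csv``, ``units.csv`` and
``spikes.parquet`` (columns unit_id, trial_id, time_ms; times in ms relative
to stimulus onset).  Spike times round-trip losslessly at 0.1-ms precision.
The same reader serves synthetic sessions and any real recordings exported
to this schema.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SessionData, TRIAL_EPOCH_MS

__all__ = ["write_session", "read_session"]

TRIAL_COLUMNS = ["trial_id", "stimulus", "choice", "correct", "withdrawal_ms"]
SPIKE_COLUMNS = ["unit_id", "trial_id", "time_ms"]


def write_session(session: SessionData, out_dir: str | Path) -> dict[str, Path]:
    """Write a session to a directory; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out / "trials.csv",
        "units": out / "units.csv",
        "spikes": out / "spikes.parquet",
    }
    session.trials.to_csv(paths["trials"], index=False)
    session.units.to_csv(paths["units"], index=False)
    spikes = session.spikes.copy()
    spikes["time_ms"] = np.round(spikes["time_ms"].astype(float), 1)
    spikes.to_parquet(paths["spikes"], index=False)
    return paths


def _require_columns(df: pd.DataFrame, needed: list[str], name: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing required column(s): {missing}")


def read_session(session_dir: str | Path) -> SessionData:
    """Read a session directory written by :func:`write_session`.

    Unsorted spike times are sorted with a warning; missing required columns
    raise a hard error naming the column.
    """
    d = Path(session_dir)
    trials = pd.read_csv(d / "trials.csv")
    units = pd.read_csv(d / "units.csv")
    spikes = pd.read_parquet(d / "spikes.parquet")
    _require_columns(trials, TRIAL_COLUMNS, "trials.csv")
    _require_columns(units, ["unit_id"], "units.csv")
    _require_columns(spikes, SPIKE_COLUMNS, "spikes.parquet")

    sorted_spikes = spikes.sort_values(
        ["unit_id", "trial_id", "time_ms"], kind="mergesort"
    ).reset_index(drop=True)
    if not spikes["time_ms"].equals(sorted_spikes["time_ms"]):
        warnings.warn("spike times were not sorted; sorting on read")
    session = SessionData(
        trials=trials, spikes=sorted_spikes, units=units, epoch_ms=TRIAL_EPOCH_MS
    )
    session.validate()
    return session
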