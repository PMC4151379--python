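"""Delimited-text input/output and run manifests shared by the CLI."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .surv_core import SurvivalSample

__all__ = ["read_sample", "write_manifest"]


def read_sample(
    path,
    id_col: str = "id",
    time_col: str = "time",
    event_col: str = "event",
    covariate_cols: list[str] | None = None,
    sep: str = ",",
) -> SurvivalSample:
    """Read subject-level survival data from a delimited text file.

    Requires a header with id/time/event columns plus numeric covariates;
    the event indicator must be coded 0/1 and required cells non-missing.
    Errors name the offending column.
    """
    df = pd.read_csv(path, sep=sep)
    for col in (id_col, time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"input file lacks required column {col!r}")
        if df[col].isna().any():
            row = int(df[df[col].isna()].index[0])
            raise ValueError(f"missing value in required column {col!r} (row {row})")
    times = pd.to_numeric(df[time_col], errors="coerce")
    if times.isna().any():
        row = int(times[times.isna()].index[0])
        raise ValueError(f"non-numeric time in column {time_col!r} (row {row})")
    events = pd.to_numeric(df[event_col], errors="coerce")
    if events.isna().any() or not set(np.unique(events)).issubset({0, 1}):
        raise ValueError(f"event column {event_col!r} must be coded 0/1")
    df[time_col] = times
    df[event_col] = events.astype(int)
    return SurvivalSample.from_dataframe(
        df, id_col=id_col, time_col=time_col, event_col=event_col,
        covariate_cols=covariate_cols,
    )


def write_manifest(path, command: str, config: dict, **counts) -> None:
    """JSON run manifest: command, configuration, seed, versions, row counts."""
    import pseudosurv

    manifest = {
        "command": command,
        "config": config,
        "versions": {
            "pseudosurv": pseudosurv.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        **counts,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
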