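"""Structured output: trajectory CSV and metrics JSON.

The time-series CSV always carries the full 16-column header (basic-variant
runs leave the extended columns empty), values printed with 12 significant
digits so a round trip through the file reproduces them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SimulationResult

__all__ = ["TIMESERIES_COLUMNS", "write_timeseries", "read_timeseries", "write_metrics"]

TIMESERIES_COLUMNS = (
    "t", "vc", "eps_c", "tau_c", "k_c", "p", "q", "V", "m", "n",
    "Fa", "PR", "PS", "PV", "u", "omega_rpm",
)


def write_timeseries(result: SimulationResult, path: str | Path) -> None:
    """Write the trajectory with derived signals as CSV.

    A comment line embeds the scenario hash so outputs are traceable to the
    configuration that produced them.
    """
    df = result.to_dataframe()
    for col in ("Fa", "PR", "PS"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(TIMESERIES_COLUMNS)]
    with open(path, "w") as fh:
        fh.write(f"# scenario_hash={result.solver_stats['scenario_hash']}\n")
        df.to_csv(fh, index=False, float_format="%.12g", na_rep="")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_metrics(metrics: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, default=default)
        fh.write("\n")
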