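"""CSV / JSON serialization for trajectories, datasets and results.

Time-series dialect: first column ``time``, one column per state name;
blank cells mark missing (masked-out) observations.  Every artifact written
alongside a run embeds the full configuration and seed for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import Trajectory
from .objective import Dataset

__all__ = [
    "write_trajectory", "read_trajectory",
    "write_dataset", "read_dataset",
    "write_json", "read_json",
    "write_trace_csv",
]


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    df = pd.DataFrame(traj.states, columns=traj.state_names)
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False)


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    if df.columns[0] != "time":
        raise ValueError(f"{path}: first column must be 'time'")
    return Trajectory(
        times=df["time"].to_numpy(float),
        states=df.iloc[:, 1:].to_numpy(float),
        state_names=list(df.columns[1:]),
    )


def write_dataset(data: Dataset, path: str | Path,
                  sidecar: str | Path | None = None) -> None:
    """Write observations as CSV (blank cell = missing); optionally write a
    JSON sidecar holding the noise metadata."""
    obs = np.where(data.mask, data.observations, np.nan)
    df = pd.DataFrame(obs, columns=data.state_names)
    df.insert(0, "time", data.times)
    df.to_csv(path, index=False, na_rep="")
    if sidecar is not None:
        write_json(data.noise_meta, sidecar)


def read_dataset(path: str | Path, sidecar: str | Path | None = None) -> Dataset:
    df = pd.read_csv(path)
    if df.columns[0] != "time":
        raise ValueError(f"{path}: first column must be 'time'")
    obs = df.iloc[:, 1:].to_numpy(float)
    meta = read_json(sidecar) if sidecar is not None else {}
    return Dataset(
        times=df["time"].to_numpy(float),
        observations=np.nan_to_num(obs),
        state_names=list(df.columns[1:]),
        mask=np.isfinite(obs),
        noise_meta=meta,
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.generic):
            return o.item()
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_trace_csv(trace: np.ndarray, path: str | Path) -> None:
    """Convergence trace: iteration index + best-so-far fitness."""
    pd.DataFrame({
        "iteration": np.arange(1, len(trace) + 1),
        "best_fitness": trace,
    }).to_csv(path, index=False)
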