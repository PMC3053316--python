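"""Trajectory, table and manifest I/O.

All outputs are plain text: long-format TSV for trajectories and speed
tables, JSON for manifests and reports, so every file is diffable and
regenerable from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LatticeState, ModelParams

__all__ = [
    "trajectory_to_frame",
    "write_trajectory_tsv",
    "read_trajectory_tsv",
    "write_manifest",
    "read_manifest",
    "write_speed_table",
]

PACKAGE_VERSION = "0.1.0"


def trajectory_to_frame(traj) -> pd.DataFrame:
    """Long-format (t, deme, N0, N1) frame from a SimTrajectory."""
    rows = []
    for t, st in zip(traj.times, traj.states):
        L = len(st.N0)
        rows.append(
            pd.DataFrame(
                {"t": np.full(L, t), "deme": np.arange(L), "N0": st.N0, "N1": st.N1}
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_trajectory_tsv(traj, path: str | Path) -> Path:
    path = Path(path)
    trajectory_to_frame(traj).to_csv(path, sep="\t", index=False)
    return path


def read_trajectory_tsv(path: str | Path):
    """Return (times, list of LatticeState) from a trajectory TSV."""
    df = pd.read_csv(path, sep="\t")
    times, states = [], []
    for t, grp in df.groupby("t", sort=True):
        grp = grp.sort_values("deme")
        times.append(int(t))
        states.append(LatticeState(grp["N0"].to_numpy(), grp["N1"].to_numpy(), t=int(t)))
    return np.asarray(times), states


def _params_dict(params: ModelParams) -> dict:
    return dataclasses.asdict(params)


def write_manifest(
    path: str | Path,
    params: ModelParams,
    engine: str,
    outputs: list[str],
    lambda_hat: float | None = None,
    extra: dict | None = None,
) -> Path:
    """JSON sidecar with the full parameter set, seed and code version."""
    path = Path(path)
    doc = {
        "engine": engine,
        "params": _params_dict(params),
        "seed": params.seed,
        "lambda_hat": lambda_hat,
        "version": PACKAGE_VERSION,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": outputs,
    }
    if extra:
        doc.update(extra)
    path.write_text(json.dumps(doc, indent=2) + "\n")
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_speed_table(rows: list[dict], path: str | Path) -> Path:
    """Collapse-ready TSV: one row per parameter cell with Gamma, v, stderr."""
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
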