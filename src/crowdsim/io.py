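"""Readers and writers: trajectory CSV, JSON summaries, XYZ snapshots."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .params import DIMER, INERT, MONOMER, ParameterSet

XYZ_TAGS = {MONOMER: "M", DIMER: "D", INERT: "I"}


def write_timeseries_csv(path, data: pd.DataFrame) -> None:
    """Write reaction progress as ``time_us,n_monomer,n_dimer``."""
    out = data[["time_us", "n_monomer", "n_dimer"]]
    out.to_csv(path, index=False, float_format="%.6f")


def read_timeseries_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["time_us", "n_monomer", "n_dimer"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df


def write_summary_json(path, summary: dict, params: ParameterSet | None = None) -> None:
    """JSON summary with a full parameter echo; key order is stable so
    identical inputs give identical bytes."""
    payload = dict(summary)
    if params is not None:
        payload["params"] = params.to_dict()
    from . import __version__

    payload["code_version"] = __version__
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_summary_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_xyz(path, positions: np.ndarray, species: np.ndarray, comment: str = "") -> None:
    """XYZ snapshot: element tags M/D/I, coordinates in nm."""
    positions = np.asarray(positions)
    with open(path, "w") as fh:
        fh.write(f"{len(positions)}\n{comment}\n")
        for sp, (x, y, z) in zip(species, positions):
            fh.write(f"{XYZ_TAGS[int(sp)]} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> tuple[np.ndarray, np.ndarray]:
    tags = {v: k for k, v in XYZ_TAGS.items()}
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        species = np.empty(n, dtype=np.int8)
        pos = np.empty((n, 3))
        for i in range(n):
            parts = fh.readline().split()
            species[i] = tags[parts[0]]
            pos[i] = [float(p) for p in parts[1:4]]
    return pos, species


def load_config(path) -> ParameterSet:
    return ParameterSet.from_toml(Path(path))
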