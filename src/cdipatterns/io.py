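"""Plain-text serialization: key=value configs and CSV state snapshots."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .integrate import IntegrationSettings
from .model import ModelParams, PopulationState

__all__ = [
    "params_to_config",
    "params_from_config",
    "settings_to_config",
    "settings_from_config",
    "save_state_csv",
    "load_state_csv",
]

PathLike = Union[str, Path]


def _dump(d: dict) -> str:
    return "".join(f"{k} = {v}\n" for k, v in d.items())


def _parse(text: str) -> dict:
    out = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out


def params_to_config(params: ModelParams) -> str:
    """One `key = value` line per field (c is canonical; c1/c2 are derived)."""
    return _dump(asdict(params))


def params_from_config(text: str) -> ModelParams:
    raw = _parse(text)
    kwargs = {}
    for key, val in raw.items():
        if key == "n_grid":
            kwargs[key] = int(val)
        elif key == "kernel":
            kwargs[key] = val
        else:
            kwargs[key] = float(val)
    return ModelParams(**kwargs)


def settings_to_config(settings: IntegrationSettings) -> str:
    return _dump(asdict(settings))


def settings_from_config(text: str) -> IntegrationSettings:
    raw = _parse(text)
    kwargs = {}
    for key, val in raw.items():
        kwargs[key] = int(val) if key == "convergence_window" else float(val)
    return IntegrationSettings(**kwargs)


def save_state_csv(state: PopulationState, path: PathLike) -> None:
    """Tidy snapshot (site_index or row/col, u, v); time goes in a header row."""
    df = state.to_dataframe()
    df.insert(0, "time", state.time)
    df.to_csv(path, index=False)


def load_state_csv(path: PathLike) -> PopulationState:
    df = pd.read_csv(path)
    time = float(df["time"].iloc[0]) if "time" in df else 0.0
    if "row" in df.columns:
        n = int(df["row"].max()) + 1
        u = np.zeros((n, n))
        v = np.zeros((n, n))
        u[df["row"], df["col"]] = df["u"]
        v[df["row"], df["col"]] = df["v"]
    elif "site_index" in df.columns:
        order = np.argsort(df["site_index"].to_numpy())
        u = df["u"].to_numpy()[order]
        v = df["v"].to_numpy()[order]
    else:  # scalar state
        u = float(df["u"].iloc[0])
        v = float(df["v"].iloc[0])
    return PopulationState(u, v, time)
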