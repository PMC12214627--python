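"""Plain-text configuration loading and delimited-text output writers.

Configuration files are flat TOML (every key at top level) echoing model
parameters and experiment settings; unknown keys are rejected. Outputs are
tab-separated tables preceded by ``#``-prefixed header metadata (seed,
derived scales) for provenance.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .params import (ConfigError, DerivedScales, ExperimentConfig,
                     ModelParams, build_config)
from .state import PREDATOR_MODE_NAMES, PREY_MODE_NAMES, WorldState

__all__ = ["load_config", "write_table", "read_table", "trajectory_frame",
           "write_example_config"]


def load_config(path: str | Path
                ) -> tuple[ModelParams, DerivedScales, ExperimentConfig]:
    """Parse a flat TOML config into validated parameter objects."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if any(isinstance(v, dict) for v in raw.values()):
        raise ConfigError("config must be flat key-value (no TOML tables)")
    exp_keys = {"strategy", "Omega_P", "chi_target", "n_realisations",
                "seed", "T_max"}
    exp_kwargs = {k: raw[k] for k in exp_keys if k in raw}
    model_raw = {k: v for k, v in raw.items() if k not in exp_keys or
                 k == "chi_target"}
    params, scales = build_config(model_raw)
    exp = ExperimentConfig(**exp_kwargs)
    return params, scales, exp


def write_example_config(path: str | Path, params: ModelParams | None = None,
                         exp: ExperimentConfig | None = None) -> None:
    """Write a complete flat-TOML config echoing every parameter."""
    params = params or ModelParams()
    exp = exp or ExperimentConfig()
    lines = ["# preyflock configuration (flat TOML; all lengths in d_pr, "
             "times in t0)"]
    for k, v in asdict(params).items():
        lines.append(f"{k} = {_toml_value(v)}")
    for k, v in asdict(exp).items():
        if v is None:
            continue
        lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, float) and math.isinf(v):
        return "inf"
    return repr(v)


def _header(meta: dict) -> str:
    return "".join(f"# {k} = {v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None
                ) -> None:
    """Tab-separated table with #-prefixed provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            fh.write(_header(meta))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def trajectory_frame(world: WorldState) -> pd.DataFrame:
    """One snapshot as a flat table (time, id, species, x, y, vx, vy, mu, mode)."""
    rows = []
    for i in range(world.n_prey):
        rows.append((world.t, i, "prey", *world.prey_x[i], *world.prey_v[i],
                     int(world.mu[i]), PREY_MODE_NAMES[int(world.prey_mode[i])]))
    for k in range(world.n_predators):
        rows.append((world.t, k, "predator", *world.pred_x[k],
                     *world.pred_v[k], 1,
                     PREDATOR_MODE_NAMES[int(world.pred_mode[k])]))
    return pd.DataFrame(rows, columns=["t", "id", "species", "x", "y",
                                       "vx", "vy", "mu", "mode"])


class TrajectoryRecorder:
    """Observer accumulating trajectory snapshots at a fixed stride."""

    def __init__(self) -> None:
        self.frames: list[pd.DataFrame] = []

    def __call__(self, world: WorldState, step_index: int) -> None:
        self.frames.append(trajectory_frame(world))

    def to_frame(self) -> pd.DataFrame:
        if not self.frames:
            return pd.DataFrame(columns=["t", "id", "species", "x", "y",
                                         "vx", "vy", "mu", "mode"])
        return pd.concat(self.frames, ignore_index=True)


def scales_meta(scales: DerivedScales, seed: int) -> dict:
    """Provenance header fields echoed into every output file."""
    return {"seed": seed, "v0": scales.v0, "t0": scales.t0,
            "chi": scales.chi, "schema_version": 1}
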