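"""Validated run configuration and file I/O.

A RunConfig gathers every knob of a reproducible run in nested blocks
(dynamics, grid, challenge, weights, comparator, preset, tasks, fit)
plus one master seed; all stochastic operations derive named child
streams from that seed.  Configs load from JSON (YAML accepted) and are
schema-validated before any computation runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_manifest",
]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DynamicsBlock(_Block):
    a: float = 1.0
    b: float = 2.0
    d_r0: float = 0.0
    dd_r0: float = 0.0

    @field_validator("a", "b")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive (got {v})")
        return v


class GridBlock(_Block):
    t_end: float = 20.0
    dt: float = 0.02

    @field_validator("t_end", "dt")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive (got {v})")
        return v


class ChallengeBlock(_Block):
    onset: float = Field(default=1.0, ge=0)
    duration: float = Field(default=3.0, ge=0)
    amplitude: float = 0.5
    shape: str = "step"


class WeightsBlock(_Block):
    tau_cross: float = Field(default=1.0, gt=0)
    slope: float = Field(default=2.0, gt=0)
    ctx_center: float = 0.0
    ctx_width: float = Field(default=0.5, gt=0)
    ctx_height: float = Field(default=0.5, ge=0)


class ComparatorBlock(_Block):
    form: str = "default"
    g: float = Field(default=0.0, ge=0.0, le=1.0)


class PresetBlock(_Block):
    name: str = "null"
    delta: float = Field(default=0.2, gt=0)
    tau: float = Field(default=2.0, gt=0)


class TaskBlock(_Block):
    task: str
    durations: list[float] = [1.0]
    n_trials: int = Field(default=100, ge=1)
    condition: str = ""
    kappa: float | None = Field(default=None, gt=0)
    noise: dict = {}


class FitBlock(_Block):
    kind: str = "dynamics"  # dynamics | kappa_reproduction | kappa_eeg
    data: str = ""  # path to a trajectory/trial CSV
    f_base: float | None = None
    n_starts: int = 16


class RunConfig(_Block):
    seed: int = 0
    out_dir: str = "cdt_out"
    dynamics: DynamicsBlock = DynamicsBlock()
    grid: GridBlock = GridBlock()
    challenge: ChallengeBlock | None = None
    weights: WeightsBlock = WeightsBlock()
    comparator: ComparatorBlock = ComparatorBlock()
    preset: PresetBlock = PresetBlock()
    tasks: list[TaskBlock] = []
    fit: FitBlock = FitBlock()

    # --- object builders -------------------------------------------------
    def build_dynamics(self):
        from .core import DynamicsParams

        return DynamicsParams(a=self.dynamics.a, b=self.dynamics.b)

    def build_state0(self):
        from .core import DeviationState

        return DeviationState(d_r=self.dynamics.d_r0, dd_r=self.dynamics.dd_r0)

    def build_grid(self):
        from .core import TimeGrid

        return TimeGrid.regular(self.grid.t_end, self.grid.dt)

    def build_challenge(self):
        from .core import ChallengeProtocol

        if self.challenge is None:
            return None
        return ChallengeProtocol(**self.challenge.model_dump())

    def build_profile(self):
        from .composition import WeightProfile

        return WeightProfile(**self.weights.model_dump())

    def build_comparator(self):
        from .composition import ComparatorSpec

        return ComparatorSpec(g=self.comparator.g, form=self.comparator.form)

    def build_preset(self):
        from .disorders import preset

        return preset(self.preset.name, delta=self.preset.delta, seed=self.seed)


def load_config(path) -> RunConfig:
    """Load and validate a JSON (or YAML) run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig.model_validate(data or {})


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(config.model_dump_json(indent=2) + "\n")


# --- CSV dialect: UTF-8, comma, '.' decimal, mandatory header, 'inf' for
# the infinite-precision sentinel -----------------------------------------


def write_trajectory_csv(traj, path) -> None:
    """Write a gain trajectory as columns t,d_r,kappa,precision."""
    df = traj.to_frame()
    df.to_csv(path, index=False, float_format="%.12g")


def read_trajectory_csv(path):
    df = pd.read_csv(path)
    required = {"t", "d_r", "kappa", "precision"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    return df


def write_manifest(out_dir, config: RunConfig, files) -> Path:
    """Write run manifest with config echo and per-file SHA-256 checksums."""
    out_dir = Path(out_dir)
    checksums = {}
    for f in files:
        f = Path(f)
        checksums[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = {
        "package": "cdt",
        "version": _package_version(),
        "config": config.model_dump(),
        "checksums": checksums,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = out_dir / "manifest.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, default=_jsonable) + "\n")
    tmp.replace(path)
    return path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("cdt")
    except Exception:
        return "unknown"
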