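"""Run configuration: validated parameter files with human-like defaults.

A configuration file (YAML or JSON) holds up to four sections - ``runner``,
``terrain``, ``ensemble`` and ``sweep`` - each optional; omitted fields fall
back to the human-like defaults (I_G = 0.17, eps_n = 0.63, phi_tol = pi/6,
v_x0 = 0.96, v_y0 = 0.26, uniform heights of range 0.06 at spacing 0.1,
M = 1e5 trials of at most 1e3 steps).  Unknown keys are rejected so typos
fail loudly, and a config round-trips losslessly through dump/load.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .model_core import RunnerParams
from .terrain import DistSpec, TerrainKind, TerrainSpec

__all__ = ["EnsembleConfig", "RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class EnsembleConfig:
    M: int = 100_000
    max_steps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("ensemble.M must be >= 1")
        if self.max_steps < 1:
            raise ValueError("ensemble.max_steps must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    runner: RunnerParams = field(default_factory=RunnerParams)
    terrain: TerrainSpec = field(default_factory=TerrainSpec)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    sweep: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "runner": self.runner.to_dict(),
            "terrain": self.terrain.to_dict(),
            "ensemble": dataclasses.asdict(self.ensemble),
            "sweep": self.sweep,
        }


def _check_keys(section: str, data: dict, allowed) -> None:
    unknown = set(data) - set(allowed)
    if unknown:
        raise ValueError(
            f"unknown key(s) in config section '{section}': {sorted(unknown)}"
        )


def _runner_from_dict(data: dict) -> RunnerParams:
    fields = {f.name for f in dataclasses.fields(RunnerParams)}
    _check_keys("runner", data, fields)
    return RunnerParams(**data)


def _terrain_from_dict(data: dict) -> TerrainSpec:
    _check_keys("terrain", data, {"kind", "lambda", "lambda_", "dist"})
    kind = TerrainKind(data.get("kind", "rough"))
    lam = float(data.get("lambda", data.get("lambda_", 0.1)))
    dist_data = dict(data.get("dist", {}))
    _check_keys(
        "terrain.dist", dist_data, {"family", "range", "range_", "kappa", "alpha", "beta"}
    )
    if "range" in dist_data:
        dist_data["range_"] = dist_data.pop("range")
    dist = DistSpec(**dist_data)
    return TerrainSpec(kind=kind, lambda_=lam, dist=dist)


def _ensemble_from_dict(data: dict) -> EnsembleConfig:
    _check_keys("ensemble", data, {"M", "max_steps", "seed"})
    return EnsembleConfig(**data)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    _check_keys("config", data, {"runner", "terrain", "ensemble", "sweep"})
    sweep = data.get("sweep")
    if sweep is not None:
        _check_keys("sweep", sweep, {"eps_n", "eps_tc", "delta_eps_t"})
        sweep = {k: [float(v) for v in vs] for k, vs in sweep.items()}
    return RunConfig(
        runner=_runner_from_dict(dict(data.get("runner", {}))),
        terrain=_terrain_from_dict(dict(data.get("terrain", {}))),
        ensemble=_ensemble_from_dict(dict(data.get("ensemble", {}))),
        sweep=sweep,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON configuration file.

    An empty file yields the full human-like default configuration.
    """
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def dump_config(cfg: RunConfig, path) -> None:
    """Write a configuration back to YAML (lossless round-trip)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
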