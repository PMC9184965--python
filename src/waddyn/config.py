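"""Strict run configuration: schema, validation and YAML/JSON round-trip.

A run configuration names a landscape family and its numerical settings and,
optionally, the signal conditions and fitting setup a command should use.
Schemas are strict: unknown keys are rejected by name with their field path,
so a typo like ``sigmaa`` fails loudly instead of silently using a default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .families import LandscapeModel, RiemannianMetric, SignalPath, make_family

__all__ = [
    "ModelConfig",
    "ConditionConfig",
    "FitParameterConfig",
    "FitConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "build_model",
    "build_conditions",
]


class ConfigError(ValueError):
    """A configuration file violates the schema; the message names the path."""


def _check_keys(mapping: dict, allowed: dict, path: str) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping, got {type(mapping).__name__}")
    for key in mapping:
        if key not in allowed:
            loc = f"{path}.{key}" if path else key
            raise ConfigError(f"unknown config key {key!r} at {loc!r}")
    for key, required in allowed.items():
        if required and key not in mapping:
            loc = f"{path}.{key}" if path else key
            raise ConfigError(f"missing required config key {key!r} at {loc!r}")


@dataclass
class ConditionConfig:
    """One named signal condition: a piecewise-linear parameter schedule."""

    name: str
    t_grid: list
    theta_knots: list  # one theta row per time knot

    _SCHEMA = {"name": True, "t_grid": True, "theta_knots": True}

    @classmethod
    def from_dict(cls, data: dict, path: str) -> "ConditionConfig":
        _check_keys(data, cls._SCHEMA, path)
        return cls(
            name=str(data["name"]),
            t_grid=[float(t) for t in data["t_grid"]],
            theta_knots=[[float(v) for v in row] for row in data["theta_knots"]],
        )

    def to_dict(self) -> dict:
        return {"name": self.name, "t_grid": self.t_grid, "theta_knots": self.theta_knots}

    def to_path(self) -> SignalPath:
        return SignalPath(np.asarray(self.t_grid), np.asarray(self.theta_knots))


@dataclass
class FitParameterConfig:
    """One free fit parameter: a uniform prior on an additive theta offset.

    The parameter adds ``value * weight(condition)`` to one component of the
    condition's scheduled theta; per-condition weights default to 1, which
    makes e.g. a baseline offset (all weights 1) and a signal sensitivity
    (weights equal to the signal level) expressible together.
    """

    name: str
    component: int
    low: float
    high: float
    condition_weights: dict = field(default_factory=dict)

    _SCHEMA = {
        "name": True,
        "component": True,
        "low": True,
        "high": True,
        "condition_weights": False,
    }

    @classmethod
    def from_dict(cls, data: dict, path: str) -> "FitParameterConfig":
        _check_keys(data, cls._SCHEMA, path)
        return cls(
            name=str(data["name"]),
            component=int(data["component"]),
            low=float(data["low"]),
            high=float(data["high"]),
            condition_weights={
                str(k): float(v) for k, v in (data.get("condition_weights") or {}).items()
            },
        )

    def to_dict(self) -> dict:
        out = {
            "name": self.name,
            "component": self.component,
            "low": self.low,
            "high": self.high,
        }
        if self.condition_weights:
            out["condition_weights"] = dict(self.condition_weights)
        return out


@dataclass
class FitConfig:
    """ABC-SMC settings: free parameters and algorithm sizes."""

    parameters: list
    n_particles: int = 200
    n_generations: int = 4
    quantile: float = 0.3
    n_cells: int = 100

    _SCHEMA = {
        "parameters": True,
        "n_particles": False,
        "n_generations": False,
        "quantile": False,
        "n_cells": False,
    }

    @classmethod
    def from_dict(cls, data: dict, path: str) -> "FitConfig":
        _check_keys(data, cls._SCHEMA, path)
        params = [
            FitParameterConfig.from_dict(p, f"{path}.parameters[{i}]")
            for i, p in enumerate(data["parameters"])
        ]
        return cls(
            parameters=params,
            n_particles=int(data.get("n_particles", 200)),
            n_generations=int(data.get("n_generations", 4)),
            quantile=float(data.get("quantile", 0.3)),
            n_cells=int(data.get("n_cells", 100)),
        )

    def to_dict(self) -> dict:
        return {
            "parameters": [p.to_dict() for p in self.parameters],
            "n_particles": self.n_particles,
            "n_generations": self.n_generations,
            "quantile": self.quantile,
            "n_cells": self.n_cells,
        }


@dataclass
class ModelConfig:
    """Full run configuration for a landscape model."""

    family: str
    theta: list | None = None
    metric: list | None = None  # 2x2 SPD matrix, identity when omitted
    sigma: float = 0.0
    dt: float = 0.01
    conditions: list = field(default_factory=list)
    fit: FitConfig | None = None

    _SCHEMA = {
        "family": True,
        "theta": False,
        "metric": False,
        "sigma": False,
        "dt": False,
        "conditions": False,
        "fit": False,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        _check_keys(data, cls._SCHEMA, "")
        conditions = [
            ConditionConfig.from_dict(c, f"conditions[{i}]")
            for i, c in enumerate(data.get("conditions") or [])
        ]
        fit = FitConfig.from_dict(data["fit"], "fit") if data.get("fit") else None
        theta = data.get("theta")
        metric = data.get("metric")
        return cls(
            family=str(data["family"]),
            theta=None if theta is None else [float(v) for v in theta],
            metric=None if metric is None else [[float(v) for v in row] for row in metric],
            sigma=float(data.get("sigma", 0.0)),
            dt=float(data.get("dt", 0.01)),
            conditions=conditions,
            fit=fit,
        )

    def to_dict(self) -> dict:
        out: dict = {"family": self.family, "sigma": self.sigma, "dt": self.dt}
        if self.theta is not None:
            out["theta"] = list(self.theta)
        if self.metric is not None:
            out["metric"] = [list(row) for row in self.metric]
        if self.conditions:
            out["conditions"] = [c.to_dict() for c in self.conditions]
        if self.fit is not None:
            out["fit"] = self.fit.to_dict()
        return out


def load_config(path) -> ModelConfig:
    """Load a YAML or JSON config file with strict key checking."""
    text = open(path).read()
    if str(path).lower().endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return ModelConfig.from_dict(data)


def save_config(config: ModelConfig, path) -> None:
    """Write a config as YAML or JSON (by file extension); lossless round-trip."""
    data = config.to_dict()
    with open(path, "w") as fh:
        if str(path).lower().endswith(".json"):
            json.dump(data, fh, indent=1)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def build_model(config: ModelConfig) -> LandscapeModel:
    family = make_family(config.family)
    metric = (
        RiemannianMetric.identity(family.dim)
        if config.metric is None
        else RiemannianMetric.constant(np.asarray(config.metric, float))
    )
    return LandscapeModel(family=family, metric=metric, theta=config.theta, sigma=config.sigma)


def build_conditions(config: ModelConfig):
    """Instantiate the config's signal conditions as population conditions."""
    from .cellpop import PopulationCondition

    return [
        PopulationCondition(name=c.name, path=c.to_path()) for c in config.conditions
    ]
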