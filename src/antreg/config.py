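"""Flat key-value configuration files and object builders.

Configs are flat YAML mappings (``key: value`` lines, ``#`` comments), one
key per model constant, so they diff cleanly and can be overridden one key
at a time from the command line.
"""

from __future__ import annotations

import yaml

from .errors import ConfigurationError
from .evolve import ParameterBounds, SearchConfig, SearchMode
from .fitness import FitnessParams
from .model import (
    ModelParameters,
    PromoterControl,
    RegulatorKinetics,
    SignalSchedule,
    TargetProteinParams,
)

__all__ = [
    "default_config",
    "load_config",
    "save_config",
    "resolve_config",
    "build_schedule",
    "build_model",
    "build_fitness",
    "build_bounds",
    "build_search",
    "parse_overrides",
]

#: every recognized flat key with its default
DEFAULTS = {
    # signal schedule
    "t0": 0.0,
    "t1": 6.0,
    "t2": 12.0,
    "s1_level": 1.0,
    "s2_level": 1.0,
    # regulator kinetics
    "kf1": 1.0,
    "kr1": 4.0,
    "R1_total": 1.0,
    "kf2": 1.0,
    "kr2": 4.0,
    "R2_total": 1.0,
    # promoter and target
    "b1": 0.0,
    "b2": 1.0,
    "Km1": 1.0,
    "Km2": 1.0,
    "hill1": 1.0,
    "kd2": 1.0,
    "T2_init": 0.0,
    # fitness
    "E_max": 5.0,
    "Km_T2": 1.0,
    "c0": 0.05,
    "cost_basis": "synthesis",
    # evolvable windows
    "b_min": 0.0,
    "b_max": 10.0,
    "Km_min": 1e-2,
    "Km_max": 1e2,
    "k_on_min": 1e-2,
    "k_on_max": 1e2,
    "k_off": 1.0,
    # search budget
    "mode": "b",
    "restarts": 3,
    "iterations": 150,
    "step": 0.4,
    "seed": 0,
    "fixed_b": 5.0,
    "epsilon_rel": 1e-3,
    "n_points": 1001,
    # sweep grids
    "kd_grid_min": 1e-3,
    "kd_grid_max": 10.0,
    "kd_grid_points": 25,
    "emax_grid_min": 0.5,
    "emax_grid_max": 10.0,
    "emax_grid_points": 8,
}


def default_config() -> dict:
    return dict(DEFAULTS)


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigurationError("config must be a flat key-value mapping")
    return data


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, default_flow_style=False, sort_keys=True)


def parse_overrides(pairs) -> dict:
    """Parse ``key=value`` command-line overrides with YAML value semantics."""
    out = {}
    for pair in pairs:
        if "=" not in pair:
            raise ConfigurationError(f"override {pair!r} is not of the form key=value")
        key, raw = pair.split("=", 1)
        out[key.strip()] = yaml.safe_load(raw)
    return out


def resolve_config(file_cfg: dict | None = None, overrides: dict | None = None) -> dict:
    """Defaults <- config file <- --set overrides, rejecting unknown keys."""
    cfg = default_config()
    for source in (file_cfg or {}, overrides or {}):
        unknown = set(source) - set(DEFAULTS)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(source)
    return cfg


def build_schedule(cfg: dict) -> SignalSchedule:
    return SignalSchedule(
        t0=float(cfg["t0"]),
        t1=float(cfg["t1"]),
        t2=float(cfg["t2"]),
        s1_level=float(cfg["s1_level"]),
        s2_level=float(cfg["s2_level"]),
    )


def build_model(cfg: dict) -> ModelParameters:
    return ModelParameters(
        reg1=RegulatorKinetics(float(cfg["kf1"]), float(cfg["kr1"]), float(cfg["R1_total"])),
        reg2=RegulatorKinetics(float(cfg["kf2"]), float(cfg["kr2"]), float(cfg["R2_total"])),
        promoter=PromoterControl(
            b1=float(cfg["b1"]),
            b2=float(cfg["b2"]),
            Km1=float(cfg["Km1"]),
            Km2=float(cfg["Km2"]),
            hill1=float(cfg["hill1"]),
        ),
        target=TargetProteinParams(kd2=float(cfg["kd2"]), T2_init=float(cfg["T2_init"])),
    )


def build_fitness(cfg: dict) -> FitnessParams:
    return FitnessParams(
        E_max=float(cfg["E_max"]),
        Km_T2=float(cfg["Km_T2"]),
        c0=float(cfg["c0"]),
        cost_basis=str(cfg["cost_basis"]),
    )


def build_bounds(cfg: dict, mode: SearchMode) -> ParameterBounds:
    if mode == SearchMode.PROMOTER_STRENGTH:
        return ParameterBounds(
            {
                "b1": (float(cfg["b_min"]), float(cfg["b_max"])),
                "b2": (float(cfg["b_min"]), float(cfg["b_max"])),
                "Km1": (float(cfg["Km_min"]), float(cfg["Km_max"])),
                "Km2": (float(cfg["Km_min"]), float(cfg["Km_max"])),
            }
        )
    return ParameterBounds(
        {
            "k_on1": (float(cfg["k_on_min"]), float(cfg["k_on_max"])),
            "k_on2": (float(cfg["k_on_min"]), float(cfg["k_on_max"])),
        }
    )


def build_search(cfg: dict, mode: str | None = None, seed: int | None = None) -> SearchConfig:
    return SearchConfig(
        mode=SearchMode(mode if mode is not None else cfg["mode"]),
        restarts=int(cfg["restarts"]),
        iterations=int(cfg["iterations"]),
        step=float(cfg["step"]),
        seed=int(cfg["seed"] if seed is None else seed),
        fixed_b=float(cfg["fixed_b"]),
        epsilon_rel=float(cfg["epsilon_rel"]),
        n_points=int(cfg["n_points"]),
    )
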