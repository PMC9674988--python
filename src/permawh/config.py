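"""Run configuration: a structured YAML file with sections for the landscape,
the AWH sampler, friction analysis, the layer model and seeds.

Every run serializes its effective (defaulted) configuration next to its
outputs so results can be reproduced from the output directory alone.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .awh import AWHConfig, GridSpec
from .dynamics import IntegratorParams
from .landscape import ThermoParams, ToyLandscape, build_landscape, default_membrane_spec
from .permeability import LayerModel

__all__ = ["RunConfig", "load_config", "dump_effective_config"]


@dataclasses.dataclass
class RunConfig:
    landscape_spec: dict
    landscape: ToyLandscape
    grid: GridSpec
    awh: AWHConfig
    integrator: IntegratorParams
    thermo: ThermoParams
    layer_model: LayerModel
    friction: dict
    solvation: dict
    seeds: list[int]
    n_steps_per_walker: int


def _defaults() -> dict:
    return {
        "landscape": default_membrane_spec(),
        "grid": {"n_z": 36, "lambda_states": None},  # lambda from the landscape
        "awh": {},
        "integrator": {},
        "thermo": {"temperature": 305.15},
        "permeability": {"layer_model": {}},
        "friction": {"n_blocks": 128, "median_window": 0.2, "lambda_index": 0},
        "solvation": {"n_steps_per_walker": 200000},
        "seeds": {"base": 1},
        "run": {"n_steps_per_walker": 200000, "n_walkers": None},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a run config, filling unset sections with defaults."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw = _merge(_defaults(), raw)
    if overrides:
        raw = _merge(raw, overrides)
    land = build_landscape(raw["landscape"])
    gs = raw["grid"]
    n_lambda = gs.get("lambda_states") or land.schedule.n_states
    grid = GridSpec(
        z_min=float(gs.get("z_min", 0.0)),
        z_max=float(gs.get("z_max", land.length)),
        n_z=int(gs["n_z"]),
        lambda_states=int(n_lambda),
    )
    awh_kwargs = dict(raw["awh"])
    if raw["run"].get("n_walkers"):
        awh_kwargs["n_walkers"] = int(raw["run"]["n_walkers"])
    awh = AWHConfig(**awh_kwargs)
    integ = IntegratorParams(**raw["integrator"])
    thermo = ThermoParams(**raw["thermo"])
    lm = LayerModel(**raw["permeability"]["layer_model"])
    base = int(raw["seeds"].get("base", 1))
    seeds = raw["seeds"].get("walkers") or list(range(base, base + awh.n_walkers))
    return RunConfig(
        landscape_spec=raw["landscape"],
        landscape=land,
        grid=grid,
        awh=awh,
        integrator=integ,
        thermo=thermo,
        layer_model=lm,
        friction=raw["friction"],
        solvation=raw["solvation"],
        seeds=[int(s) for s in seeds],
        n_steps_per_walker=int(raw["run"]["n_steps_per_walker"]),
    )


def dump_effective_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize the effective configuration of a run as YAML."""
    doc = {
        "landscape": cfg.landscape_spec,
        "grid": {
            "z_min": cfg.grid.z_min,
            "z_max": cfg.grid.z_max,
            "n_z": cfg.grid.n_z,
            "lambda_states": cfg.grid.lambda_states,
        },
        "awh": dataclasses.asdict(cfg.awh)
        if not isinstance(cfg.awh.target_spec, str)
        else {**dataclasses.asdict(cfg.awh), "target_spec": cfg.awh.target_spec},
        "integrator": dataclasses.asdict(cfg.integrator),
        "thermo": dataclasses.asdict(cfg.thermo),
        "permeability": {"layer_model": dataclasses.asdict(cfg.layer_model)},
        "friction": cfg.friction,
        "solvation": cfg.solvation,
        "seeds": {"walkers": cfg.seeds},
        "run": {"n_steps_per_walker": cfg.n_steps_per_walker},
    }
    if not isinstance(doc["awh"]["target_spec"], str):
        doc["awh"]["target_spec"] = [float(x) for x in doc["awh"]["target_spec"]]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
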