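"""YAML configuration schema and loaders.

A single config file describes the community (species, resources,
interactions), the thermal setup, the solver, and optional scenario
settings.  Unknown keys raise, so typos fail loudly.

Schema (all species/resource fields mirror the dataclasses)::

    species:
      - name: forage_small
        w0: 1.0e-3
        Wi: 30.0
        ...
    resources:
      - name: pelagic
        r0: 0.2
        kappa: 5.0e11
        lambda_: 2.05
        w_min: 1.0e-7
        w_max: 1.0
    thermal:
      Tref: 283.15
      scenario: both
      E_met: [0.59, 0.08]
      ...
    solver:
      dt: 0.1
      t_max: 200.0
    grid:
      bins_per_decade: 15
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .model_core import Model, ResourceParams, SpeciesParams
from .dynamics_engine import SolverConfig
from .thermal import ThermalConfig

__all__ = ["load_config", "dump_config", "config_hash", "model_from_config"]


def _filter_kwargs(cls, data: dict, context: str) -> dict:
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    return data


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return raw


def model_from_config(raw: dict) -> tuple[Model, ThermalConfig, SolverConfig]:
    species = [
        SpeciesParams(**_filter_kwargs(SpeciesParams, dict(s, theta_R=tuple(s.get("theta_R", (1.0,)))), f"species[{k}]"))
        for k, s in enumerate(raw.get("species", []))
    ]
    resources = [
        ResourceParams(**_filter_kwargs(ResourceParams, dict(r), f"resources[{k}]"))
        for k, r in enumerate(raw.get("resources", []))
    ]
    if not species or not resources:
        raise ValueError("config must define at least one species and one resource")
    th_raw = dict(raw.get("thermal", {}))
    for key in ("E_met", "E_cons", "E_search", "E_mort", "E_r0", "E_kappa"):
        if key in th_raw and th_raw[key] is not None:
            th_raw[key] = tuple(th_raw[key])
    thermal = ThermalConfig(**_filter_kwargs(ThermalConfig, th_raw, "thermal"))
    solver = SolverConfig(**_filter_kwargs(SolverConfig, dict(raw.get("solver", {})), "solver"))
    bins = int(raw.get("grid", {}).get("bins_per_decade", 15))
    model = Model(species, resources, bins_per_decade=bins)
    return model, thermal, solver


def dump_config(model: Model, thermal: ThermalConfig, solver: SolverConfig, path: str | Path) -> None:
    def clean(obj) -> dict:
        out = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    raw = {
        "species": [clean(sp) for sp in model.species],
        "resources": [clean(r) for r in model.resources],
        "thermal": clean(thermal),
        "solver": clean(solver),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def config_hash(raw: dict) -> str:
    return hashlib.sha256(json.dumps(raw, sort_keys=True, default=str).encode()).hexdigest()[:12]
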