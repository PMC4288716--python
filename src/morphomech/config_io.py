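"""YAML serialization of scenarios and solver settings.

The scenario schema mirrors the dataclasses: a ``dome`` block (radius,
layers, resolution, jitter, seed), a ``regions`` list (name, kind and the
geometric predicate parameters), a ``params`` map from region name to the
mechanical parameter block ({pressure, modulus, anisotropy, extensibility,
threshold, ...}, anisotropy as {mode, axis/center, ratio}), an ``events``
map (step -> region -> parameter changes), and scalars dt / n_steps /
growth_mode.  Unknown keys are rejected by name so configuration typos
fail loudly.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import numpy as np
import yaml

from .simulator import RegionParams, Scenario
from .solver import SolverConfig
from .template_gen import AnisotropyField, DomeSpec, RegionSpec

__all__ = ["scenario_to_dict", "scenario_from_dict", "load_scenario",
           "save_scenario", "solver_config_from_dict"]


class ConfigError(ValueError):
    """Raised for malformed scenario/solver configuration documents."""


def _check_keys(doc: dict, allowed: set[str], where: str) -> None:
    bad = set(doc) - allowed
    if bad:
        raise ConfigError(f"unknown field(s) {sorted(bad)} in {where}")


def _aniso_to_dict(af: AnisotropyField) -> dict:
    out = {"mode": af.mode}
    if af.mode == "circumferential":
        out.update(axis=np.asarray(af.axis, float).tolist(), ratio=af.ratio)
    elif af.mode == "ortho-radial":
        out.update(center=np.asarray(af.center, float).tolist(), ratio=af.ratio)
    elif af.mode == "gradient":
        out.update(axis=np.asarray(af.axis, float).tolist(),
                   bottom_ratio=af.bottom_ratio, top_ratio=af.top_ratio)
    return out


def _aniso_from_dict(doc: dict) -> AnisotropyField:
    _check_keys(doc, {"mode", "axis", "center", "ratio", "bottom_ratio",
                      "top_ratio"}, "anisotropy")
    kw = dict(doc)
    for key in ("axis", "center"):
        if key in kw and kw[key] is not None:
            kw[key] = np.asarray(kw[key], float)
    return AnisotropyField(**kw)


def _params_to_dict(rp: RegionParams) -> dict:
    out = {f.name: getattr(rp, f.name) for f in fields(RegionParams)}
    out["anisotropy"] = _aniso_to_dict(rp.anisotropy)
    return out


def _params_from_dict(doc: dict, where: str) -> RegionParams:
    allowed = {f.name for f in fields(RegionParams)}
    _check_keys(doc, allowed, where)
    kw = dict(doc)
    if "anisotropy" in kw:
        kw["anisotropy"] = _aniso_from_dict(kw["anisotropy"] or {"mode": "isotropic"})
    return RegionParams(**kw)


def _region_to_dict(rs: RegionSpec) -> dict:
    out = {"name": rs.name, "kind": rs.kind}
    if rs.kind == "height_band":
        out.update(lo=rs.lo, hi=rs.hi)
    elif rs.kind in ("cap", "ring"):
        out["center"] = np.asarray(rs.center, float).tolist()
        out["angle"] = rs.angle
        if rs.kind == "ring":
            out["inner_angle"] = rs.inner_angle
        if rs.side:
            out["side"] = rs.side
    if rs.layers is not None:
        out["layers"] = list(rs.layers)
    return out


def _region_from_dict(doc: dict) -> RegionSpec:
    allowed = {f.name for f in fields(RegionSpec)}
    _check_keys(doc, allowed, f"region {doc.get('name', '?')!r}")
    kw = dict(doc)
    if kw.get("center") is not None:
        kw["center"] = np.asarray(kw["center"], float)
    if kw.get("layers") is not None:
        kw["layers"] = tuple(kw["layers"])
    return RegionSpec(**kw)


def scenario_to_dict(sc: Scenario) -> dict:
    return {
        "name": sc.name,
        "dome": {"radius": sc.dome.radius, "layers": sc.dome.layers,
                 "resolution": sc.dome.resolution, "jitter": sc.dome.jitter,
                 "seed": sc.dome.seed},
        "regions": [_region_to_dict(r) for r in sc.regions],
        "params": {k: _params_to_dict(v) for k, v in sc.params.items()},
        "events": {int(k): v for k, v in sc.events.items()},
        "default_region": sc.default_region,
        "dt": sc.dt,
        "n_steps": sc.n_steps,
        "growth_mode": sc.growth_mode,
    }


def scenario_from_dict(doc: dict) -> Scenario:
    _check_keys(doc, {"name", "dome", "regions", "params", "events",
                      "default_region", "dt", "n_steps", "growth_mode"},
                "scenario")
    if "name" not in doc:
        raise ConfigError("scenario document missing required field 'name'")
    dome_doc = doc.get("dome", {})
    _check_keys(dome_doc, {"radius", "layers", "resolution", "jitter", "seed"},
                "dome")
    return Scenario(
        name=doc["name"],
        dome=DomeSpec(**dome_doc),
        regions=[_region_from_dict(r) for r in doc.get("regions", [])],
        params={k: _params_from_dict(v, f"params[{k!r}]")
                for k, v in doc.get("params", {}).items()},
        events={int(k): v for k, v in doc.get("events", {}).items()},
        default_region=doc.get("default_region", "Pe"),
        dt=float(doc.get("dt", 1.0)),
        n_steps=int(doc.get("n_steps", 30)),
        growth_mode=doc.get("growth_mode", "material"),
    )


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: scenario YAML must be a mapping")
    return scenario_from_dict(doc)


def save_scenario(sc: Scenario, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(sc),
                                         sort_keys=False))


def solver_config_from_dict(doc: dict) -> SolverConfig:
    _check_keys(doc, {"eta", "force_tol", "max_iters", "cg_tol",
                      "cg_max_iters", "fd_probe"}, "solver")
    return SolverConfig(**doc)
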