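"""Declarative YAML configuration for simulation and analysis runs.

A config file has flat key-value blocks, one per component::

    geometry:            # lengths in um
      ostium_diameter: 7.0
      collar_length: 4.8
    kinematics:          # lengths um, frequency Hz
      amplitude: 1.0
      envelope_scale: 1.0
      vane_width_confined: 0.7
    solver:              # h um, back_pressure Pa
      h: 0.5
      phases_per_period: 8
    tracers:
      n_particles: 2000
      seed: 0
    synthetic:
      n_sponges: 10
      seed: 0

Unknown keys raise immediately (typos should not silently fall back to
defaults).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .geometry import ChamberGeometry
from .kinematics import BeatKinematics
from .solver import SolverConfig
from .synthetic import GeneratorConfig


_SECTIONS = {
    "geometry": ChamberGeometry,
    "kinematics": BeatKinematics,
    "solver": SolverConfig,
    "synthetic": GeneratorConfig,
}

_PROFILES = {
    # coarse test profile: minutes on one CPU for a full beat period
    "coarse": {"h": 1.0, "phases_per_period": 8},
    # standard profile used for the quantitative runs
    "standard": {"h": 0.625, "phases_per_period": 8},
    # fine profile for convergence checks
    "fine": {"h": 0.5, "phases_per_period": 8},
}


def _build(cls, values: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - names
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if "phase_offsets" in values and values["phase_offsets"] is not None:
        values["phase_offsets"] = tuple(values["phase_offsets"])
    if "beat_plane_azimuths" in values and values["beat_plane_azimuths"] is not None:
        values["beat_plane_azimuths"] = tuple(values["beat_plane_azimuths"])
    return cls(**values)


def load_config(path_or_dict) -> dict:
    """Parse a run config into component dataclasses.

    Returns a dict with keys geometry, kinematics, solver, synthetic,
    tracers (tracers stays a plain dict).  A top-level ``profile`` key
    (coarse/standard/fine) seeds the solver block.
    """
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict)
    profile = raw.pop("profile", None)
    out = {}
    solver_vals = dict(_PROFILES.get(profile, {}))
    for section, cls in _SECTIONS.items():
        vals = dict(raw.pop(section, {}) or {})
        if section == "solver":
            solver_vals.update(vals)
            vals = solver_vals
        out[section] = _build(cls, vals)
    out["tracers"] = dict(raw.pop("tracers", {}) or {})
    if raw:
        raise KeyError(f"unknown config sections: {sorted(raw)}")
    return out


def dump_config(components: dict, path) -> None:
    raw = {}
    for section in _SECTIONS:
        obj = components.get(section)
        if obj is not None:
            raw[section] = dataclasses.asdict(obj)
    if components.get("tracers"):
        raw["tracers"] = dict(components["tracers"])
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
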