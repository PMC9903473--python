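"""Run configuration: demonstrator defaults, YAML overrides, helpers.

A single nested-dict configuration drives every command.  The defaults
are the demonstrator's operating point: v_max = 120 mm/s, a = 100 mm/s**2
(derated to limit sloshing), 50 um line pitch, 25 um transfer tolerance,
0.04 s line-switch time.  A YAML file deep-merges over the defaults; the
CLI applies further per-flag overrides on top.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

from .kinematics import StageKinematics
from .plate import PlateLayout, Well, standard_six_well
from .targeting import SelectionRules

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "config_hash",
    "config_kinematics",
    "config_layout",
    "config_selection_rules",
]

DEFAULT_CONFIG: dict = {
    "stage": {
        "v_max_mm_s": 120.0,
        "accel_mm_s2": 100.0,
    },
    "plan": {
        "pitch_um": 50.0,
        "tolerance_um": 25.0,
        "t_switch_s": 0.04,
        "pause_s": 0.1,
        # None -> scan the usable-area length (120 mm); set e.g. 127.76
        # to sweep the full plate length instead
        "line_length_mm": None,
        "min_trigger_separation_um": 0.0,
    },
    "stopgo": {
        "move_model": "max",
        "pause_s": 1.0,
    },
    "sim": {
        "n_cells": [100, 1000, 10000, 100000],
        "pauses_s": [0.1, 1.0],
        "reps": 5,
        "base_seed": 1,
    },
    "select": {
        "min_size": None,
        "max_size": None,
        "min_roundness": None,
        "max_roundness": None,
        "min_colony_percent": None,
        "max_colony_percent": None,
    },
    "focus": {
        "grid_k": 3,
        "z_range_um": 16.0,
        "n_slices": 9,
        "noise": 0.2,
        "plane_um": [5.0, 0.3, -0.2],  # z = c0 + c1*x + c2*y (x, y mm)
    },
    "plate": None,  # optional custom layout (see config_layout)
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None) -> dict:
    """Defaults, optionally deep-merged with a YAML file."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = _deep_merge(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    """Short stable digest of a configuration, for log provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def config_kinematics(cfg: dict) -> StageKinematics:
    return StageKinematics(
        v_max=float(cfg["stage"]["v_max_mm_s"]),
        a=float(cfg["stage"]["accel_mm_s2"]),
    )


def config_layout(cfg: dict) -> PlateLayout:
    """The standard six-well layout, or a custom one from ``plate``.

    A custom layout specifies plate_width/plate_height/usable_origin/
    usable_size plus a ``wells`` list of [cx, cy, radius] (all mm).
    """
    plate = cfg.get("plate")
    if plate is None:
        return standard_six_well()
    return PlateLayout(
        plate_width=float(plate["plate_width"]),
        plate_height=float(plate["plate_height"]),
        usable_origin=tuple(plate["usable_origin"]),
        usable_size=tuple(plate["usable_size"]),
        wells=tuple(Well(*map(float, w)) for w in plate["wells"]),
    )


def config_selection_rules(cfg: dict) -> SelectionRules:
    s = cfg["select"]
    return SelectionRules(
        min_size=s.get("min_size"),
        max_size=s.get("max_size"),
        min_roundness=s.get("min_roundness"),
        max_roundness=s.get("max_roundness"),
        min_colony_percent=s.get("min_colony_percent"),
        max_colony_percent=s.get("max_colony_percent"),
    )
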