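"""Run configuration: schema-checked YAML with explicit defaults.

A config file holds up to five sections mirroring the library layers.
Unknown sections or keys are rejected outright — silent typos in an
analysis config are worse than a hard error.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "resolve_config", "config_hash"]

DEFAULTS: dict = {
    "model": {
        "D_in": 0.01,  # um^2/s
        "D_out": 0.1,  # um^2/s
        "R": 5.0,  # um
        "ell": None,  # um; None -> R/100
        "L": None,  # um; None -> 10 R
        "phi_in": 0.3,
        "P": 150.0,
    },
    "grid": {
        "n_cells": 80,
        "n_steps": 300,
        "d_interp": "resistive",
    },
    "pipeline": {
        "bin_width": 1.0,  # px
        "time_lag": 3,  # frames dropped from the stack (incl. prebleach)
        "exclusion_bins": 10,
        "sort": True,
        "sort_mode": "sort",
        "smooth_window": 5,
        "pixel_size": 0.1,  # um/px
        "background": 100.0,  # counts
        "prebleach_index": 0,
        "center": None,  # [x, y] px or None -> auto
    },
    "fit": {
        "din_bounds": [1e-5, 1e3],
        "dout_bounds": [1e-3, 1e3],
        "P_min": 5.0,
        "P_max": 5000.0,
        "P_points": 15,
        "forward": "sharp",
        "refine": True,
        "weights": "bin_counts",
        "per_frame": False,
    },
    "synthetic": {
        "seed": 7,
        "noise_sigma": 0.0,
        "psf_width": 0.0,
        "bleach_offset": 0.03,
        "shape": [128, 128],
        "n_frames": 40,
        "window_factor": 3.0,  # observation window in units of P R^2 / (3 D_out)
        "P_values": [5.0, 150.0],
        "D_out_values": [0.1, 1.0],
    },
    "geometry": {
        "box": [6.0, 6.0, 6.0],
        "spacing": 0.125,
        "centers": [[3.0, 3.0, 3.0]],
        "radii": [1.0],
        "bleached": [True],
        "coverslip": False,
        "n_steps": 120,
        "t_end": 300.0,
        "n_frames": 40,
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = {}
    for key, value in override.items():
        if key not in defaults:
            raise KeyError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, f"{path}{key}.")
        else:
            out[key] = value
    for key, value in defaults.items():
        out.setdefault(key, value)
    return out


def resolve_config(override: dict | None = None) -> dict:
    """Defaults overlaid with ``override``; unknown keys rejected."""
    return _merge(DEFAULTS, override or {})


def load_config(path: str | Path | None) -> dict:
    """Read a YAML config file and resolve it against the defaults."""
    if path is None:
        return resolve_config({})
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return resolve_config(data)


def config_hash(cfg: dict) -> str:
    """Short stable digest of a resolved config, for provenance headers."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
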