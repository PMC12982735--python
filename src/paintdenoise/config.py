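"""Run configuration: nested defaults, YAML loading, strict key checking."""

from __future__ import annotations

import copy
import hashlib
import json
from typing import Any, Mapping

import yaml

from .datatypes import ValidationError

DEFAULTS: dict[str, Any] = {
    "clustering": {
        "eps_nm": "auto",  # "auto" = median localization precision
        "min_pts": 5,
        "render_pixel_frac": 0.5,
        "peak_rel_threshold": 0.3,
        "peak_min_sep_frac": 1.0,
        "gaussian_render": False,
    },
    "kinetics": {
        "max_gap_s": 1.0,  # 2.0 for Halo-tagged targets
        "dark_time_convention": "gap",
    },
    "test": {
        "alpha": 0.01,
        "method": "bootstrap",
        "bootstrap_B": 10000,
        "min_times": 4,
        "seed": 0,
    },
    "denoise": {
        "min_events": 8,
        "cutoff": 1.0,
        "ratio_form": "excess",  # (r_s - r_b)/r_b; "ratio" = r_s/r_b
    },
    "io": {
        "column_map": {},
        "frame_duration_s": 0.2,
        "n_frames": None,
    },
}


def _merge(base: dict, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ValidationError(f"unknown config key {here!r}")
        if isinstance(base[key], dict) and key != "column_map":
            if not isinstance(val, Mapping):
                raise ValidationError(f"config key {here!r} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | None = None) -> dict[str, Any]:
    """Defaults deep-merged with a YAML file; unknown keys are rejected."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, Mapping):
        raise ValidationError("config file must contain a mapping")
    return _merge(DEFAULTS, user)


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable short hash of a config for run manifests."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
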