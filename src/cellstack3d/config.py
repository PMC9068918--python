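"""Experiment configuration: defaults, YAML loading and hashing."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

DEFAULT_CONFIG: dict[str, Any] = {
    "phantom": {
        "shape": [51, 51],
        "grid_period": 10,
        "octaves": 1,
        "persistence": 0.5,
        "threshold": 0.5,
        "snr_range": [2.0, 10.0],
        "background_mean_range": [50.0, 150.0],
        "cv": 0.15,
    },
    "optics": {
        "kind": "gaussian",
        "sigma0_px": 0.5,
        "slope_px_per_mm": 4.0,
        "truncation_radius_sigmas": 3.0,
        "separation_um": 1000.0,
        # documentation only (plot axes); never used in computation
        "pixel_pitch_um": 55.0,
    },
    "dataset": {"n_train": 20000, "n_test": 1000, "seed": 0},
    "train": {"epochs": 20, "batch_size": 32, "learning_rate": 1e-3, "seed": 0},
    "eval": {"threshold": 0.5},
    "output_dir": None,
}

FAST_PROFILE = {
    "dataset": {"n_train": 2000, "n_test": 200},
    "train": {"epochs": 12},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, fast: bool = False) -> dict:
    """Default config, optionally overridden by a YAML file and/or --fast."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if fast:
        cfg = _merge(cfg, FAST_PROFILE)
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def snapshot(cfg: dict, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "config_snapshot.yaml", "w") as fh:
        yaml.safe_dump({**cfg, "config_hash": config_hash(cfg)}, fh)
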