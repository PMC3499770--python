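"""Pipeline configuration: YAML/JSON loading with strict key validation.

Unknown keys anywhere in the file are rejected, and every stochastic stage
must carry an explicit seed, so a run is a pure function of (inputs, config).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    pass


_SCHEMA: dict[str, dict[str, Any]] = {
    "io": {
        "tables": list,
        "control_id": str,
        "scale": str,
        "gene_sets": str,
        "gene_sets_min_size": int,
    },
    "filter": {
        "enabled": bool,
        "fc_threshold": (int, float),
        "min_fc_timepoints": int,
        "cv_threshold": (int, float),
        "cv_scope": str,
    },
    "table_norm": {"method": str},
    "statis": {
        "mode": str,
        "n_components": int,
        "weight_norm": str,
        "sign_convention": str,
    },
    "bootstrap": {
        "enabled": bool,
        "B": int,
        "seed": int,
        "basis": str,
        "alpha_level": (int, float),
        "components_for_union": list,
    },
    "enrichment": {
        "enabled": bool,
        "fdr_cutoff": (int, float),
        "min_set_size": int,
        "background": str,
        "background_list": list,
    },
    "simulate": {
        "n_genes": int,
        "n_timepoints": int,
        "beta": (int, float),
        "sigma": (int, float),
        "seed": int,
        "outlier": (str, type(None)),
        "n_decoys": int,
        "decoy_seed": int,
    },
    "alt_normalization": None,  # top-level boolean
}

DEFAULTS: dict[str, Any] = {
    "io": {"scale": "log2", "gene_sets": None, "gene_sets_min_size": 3},
    "filter": {
        "enabled": True,
        "fc_threshold": 2.0,
        "min_fc_timepoints": 2,
        "cv_threshold": 1.0,
        "cv_scope": "per_condition",
    },
    "table_norm": {"method": "table_scale"},
    "statis": {"mode": "rows", "n_components": 3, "weight_norm": "sum1",
               "sign_convention": "largest_abs_positive"},
    "bootstrap": {
        "enabled": True,
        "B": 1000,
        "basis": "factor_scores",
        "alpha_level": 0.01,
        "components_for_union": [1, 2],
    },
    "enrichment": {
        "enabled": True,
        "fdr_cutoff": 0.01,
        "min_set_size": 3,
        "background": "filtered",
    },
    "simulate": {
        "n_genes": 500,
        "n_timepoints": 23,
        "beta": 2.0,
        "sigma": 0.5,
        "outlier": None,
        "n_decoys": 5,
    },
    "alt_normalization": False,
}


def _merge_block(name: str, user: dict[str, Any]) -> dict[str, Any]:
    schema = _SCHEMA[name]
    merged = dict(DEFAULTS.get(name, {}))
    for key, value in user.items():
        if key not in schema:
            raise ConfigError(f"unknown key {key!r} in config block {name!r}")
        expected = schema[key]
        if value is not None and not isinstance(value, expected):
            raise ConfigError(
                f"config {name}.{key}: expected {expected}, got {type(value).__name__}"
            )
        merged[key] = value
    return merged


def validate_config(raw: dict[str, Any]) -> dict[str, Any]:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cfg: dict[str, Any] = {}
    for key, block in raw.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown top-level config key {key!r}")
        if key == "alt_normalization":
            if not isinstance(block, bool):
                raise ConfigError("alt_normalization must be a boolean")
            cfg[key] = block
        else:
            if not isinstance(block, dict):
                raise ConfigError(f"config block {key!r} must be a mapping")
            cfg[key] = _merge_block(key, block)
    for name in _SCHEMA:
        cfg.setdefault(
            name,
            DEFAULTS[name] if not isinstance(DEFAULTS.get(name), dict) else dict(DEFAULTS[name]),
        )
    if (
        "bootstrap" in raw
        and cfg["bootstrap"].get("enabled", True)
        and "seed" not in cfg["bootstrap"]
    ):
        raise ConfigError("bootstrap.seed is required when the bootstrap is enabled")
    return cfg


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def config_hash(cfg: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
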