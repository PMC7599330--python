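"""JSON run configuration: schemas per subcommand, validation, round-trip."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger("dx2quant")

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "SCHEMAS"]


class ConfigError(ValueError):
    pass


# key -> default; ``REQUIRED`` marks keys that must be present
REQUIRED = object()

SCHEMAS: dict[str, dict[str, object]] = {
    "simulate-images": {
        "outdir": REQUIRED,
        "n_fields": 1,
        "seed": 0,
        "width": 512,
        "height": 512,
        "n_cells": 12,
        "nucleus_radius": [12.0, 18.0],
        "mean_red_foci_per_cell": 8.0,
        "mean_green_foci_per_cell": 4.0,
        "spot_sigma": 1.5,
        "spot_amplitude": 600.0,
        "nucleus_intensity": 400.0,
        "background_level": 100.0,
        "noise_sd": 5.0,
        "poisson_noise": False,
    },
    "quant-images": {
        "indir": REQUIRED,
        "out": REQUIRED,
        "threshold": "otsu",
        "min_size_foci": 4,
        "min_size_nucleus": 200,
        "mode": "total_area",
        "per_cell": True,
    },
    "simulate-reads": {
        "out": REQUIRED,
        "n_full": 0,
        "n_skip": 0,
        "n_other": 0,
        "n_unspliced": 0,
        "read_len": 75,
        "seed": 0,
        "model": None,
    },
    "quant-junctions": {
        "sam": REQUIRED,
        "out": REQUIRED,
        "min_mapq": 0,
        "tolerance": 0,
        "model": None,
    },
    "cohort": {
        "table": REQUIRED,
        "out": REQUIRED,
        "endpoint": "os",
        "stratify": "column:dx2_positive",
        "adjust": [],
    },
    "geneset": {
        "expr": REQUIRED,
        "groups": REQUIRED,
        "gmt": REQUIRED,
        "out": REQUIRED,
        "min_set_size": 5,
    },
}


@dataclass(frozen=True)
class RunConfig:
    """A validated subcommand configuration with defaults filled in."""

    subcommand: str
    params: dict = field(default_factory=dict)
    default_keys: tuple[str, ...] = field(default=(), compare=False)  # provenance

    def __getitem__(self, key: str):
        return self.params[key]


def validate(subcommand: str, params: dict) -> RunConfig:
    """Validate keys against the subcommand schema and fill defaults."""
    if subcommand not in SCHEMAS:
        raise ConfigError(
            f"unknown subcommand {subcommand!r}; expected one of "
            f"{sorted(SCHEMAS)}"
        )
    schema = SCHEMAS[subcommand]
    unknown = sorted(set(params) - set(schema))
    if unknown:
        raise ConfigError(f"unknown config keys for {subcommand!r}: {unknown}")
    missing = sorted(
        k for k, v in schema.items() if v is REQUIRED and k not in params
    )
    if missing:
        raise ConfigError(f"missing required config keys for {subcommand!r}: {missing}")
    filled = dict(params)
    defaults = []
    for key, default in schema.items():
        if key not in filled:
            filled[key] = default
            defaults.append(key)
            log.debug("config default applied: %s = %r", key, default)
    return RunConfig(subcommand=subcommand, params=filled, default_keys=tuple(defaults))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON config ({"subcommand": ..., key: value, ...})."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict) or "subcommand" not in raw:
        raise ConfigError(f"{path}: config must be an object with a 'subcommand' key")
    sub = raw.pop("subcommand")
    cfg = validate(sub, raw)
    for key in cfg.default_keys:
        log.info("config %s: default %s = %r", path, key, cfg.params[key])
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config so that load_config round-trips losslessly."""
    with open(path, "w") as fh:
        json.dump({"subcommand": cfg.subcommand, **cfg.params}, fh, indent=2, sort_keys=True)
        fh.write("\n")
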