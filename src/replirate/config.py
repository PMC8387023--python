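"""YAML run configuration: schema checking and provenance echo.

One flat mapping per run. Unknown keys are rejected (naming the offending
key); numeric ranges are enforced by the parameter dataclasses the values
feed into. Stochastic subcommands require a seed, either in the config or
as a command-line flag (flags override config values).
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .errors import ValidationError
from .simulate import GelSimParams, QpcrNoiseModel, UnwindingParams

_UNWINDING_KEYS = (
    {f.name for f in fields(UnwindingParams)}
    | {f.name for f in fields(QpcrNoiseModel)}
    | {"replicates", "condition"}
)
_GEL_KEYS = {f.name for f in fields(GelSimParams)}
_PULSE_CHASE_KEYS = {
    "chase_rates",
    "pulse_rate",
    "pulse_duration",
    "pulse_length_cv",
    "chase_timepoints",
    "n_molecules",
    "seed",
    "gel",
}
_ANALYZE_UNWINDING_KEYS = {
    "sites_used",
    "reference_site",
    "control_label",
    "anchor_zero",
    "B",
    "seed",
}
_ANALYZE_GEL_KEYS = {"span", "threshold", "through_origin"}

SCHEMAS: dict[str, set[str]] = {
    "simulate-unwinding": _UNWINDING_KEYS,
    "simulate-gel": _GEL_KEYS,
    "simulate-pulse-chase": _PULSE_CHASE_KEYS,
    "analyze-unwinding": _ANALYZE_UNWINDING_KEYS,
    "analyze-gel": _ANALYZE_GEL_KEYS,
}


def load_config(path: str | Path, subcommand: str) -> dict:
    """Load and schema-check the YAML config for ``subcommand``."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ValidationError(f"config {path} does not parse as YAML: {exc}") from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    schema = SCHEMAS.get(subcommand)
    if schema is None:
        raise ValidationError(f"unknown subcommand {subcommand!r}")
    unknown = set(cfg) - schema
    if unknown:
        raise ValidationError(
            f"config {path}: unknown key {sorted(unknown)[0]!r} for {subcommand}"
        )
    if subcommand == "simulate-pulse-chase" and "gel" in cfg:
        gel = cfg["gel"]
        if not isinstance(gel, dict):
            raise ValidationError("config key 'gel' must be a mapping")
        unknown = set(gel) - _GEL_KEYS
        if unknown:
            raise ValidationError(
                f"config key 'gel': unknown key {sorted(unknown)[0]!r}"
            )
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    """Echo the resolved configuration (provenance record)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def require_seed(cfg: dict, cli_seed: int | None) -> int:
    """Resolve the mandatory seed for a stochastic subcommand."""
    if cli_seed is not None:
        return int(cli_seed)
    if "seed" in cfg and cfg["seed"] is not None:
        return int(cfg["seed"])
    raise ValidationError("seed is required: set 'seed' in the config or pass --seed")
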