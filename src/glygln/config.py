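"""Structured text (YAML/JSON) configuration for parameters and scenarios.

Keys follow the model's own symbol names (``kf_Glc``, ``kr_3``,
``Capacity_M``, ``Oligomycin``, ``2DG``, ...).  Loading is strict: unknown
or missing keys raise a :class:`ConfigError` naming every offender, and
every file carries an explicit ``units`` block because the model's time
unit (minutes) is a modelling commitment, not a convention.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .model import RATE_CONSTANT_NAMES, RateConstants
from .simulate import Scenario

__all__ = [
    "ConfigError",
    "load_rate_constants",
    "save_rate_constants",
    "load_scenario",
    "save_scenario",
    "DEFAULT_UNITS",
]

DEFAULT_UNITS: dict[str, str] = {
    "time": "minute",
    "rate_constants": "per_minute",
    "concentrations": "model_units_nominally_uM",
}

#: Scenario config keys -> Scenario dataclass fields.
_SCENARIO_KEYS: dict[str, str] = {
    "Glc_ex": "glc_ex",
    "Gln_ex": "gln_ex",
    "Oligomycin": "dose_oligomycin",
    "2DG": "dose_2DG",
    "Capacity_Glc": "capacity_glc",
    "Capacity_Gln": "capacity_gln",
    "Capacity_M": "capacity_m",
    "horizon_min": "horizon",
    "n_samples": "n_samples",
    "sample_interval_min": "sample_interval",
    "clamp_modulator_factors": "clamp_modulator_factors",
}

_OPTIONAL_RATE_KEYS = frozenset(
    f.name for f in dataclasses.fields(RateConstants)
    if f.default is not dataclasses.MISSING
)
_OPTIONAL_SCENARIO_KEYS = frozenset(_SCENARIO_KEYS)  # Scenario has full defaults


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


def _read_structured(path: str | Path) -> Any:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _check_keys(
    mapping: Mapping[str, Any],
    known: frozenset[str] | set[str],
    optional: frozenset[str] | set[str],
    where: str,
) -> None:
    unknown = sorted(set(mapping) - set(known))
    missing = sorted(set(known) - set(optional) - set(mapping))
    problems = []
    if unknown:
        problems.append(f"unknown keys {unknown}")
    if missing:
        problems.append(f"missing keys {missing}")
    if problems:
        raise ConfigError(f"{where}: " + "; ".join(problems))


def load_rate_constants(path: str | Path) -> RateConstants:
    """Load a rate-constant set; expects a top-level ``rate_constants`` block
    (a bare mapping of constants is also accepted)."""
    doc = _read_structured(path)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    block = doc.get("rate_constants", doc)
    if not isinstance(block, Mapping):
        raise ConfigError(f"{path}: 'rate_constants' must be a mapping")
    _check_keys(
        block, set(RATE_CONSTANT_NAMES), _OPTIONAL_RATE_KEYS, f"{path} rate_constants"
    )
    try:
        return RateConstants(**{k: float(v) for k, v in block.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_rate_constants(k: RateConstants, path: str | Path) -> None:
    path = Path(path)
    doc = {"units": dict(DEFAULT_UNITS), "rate_constants": k.to_mapping()}
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario; expects a top-level ``scenario`` block (a bare
    mapping is also accepted)."""
    doc = _read_structured(path)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    block = doc.get("scenario", doc)
    if not isinstance(block, Mapping):
        raise ConfigError(f"{path}: 'scenario' must be a mapping")
    _check_keys(block, set(_SCENARIO_KEYS), _OPTIONAL_SCENARIO_KEYS, f"{path} scenario")
    kwargs: dict[str, Any] = {}
    for key, value in block.items():
        field = _SCENARIO_KEYS[key]
        if field == "n_samples":
            kwargs[field] = int(value)
        elif field == "clamp_modulator_factors":
            kwargs[field] = bool(value)
        else:
            kwargs[field] = float(value)
    try:
        return Scenario(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    path = Path(path)
    block = {
        key: getattr(scenario, field) for key, field in _SCENARIO_KEYS.items()
    }
    doc = {
        "units": {k: v for k, v in DEFAULT_UNITS.items() if k != "rate_constants"},
        "scenario": block,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
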