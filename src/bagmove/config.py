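"""Run configuration: defaults, JSON loading, validation and overrides.

A flat two-level schema mirrors every config-exposed parameter of the
modelling pipeline. Unknown keys are rejected and constraint violations name
the offending key path, so a typo in a config file fails loudly rather than
silently falling back to a default.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

__all__ = ["RunConfig", "load_config", "DEFAULTS"]


DEFAULTS: dict[str, dict[str, Any]] = {
    "learner": {"kind": "knn", "k": 5, "k_grid": None},
    "ensemble": {"B": 100},
    "bootstrap": {"scheme": "iid", "n_blocks": None},
    "interval": {"level": 0.95},
    "grid": {"step": 1.0},
    "derived": {"point": "mean_path"},
    "rng": {"seed": None},
}

_VALIDATORS = {
    "learner.kind": lambda v: v in ("knn", "weighted_knn"),
    "learner.k": lambda v: isinstance(v, int) and v >= 1,
    "learner.k_grid": lambda v: v is None
    or (isinstance(v, (list, tuple)) and len(v) > 0 and all(isinstance(k, int) and k >= 1 for k in v)),
    "ensemble.B": lambda v: isinstance(v, int) and v >= 1,
    "bootstrap.scheme": lambda v: v in ("iid", "blocked"),
    "bootstrap.n_blocks": lambda v: v is None or (isinstance(v, int) and v >= 1),
    "interval.level": lambda v: isinstance(v, (int, float)) and 0 < v < 1,
    "grid.step": lambda v: isinstance(v, (int, float)) and v > 0,
    "derived.point": lambda v: v in ("mean_path", "ensemble_median"),
    "rng.seed": lambda v: v is None or isinstance(v, int),
}


class ConfigError(ValueError):
    """Invalid configuration: unknown key, type mismatch or constraint."""


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully-materialized run configuration."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, dotted: str) -> Any:
        section, key = dotted.split(".", 1)
        return self.values[section][key]

    def to_json(self) -> str:
        return json.dumps(self.values, sort_keys=True, indent=1)

    def digest(self) -> str:
        """Short stable hash of the effective configuration."""
        return hashlib.sha256(
            json.dumps(self.values, sort_keys=True).encode()
        ).hexdigest()[:12]


def _merge(effective: dict, updates: dict, source: str) -> None:
    for section, entries in updates.items():
        if section not in effective:
            raise ConfigError(f"unknown config section {section!r} ({source})")
        if not isinstance(entries, dict):
            raise ConfigError(f"section {section!r} must be a mapping ({source})")
        for key, value in entries.items():
            if key not in effective[section]:
                raise ConfigError(f"unknown config key '{section}.{key}' ({source})")
            effective[section][key] = value


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load configuration with precedence defaults < file < overrides.

    ``overrides`` uses dotted keys (e.g. ``{"ensemble.B": 50}``), matching
    command-line flags.
    """
    effective = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            text = fh.read().strip()
        data = json.loads(text) if text else {}
        _merge(effective, data, source=str(path))
    for dotted, value in (overrides or {}).items():
        if "." not in dotted:
            raise ConfigError(f"override key {dotted!r} must be section.key")
        section, key = dotted.split(".", 1)
        _merge(effective, {section: {key: value}}, source="override")
    for dotted, check in _VALIDATORS.items():
        section, key = dotted.split(".", 1)
        value = effective[section][key]
        if isinstance(value, bool) or not check(value):
            raise ConfigError(f"invalid value {value!r} for {dotted}")
    return RunConfig(effective)
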