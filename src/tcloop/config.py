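"""Run configuration: YAML/JSON loading with eager validation.

A config file has a ``params`` block (any subset of tau, m1, m2, e, e0,
p, a, variant — omitted keys take the nominal defaults) plus optional
per-command blocks and run-level settings.  Unknown keys are rejected
by name so typos never silently fall back to defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kinetics import ModelParams

__all__ = ["RunConfig", "ConfigError", "load_config", "params_from_dict"]

_PARAM_KEYS = {"tau", "m1", "m2", "e", "e0", "p", "a", "variant"}
_TOP_KEYS = {"params", "simulate", "equilibria", "bifurcation", "basins",
             "outdir", "seed", "log_level"}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    params: ModelParams = field(default_factory=ModelParams)
    simulate: dict = field(default_factory=dict)
    equilibria: dict = field(default_factory=dict)
    bifurcation: dict = field(default_factory=dict)
    basins: dict = field(default_factory=dict)
    outdir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "simulate": dict(self.simulate),
            "equilibria": dict(self.equilibria),
            "bifurcation": dict(self.bifurcation),
            "basins": dict(self.basins),
            "outdir": self.outdir,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def params_from_dict(d: dict) -> ModelParams:
    unknown = set(d) - _PARAM_KEYS
    if unknown:
        raise ConfigError(
            f"unknown parameter key(s) {sorted(unknown)}; "
            f"expected a subset of {sorted(_PARAM_KEYS)}"
        )
    try:
        return ModelParams(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid parameters: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(unknown)}; "
            f"expected a subset of {sorted(_TOP_KEYS)}"
        )
    params = params_from_dict(raw.get("params", {}) or {})
    cfg = RunConfig(
        params=params,
        simulate=raw.get("simulate", {}) or {},
        equilibria=raw.get("equilibria", {}) or {},
        bifurcation=raw.get("bifurcation", {}) or {},
        basins=raw.get("basins", {}) or {},
        outdir=str(raw.get("outdir", ".")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    return cfg
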