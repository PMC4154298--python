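"""Run configuration: schema, validation and YAML/JSON round-tripping.

A :class:`RunConfig` fully determines one pipeline run (command,
model parameters, protocol or pulse design, noise, seed, output
directory). Configs are plain mappings on disk — YAML, with JSON
accepted since YAML is a superset — and unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .exceptions import ConfigError, ValidationError
from .model import RateParameters
from .protocols import Protocol, PulseChaseDesign, condition_from_name
from .synthetic import NoiseModel, paper_like_params

__all__ = ["RunConfig", "parse_config", "serialize_config", "COMMANDS"]

COMMANDS = ("simulate", "pulsechase", "fit-neutral", "fit-switch", "synth", "stochastic")

#: Commands whose output is random and therefore require an explicit seed.
_STOCHASTIC_COMMANDS = ("synth", "stochastic")

_DEFAULT_PARAMETERS = paper_like_params().to_dict()
_DEFAULT_DESIGN = {
    "total_duration": 6.0,
    "pulse_duration": 1.0,
    "pulse_start_days": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
    "pulse_condition": "AC",
    "base_condition": "N2B27",
}
_DEFAULT_NOISE = {"n_sampled": 10_000, "eps_fp": 0.01, "eps_fn": 0.01}
_DEFAULT_FIT = {
    "n_starts": 20,
    "rate_bounds": [1e-4, 10.0],
    "theta_bounds": [0.01, 0.99],
    "weighting": "none",
}


@dataclass(frozen=True, eq=True)
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    command: str
    parameters: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PARAMETERS))
    signal_law: str = "instantaneous"
    protocol: tuple[tuple[str, float], ...] = (("N2B27", 6.0),)
    design: dict = field(default_factory=lambda: dict(_DEFAULT_DESIGN))
    noise: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    days: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    synth_kind: str = "neutral"
    n_cells: int = 10_000
    dt: float = 0.02
    fit: dict = field(default_factory=lambda: dict(_DEFAULT_FIT))
    dataset: str | None = None
    fixed: dict = field(default_factory=dict)
    seed: int | None = None  # stochastic commands require one explicitly
    out_dir: str = "fatekinetics_run"
    log_level: str = "INFO"

    # -- constructed domain objects -------------------------------------
    def rate_parameters(self) -> RateParameters:
        try:
            return RateParameters(**self.parameters)
        except (TypeError, ValidationError) as exc:
            raise ConfigError(f"invalid 'parameters' block: {exc}") from exc

    def protocol_object(self) -> Protocol:
        try:
            return Protocol(
                [(days, condition_from_name(name)) for name, days in self.protocol]
            )
        except (ValidationError, KeyError) as exc:
            raise ConfigError(f"invalid 'protocol' block: {exc}") from exc

    def design_object(self) -> PulseChaseDesign:
        block = dict(self.design)
        try:
            return PulseChaseDesign(
                total_duration=block["total_duration"],
                pulse_duration=block["pulse_duration"],
                pulse_start_days=tuple(block["pulse_start_days"]),
                pulse_condition=condition_from_name(block["pulse_condition"]),
                base_condition=condition_from_name(block["base_condition"]),
            )
        except (ValidationError, KeyError) as exc:
            raise ConfigError(f"invalid 'design' block: {exc}") from exc

    def noise_object(self) -> NoiseModel:
        if self.seed is None:
            raise ConfigError("noise model needs a seed")
        try:
            return NoiseModel(seed=self.seed, **self.noise)
        except (TypeError, ValidationError) as exc:
            raise ConfigError(f"invalid 'noise' block: {exc}") from exc


def _check_unknown(block: Mapping, allowed: set[str], context: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")


def _normalize(raw: Mapping[str, Any]) -> RunConfig:
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    _check_unknown(raw, allowed, "config")
    data: dict[str, Any] = dict(raw)

    command = data.get("command")
    if command not in COMMANDS:
        raise ConfigError(f"'command' must be one of {COMMANDS}, got {command!r}")

    if "parameters" in data:
        _check_unknown(
            data["parameters"],
            {"lambda_D", "lambda_N", "lambda_M_low", "lambda_M_high", "theta"},
            "'parameters'",
        )
        merged = dict(_DEFAULT_PARAMETERS)
        merged.update({k: float(v) for k, v in data["parameters"].items()})
        data["parameters"] = merged
    if "noise" in data:
        _check_unknown(data["noise"], set(_DEFAULT_NOISE), "'noise'")
        merged = dict(_DEFAULT_NOISE)
        merged.update(data["noise"])
        data["noise"] = merged
    if "design" in data:
        _check_unknown(data["design"], set(_DEFAULT_DESIGN), "'design'")
        merged = dict(_DEFAULT_DESIGN)
        merged.update(data["design"])
        merged["pulse_start_days"] = [float(v) for v in merged["pulse_start_days"]]
        data["design"] = merged
    if "fit" in data:
        _check_unknown(data["fit"], set(_DEFAULT_FIT), "'fit'")
        merged = dict(_DEFAULT_FIT)
        merged.update(data["fit"])
        data["fit"] = merged
    if "protocol" in data:
        try:
            data["protocol"] = tuple(
                (str(seg["condition"]), float(seg["days"])) for seg in data["protocol"]
            )
        except (TypeError, KeyError) as exc:
            raise ConfigError(
                "'protocol' must be a list of {condition, days} mappings"
            ) from exc
    if "days" in data:
        data["days"] = tuple(float(d) for d in data["days"])
    if data.get("synth_kind", "neutral") not in ("neutral", "pulse_chase"):
        raise ConfigError("'synth_kind' must be 'neutral' or 'pulse_chase'")
    if "seed" in data and data["seed"] is not None:
        data["seed"] = int(data["seed"])

    config = RunConfig(**data)

    if config.command in _STOCHASTIC_COMMANDS and config.seed is None:
        raise ConfigError(f"command {config.command!r} requires an explicit 'seed'")
    # Force construction now so schema errors surface at parse time.
    config.rate_parameters()
    if config.command in ("simulate", "fit-neutral", "stochastic"):
        config.protocol_object()
    if config.command in ("pulsechase", "fit-switch") or config.synth_kind == "pulse_chase":
        config.design_object()
    if config.command == "synth":
        config.noise_object()
    if config.command == "fit-switch":
        for key in ("lambda_D", "lambda_N"):
            if key not in config.fixed:
                raise ConfigError(f"command 'fit-switch' requires fixed.{key}")
    if config.command in ("fit-neutral", "fit-switch") and not config.dataset:
        raise ConfigError(f"command {config.command!r} requires a 'dataset' CSV path")
    return config


def parse_config(
    path: str | Path | None = None, **overrides: Any
) -> RunConfig:
    """Load and validate a run configuration.

    ``path`` points to a YAML (or JSON) mapping; ``overrides`` are
    applied on top (None values ignored), so CLI flags win over the
    file. Unknown keys anywhere raise :class:`ConfigError` naming the
    offending key.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping at top level")
        raw.update(loaded)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return _normalize(raw)


def serialize_config(config: RunConfig) -> dict[str, Any]:
    """Plain-mapping form of a config; parse_config inverts it."""
    out = dataclasses.asdict(config)
    out["protocol"] = [
        {"condition": name, "days": days} for name, days in config.protocol
    ]
    out["days"] = list(config.days)
    return out
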