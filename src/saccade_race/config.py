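"""Run configuration: a single YAML file, strictly validated.

Unknown keys are rejected by name; parameter overrides must be NetworkParams
fields; the loaded configuration round-trips losslessly through
:func:`save_config` / :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List

import yaml

from .exceptions import ConfigError, ParameterError
from .experiment import ConditionSpec, condition_by_name
from .network import NetworkParams

_PARAM_FIELDS = {f.name for f in dataclasses.fields(NetworkParams)}


@dataclasses.dataclass
class RunConfig:
    condition: str = "control"
    overrides: Dict[str, object] = dataclasses.field(default_factory=dict)
    ntrials: int = 5000
    master_seed: int = 12345
    delays: List[float] = dataclasses.field(default_factory=lambda: [0.0, 10.0, 30.0, 50.0])
    out_dir: str = "results"
    verbosity: int = 0

    def to_condition(self) -> ConditionSpec:
        return condition_by_name(self.condition, **self.overrides)

    def resolve_params(self) -> NetworkParams:
        return self.to_condition().resolve()


_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def _validate(cfg: RunConfig) -> RunConfig:
    unknown = set(cfg.overrides) - _PARAM_FIELDS
    if unknown:
        raise ConfigError(f"unknown parameter override(s): {sorted(unknown)}")
    if cfg.ntrials < 1:
        raise ConfigError(f"ntrials must be >= 1, got {cfg.ntrials}")
    try:
        params = cfg.resolve_params()
    except ParameterError as exc:
        raise ConfigError(f"invalid parameters: {exc}") from exc
    # config files must describe a working antisaccade setup: the planned
    # input has to dominate the reactive one.
    if params.input_planned <= params.input_reactive:
        raise ConfigError(
            f"input_planned ({params.input_planned}) must exceed "
            f"input_reactive ({params.input_reactive})"
        )
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the full defaults (control condition, 5000 trials).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**raw)
    return _validate(cfg)


def save_config(cfg: RunConfig, path) -> None:
    _validate(cfg)
    data = dataclasses.asdict(cfg)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
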