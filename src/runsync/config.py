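"""YAML experiment configuration for the command-line interface.

Schema (all keys optional; defaults reproduce the six-condition initial
experiment with 36 participants)::

    experiment:
      n_participants: 36
      seed: 0
      randomize_order: true
      conditions:
        - {strategy: S0}
        - {strategy: S1}
        - {strategy: S2}
        - {strategy: S3, target_phase_deg: -70}
        - {strategy: S4, target_phase_deg: -70}
        - {strategy: S5, target_phase_deg: -70}
      protocol: {silence_duration: 25, n_songs: 5, song_duration: 55}
      population: {}   # overrides of runner.DEFAULT_POPULATION entries
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import yaml

from .exceptions import ConfigurationError
from .session import ExperimentDesign, Protocol, default_conditions
from .strategies import StrategyConfig

__all__ = ["load_design", "design_from_mapping", "default_config_yaml"]

_STRATEGY_KEYS = {
    "target_phase_deg",
    "tempo_offset_bpm",
    "cadence_window",
    "osc_gain_phase",
    "osc_gain_freq",
    "max_step_shift",
}


def design_from_mapping(config: Mapping) -> ExperimentDesign:
    """Build an :class:`ExperimentDesign` from a parsed configuration."""
    exp = dict(config.get("experiment", config) or {})
    conditions = exp.get("conditions")
    if conditions is None:
        parsed = default_conditions()
    else:
        parsed = []
        for entry in conditions:
            entry = dict(entry)
            sid = entry.pop("strategy", None)
            if sid is None:
                raise ConfigurationError(f"condition missing 'strategy': {entry}")
            unknown = set(entry) - _STRATEGY_KEYS
            if unknown:
                raise ConfigurationError(f"unknown strategy keys: {sorted(unknown)}")
            parsed.append(StrategyConfig(strategy_id=sid, **entry))
    protocol = Protocol(**(exp.get("protocol") or {}))
    return ExperimentDesign(
        n_participants=int(exp.get("n_participants", 36)),
        conditions=parsed,
        master_seed=int(exp.get("seed", 0)),
        population=exp.get("population") or None,
        protocol=protocol,
        randomize_order=bool(exp.get("randomize_order", True)),
    )


def load_design(path: str | Path) -> ExperimentDesign:
    """Load an experiment design from a YAML file."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, Mapping):
        raise ConfigurationError("configuration root must be a mapping")
    return design_from_mapping(config)


def default_config_yaml() -> str:
    """The default configuration, as a YAML document."""
    return __doc__.split("::", 1)[1].replace("\n    ", "\n").strip() + "\n"
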