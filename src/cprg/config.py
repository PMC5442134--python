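"""Configuration loading, validation, fixtures and output serialization.

A run is fully described by one YAML (or JSON) file with four optional
sections — ``game``, ``agent``, ``reward``, ``experiment`` — whose keys
map one-to-one onto :class:`~cprg.dynamics.GameParams`,
:class:`~cprg.learning.LearnerConfig`, :class:`~cprg.learning.RewardSpec`
and :class:`~cprg.engine.ExperimentSpec`.  Unknown keys are rejected so a
typo in a parameter name cannot silently fall back to a default.  An
empty file reproduces the reference parameterization exactly.

All floating-point output is written with 10 significant digits; every
run emits a JSON manifest (config echo, seed, row counts) so results can
be traced back to their exact inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dynamics import GameParams
from .engine import ExperimentSpec, SimulationResult
from .learning import LearnerConfig, RewardSpec

__all__ = ["RunConfig", "load_config", "config_from_dict", "make_fixture", "write_outputs"]

_SECTION_TYPES = {
    "game": GameParams,
    "agent": LearnerConfig,
    "reward": RewardSpec,
    "experiment": ExperimentSpec,
}
_TOP_LEVEL_KEYS = set(_SECTION_TYPES) | {"output_dir", "log_level"}

# list-valued ExperimentSpec fields arrive as YAML lists; stored as tuples
_TUPLE_FIELDS = {"n_sweep", "cost_values", "weight_values"}


@dataclass(frozen=True)
class RunConfig:
    """A fully validated run configuration."""

    game: GameParams = field(default_factory=GameParams)
    agent: LearnerConfig = field(default_factory=LearnerConfig)
    reward: RewardSpec = field(default_factory=RewardSpec)
    experiment: ExperimentSpec = field(default_factory=ExperimentSpec)
    output_dir: str = "cprg_out"
    log_level: str = "info"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in _TUPLE_FIELDS:
            d["experiment"][k] = list(d["experiment"][k])
        return d


def _build_section(name: str, cls, data: dict):
    if not isinstance(data, dict):
        raise ValueError(f"section '{name}' must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in section '{name}': {sorted(unknown)}; "
            f"valid keys: {sorted(known)}"
        )
    kwargs = dict(data)
    for k in _TUPLE_FIELDS & set(kwargs):
        kwargs[k] = tuple(kwargs[k])
    try:
        return cls(**kwargs)
    except ValueError as e:
        raise ValueError(f"invalid value in section '{name}': {e}") from e


def config_from_dict(data: dict | None) -> RunConfig:
    """Validate a nested dict (parsed YAML/JSON) into a :class:`RunConfig`."""
    data = data or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _TOP_LEVEL_KEYS
    if unknown:
        raise ValueError(
            f"unknown top-level key(s): {sorted(unknown)}; "
            f"valid keys: {sorted(_TOP_LEVEL_KEYS)}"
        )
    sections = {
        name: _build_section(name, cls, data.get(name, {}))
        for name, cls in _SECTION_TYPES.items()
    }
    return RunConfig(
        **sections,
        output_dir=str(data.get("output_dir", "cprg_out")),
        log_level=str(data.get("log_level", "info")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON config file.

    An empty file (or one with only some sections) is valid: omitted keys
    take the reference defaults.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as e:
        raise ValueError(f"cannot read config file {path}: {e}") from e
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ValueError(f"cannot parse config file {path}: {e}") from e
    return config_from_dict(data)


_FIXTURES = {
    # reference parameterization, full experiment scale
    "default": {},
    # cheap effort: almost any action is profitable, sustainability is the
    # only brake -> over-harvesting regime
    "low_cost": {"game": {"c": 0.2}},
    # dear effort: the viable region shrinks to a sliver -> loss regime
    "high_cost": {"game": {"c": 0.8}},
    # group-size sweep at equal reward weighting
    "group_sweep": {"reward": {"w": 0.5}},
    # full cost x weight grid at the reference group size
    "cost_weight_grid": {"experiment": {"n_agents": 10}},
    # tiny end-to-end run that exercises every module in seconds
    "smoke": {
        "experiment": {
            "n_agents": 3,
            "rounds": 200,
            "replicates": 3,
            "late_window": 50,
            "n_sweep": [1, 2, 3],
            "cost_values": [0.2, 0.5, 0.8],
            "weight_values": [0.3, 0.5, 0.7],
        }
    },
}


def make_fixture(name: str) -> RunConfig:
    """Ready-to-run config for a named scenario.

    ``default`` (reference parameters), ``low_cost`` (c = 0.2),
    ``high_cost`` (c = 0.8), ``group_sweep``, ``cost_weight_grid``, and
    ``smoke`` (3 agents, 200 rounds, 3 replicates — seconds to run).
    """
    try:
        overrides = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return config_from_dict(overrides)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_outputs(result: SimulationResult, config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Write timeseries.csv, agents.csv, summary.csv and manifest.json.

    Floats are serialized with 10 significant digits, enough for the
    round-trip of every trajectory value at printed precision.  Returns
    the manifest dict.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        result.trajectories.to_csv(out / "timeseries.csv", index=False, float_format="%.10g")
        result.agent_trajectories.to_csv(out / "agents.csv", index=False, float_format="%.10g")
        summary_df = pd.DataFrame([result.summary])
        summary_df.to_csv(out / "summary.csv", index=False, float_format="%.10g")
        manifest = {
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "seed": config.experiment.base_seed,
            "rows": {
                "timeseries": int(len(result.trajectories)),
                "agents": int(len(result.agent_trajectories)),
            },
            "version": _package_version(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except OSError as e:
        raise OSError(f"cannot write outputs under {out}: {e}") from e
    return manifest


def _package_version() -> str:
    from . import __version__

    return __version__
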