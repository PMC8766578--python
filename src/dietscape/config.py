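"""Pipeline configuration: schema, defaults, validation, round-tripping.

Configuration is plain structured text (YAML or JSON — YAML is a
superset). Unknown keys are rejected so typos fail loudly; every
omitted key takes the study default (10 active days, 30 participants
per zip, SMD balance threshold 0.25, caliper 2.5 shrinking by 0.1,
1000 bootstrap replications).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Configuration schema violation; message names the offending key."""


@dataclass
class PipelineConfig:
    # study filters
    min_days: int = 10
    min_participants: int = 30
    # matching / inference
    balance_threshold: float = 0.25
    caliper_start: float = 2.5
    caliper_step: float = 0.1
    bootstrap_reps: int = 1000
    split: str = "median"
    factors: list[str] = field(
        default_factory=lambda: [
            "income", "college_frac", "grocery_access", "fastfood_access",
        ]
    )
    subgroups: list[str] = field(default_factory=lambda: ["all"])
    # inputs: either a simulation block (kwargs for SimConfig) or a map of
    # real input file paths (logs, participants, tracts, crosswalk,
    # businesses, centroids, demographics)
    simulate: dict | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    rules_dir: str | None = None
    run_null_check: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_days < 1:
            raise ConfigError("min_days: must be >= 1")
        if self.min_participants < 1:
            raise ConfigError("min_participants: must be >= 1")
        if self.balance_threshold <= 0:
            raise ConfigError("balance_threshold: must be > 0")
        if not (self.caliper_start > self.caliper_step > 0):
            raise ConfigError("caliper_start/caliper_step: need start > step > 0")
        if self.bootstrap_reps < 1:
            raise ConfigError("bootstrap_reps: must be >= 1")
        if self.split not in ("median", "quartile"):
            raise ConfigError(f"split: unknown value {self.split!r}")
        # simulate-vs-inputs completeness is checked at run time by the
        # runner, which can name the stage and the missing path.


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a configuration file (YAML or JSON)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root: must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a configuration back out; load→dump→load is the identity."""
    Path(path).write_text(
        yaml.safe_dump(asdict(config), sort_keys=True), encoding="utf-8"
    )
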