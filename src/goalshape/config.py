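"""Run configuration: thresholds, schedule, simulation block, seed.

Configurations load from YAML; a stable SHA-256 hash of the canonical JSON
form is embedded (with the seed) in every output file so that any table can
be traced back to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .cohort_sim import SimParams
from .engine import Schedule

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    sim: SimParams = field(default_factory=SimParams)
    schedule: Schedule = field(default_factory=Schedule)
    run_in_compliance_threshold: float = 0.5
    confidence_low_cutoff: int = 4
    verbosity: str = "info"

    def validate(self) -> None:
        self.sim.validate()
        if not 0.0 <= self.run_in_compliance_threshold <= 1.0:
            raise ValueError("run_in_compliance_threshold must be in [0, 1]")
        if not 1 <= self.confidence_low_cutoff <= 5:
            raise ValueError("confidence_low_cutoff must be in 1..5")

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "schedule": asdict(self.schedule),
            "run_in_compliance_threshold": self.run_in_compliance_threshold,
            "confidence_low_cutoff": self.confidence_low_cutoff,
            "verbosity": self.verbosity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(
            sim=SimParams.from_dict(d.get("sim", {})),
            schedule=Schedule(**d.get("schedule", {})),
            run_in_compliance_threshold=d.get("run_in_compliance_threshold", 0.5),
            confidence_low_cutoff=d.get("confidence_low_cutoff", 4),
            verbosity=d.get("verbosity", "info"),
        )
        cfg.validate()
        return cfg


def load_config(path: Optional[Union[str, Path]] = None) -> RunConfig:
    """Load a YAML config; with no path, return validated defaults."""
    if path is None:
        cfg = RunConfig()
        cfg.validate()
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the canonical configuration."""
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
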