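"""Run configuration: defaults, YAML (de)serialization, merging."""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import yaml

from .exceptions import ValidationError
from .point_pattern import GemeConfig
from .simulation import SimulationSpec


@dataclass(frozen=True)
class AnalysisConfig:
    """Group-comparison settings: significance level, replicate count, test."""

    alpha: float = 0.05
    replicates: int = 100
    test: str = "welch"


@dataclass
class RunConfig:
    """Full configuration of a pipeline run.

    Defaults mirror the documented module defaults; a config file overrides
    them and command-line flags override the file.  All randomness flows from
    ``seed``.
    """

    geme: GemeConfig = field(default_factory=GemeConfig)
    simulation: list[SimulationSpec] = field(default_factory=list)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "geme": dataclasses.asdict(self.geme),
            "simulation": [dataclasses.asdict(s) for s in self.simulation],
            "analysis": dataclasses.asdict(self.analysis),
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"geme", "simulation", "analysis", "seed", "log_level"}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            geme=GemeConfig(**d.get("geme", {})),
            simulation=[SimulationSpec(**s) for s in d.get("simulation", [])],
            analysis=AnalysisConfig(**d.get("analysis", {})),
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError("config file must contain a mapping")
        return cls.from_dict(data)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())
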