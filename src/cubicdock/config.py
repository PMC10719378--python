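"""Structured run configuration with defaults and provenance.

All defaults follow the published protocol: population 100, 50
generations, mutation/recombination rates 0.1/0.7, trimming thresholds
90/70/70, redundancy pruning at 0.1 A relaxed by 0.005 A for up to 18
steps, and the 1000 -> 100 -> 5 selection funnel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .ccs import CCSConfig
from .energy import EnergyConfig
from .engine import DEConfig
from .ensemble import EnsembleConfig
from .selection import SelectionConfig


class ConfigError(Exception):
    pass


@dataclass
class RunConfig:
    de: DEConfig = field(default_factory=DEConfig)
    ccs: CCSConfig = field(default_factory=CCSConfig)
    energy: EnergyConfig = field(default_factory=EnergyConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0
    output_dir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        kwargs = {}
        sections = {
            "de": DEConfig,
            "ccs": CCSConfig,
            "energy": EnergyConfig,
            "ensemble": EnsembleConfig,
            "selection": SelectionConfig,
        }
        for name, klass in sections.items():
            sub = doc.pop(name, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - valid
            if unknown:
                raise ConfigError(f"unknown keys in {name!r}: {sorted(unknown)}")
            kwargs[name] = klass(**sub)
        for key in ("seed", "output_dir"):
            if key in doc:
                kwargs[key] = doc.pop(key)
        if doc:
            raise ConfigError(f"unknown top-level keys: {sorted(doc)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def provenance(self) -> dict:
        from . import __version__

        return {
            "config": self.to_dict(),
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "version": __version__,
        }


def show_defaults() -> str:
    return yaml.safe_dump(RunConfig().to_dict(), sort_keys=False)
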