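"""Pipeline configuration: defaults, YAML round-trip, and artifact hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .clustering import HDBSCANConfig
from .dissimilarity import ForestConfig
from .errors import ConfigurationError


@dataclass
class MDSConfig:
    n_init: int = 4
    max_iter: int = 300


@dataclass
class PipelineConfig:
    """Everything a run needs; all seeds are explicit after materialization."""

    seed: int = 0
    n_patients: int = 18_732
    generation_mode: str = "exact_counts"
    separation: float = 1.0
    subsample_fraction: float = 0.10
    subsample_threshold: int = 5000
    forest: ForestConfig = field(default_factory=ForestConfig)
    mds: MDSConfig = field(default_factory=MDSConfig)
    hdbscan: HDBSCANConfig = field(default_factory=HDBSCANConfig)
    taxonomy_path: str | None = None
    cohort_path: str = "cohort.csv"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in (("forest", ForestConfig), ("mds", MDSConfig), ("hdbscan", HDBSCANConfig)):
            if key in payload and isinstance(payload[key], dict):
                payload[key] = sub(**payload[key])
        return cls(**payload)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
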