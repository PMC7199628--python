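"""Run configuration: one YAML document driving every CLI command.

All fields have working defaults, so ``simulate`` + ``evaluate`` run with
no config file at all.  A config file only needs to state the fields it
overrides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .metrics import METRIC_NAMES, get_metric
from .spectral import DEFAULT_BAND, DEFAULT_EPSILON, WelchConfig
from .synthetic import GeneratorConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int = 42
    metrics: list[str] = field(default_factory=lambda: list(METRIC_NAMES))
    feature: str = "dft-welch"
    band: tuple[float, float] = DEFAULT_BAND
    epsilon: float = DEFAULT_EPSILON
    welch: WelchConfig = field(default_factory=WelchConfig)
    aggregation: str = "max"
    grid_step: float = 0.01
    n_templates: int = 30
    group_size: int = 30
    n_repetitions: int = 20
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    dataset_path: str | None = None
    layout: str = "per-file"

    def __post_init__(self) -> None:
        for m in self.metrics:
            get_metric(m)
        if self.aggregation not in ("max", "min"):
            raise ValueError("aggregation must be 'max' or 'min'")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        if "welch" in doc:
            doc["welch"] = WelchConfig(**doc["welch"])
        if "generator" in doc:
            gen = dict(doc["generator"])
            if "anomaly_amp_jitter" in gen:
                gen["anomaly_amp_jitter"] = tuple(gen["anomaly_amp_jitter"])
            doc["generator"] = GeneratorConfig(**gen)
        if "band" in doc:
            doc["band"] = tuple(doc["band"])
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "metrics": list(self.metrics),
            "feature": self.feature,
            "band": list(self.band),
            "epsilon": self.epsilon,
            "welch": self.welch.to_dict(),
            "aggregation": self.aggregation,
            "grid_step": self.grid_step,
            "n_templates": self.n_templates,
            "group_size": self.group_size,
            "n_repetitions": self.n_repetitions,
            "generator": self.generator.to_dict(),
            "dataset_path": self.dataset_path,
            "layout": self.layout,
        }

    def with_seed(self, seed: int) -> "RunConfig":
        """Return a copy with both protocol and generator seeds replaced."""
        doc = self.to_dict()
        doc["seed"] = seed
        doc["generator"]["seed"] = seed
        return RunConfig.from_dict(doc)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML (or JSON, a YAML subset); None -> defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"config file not found: {path}")
    doc = yaml.safe_load(path.read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(doc)
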