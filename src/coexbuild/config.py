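"""Pipeline configuration: defaults, validation, YAML round-tripping."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters with their production defaults.

    Defaults: 2e6 minimum total mapped counts per run, mean count 30 per
    gene, pseudocount 0.125, 1000-PC truncation, 10% PC subsampling, 1000
    repetitions, pathway size cutoff 50, partial ROC at 1% FPR, top 1% of
    coexpressed lists for supportability.
    """

    min_total_counts: int = 2_000_000
    min_mean_count: float = 30.0
    pseudocount: float = 0.125
    max_pcs: int = 1000
    subsample_fraction: float = 0.10
    n_repetitions: int = 1000
    pathway_max_size: int = 50
    fpr_max: float = 0.01
    top_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_total_counts <= 0:
            raise ConfigError("min_total_counts must be positive")
        if self.min_mean_count <= 0:
            raise ConfigError("min_mean_count must be positive")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be positive")
        if self.max_pcs < 1:
            raise ConfigError("max_pcs must be >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise ConfigError("subsample_fraction must be in (0, 1]")
        if self.n_repetitions < 1:
            raise ConfigError("n_repetitions must be >= 1")
        if self.pathway_max_size < 3:
            raise ConfigError("pathway_max_size must be >= 3")
        if not 0 < self.fpr_max <= 1:
            raise ConfigError("fpr_max must be in (0, 1]")
        if not 0 < self.top_fraction <= 1:
            raise ConfigError("top_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash identifying this parameter set."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config file; unknown keys are rejected."""
    with open(path, "rt") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return PipelineConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
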