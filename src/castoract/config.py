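"""Pipeline configuration (YAML-loadable, strictly validated)."""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["ForestConfig", "PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised for malformed or invalid configuration files."""


class ForestConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_trees: int = Field(default=500, ge=1)
    mtry: int = Field(default=2, ge=1)


class PipelineConfig(BaseModel):
    """Everything the end-to-end pipeline needs; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_per_class: int = Field(default=100, ge=1)
    sample_rate_accel: float = Field(default=8.0, gt=0)
    sample_rate_pressure: float = Field(default=2.0, gt=0)
    window_s: float = Field(default=2.0, gt=0)
    means_from: str = "static"
    sds_from: str = "raw"
    folds: int = Field(default=10, ge=2)
    forest: ForestConfig = Field(default_factory=ForestConfig)
    #: per-behaviour generator overrides, e.g. {walking: {odba_target: 0.3}}
    profiles: Optional[dict[str, dict]] = None
    out_dir: str = "results"


def load_config(path: Optional[str]) -> PipelineConfig:
    """Load and validate a YAML pipeline config (defaults when path is None)."""
    if path is None:
        return PipelineConfig()
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if data is None:
        return PipelineConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    try:
        return PipelineConfig(**data)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
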