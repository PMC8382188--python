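"""Instance configuration: validated YAML describing a knowledge-base build."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["CollectionConfig", "WeightingConfig", "InstanceConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


class CollectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    path: str
    format: Literal["gmt", "yaml", "json", "obo"] = "yaml"


class WeightingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    c0: float = 0.0
    c1: float = 1.0

    @field_validator("c0", "c1")
    @classmethod
    def non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("weighting constants must be >= 0")
        return v


class InstanceConfig(BaseModel):
    """Build-time settings for one knowledge-base instance.

    Defaults follow the package's standard instances: k = 6 with uniform
    weighting suits gene-set collections (symbols are short and equally
    informative); information-content weighting (c0 = 0, c1 = 1) suits
    mixed natural-language text.
    """

    model_config = ConfigDict(extra="forbid")
    collections: list[CollectionConfig] = Field(min_length=1)
    k: int = 6
    weighting: WeightingConfig = WeightingConfig()
    max_features: int = 200_000
    diffusion: dict[str, float] = Field(default_factory=dict)
    index_backend: Literal["exact"] = "exact"

    @field_validator("k")
    @classmethod
    def positive_k(cls, v: int) -> int:
        if v < 1:
            raise ValueError("k must be >= 1")
        return v


def load_config(path: str | Path) -> InstanceConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
        return InstanceConfig.model_validate(raw)
    except Exception as exc:  # pydantic error message names the offending key
        raise ConfigError(str(exc)) from exc
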