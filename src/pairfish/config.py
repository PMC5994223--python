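"""Run configuration: validated parameters with provenance hashing.

Every output file of a pipeline run carries the SHA-256 hash of the
canonicalized configuration, so two runs are byte-comparable iff their
configurations (and seeds) agree.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    pass


class RunConfig(BaseModel):
    """All tunable pipeline parameters; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    pixel_size_um: float = Field(0.325, gt=0)
    nuclear_channel: int = Field(0, ge=0)
    signal_channel: int = Field(1, ge=0)

    # calibration
    k_sigma: float = Field(3.0, ge=0)
    diameter_mode: Literal["fixed", "wt-derived"] = "fixed"
    fixed_diameter_px: float = Field(3.0, ge=0)
    wt_fraction: float = Field(0.5, gt=0, le=1)

    # detection
    connectivity: Literal[4, 8] = 8
    declump: bool = False
    max_single_dot_area_px: int = Field(40, gt=0)

    # segmentation
    min_nucleus_area_px: int = Field(60, gt=0)
    max_nucleus_area_px: int = Field(5000, gt=0)
    smoothing_sigma: float = Field(2.0, ge=0)

    # assignment / positivity
    max_distance_px: float = Field(30.0, ge=0)
    tie_break: Literal["lowest-label"] = "lowest-label"
    positive_min_dots: int = Field(1, ge=1)
    histogram_max_bin: int = Field(15, ge=1)

    seed: int = 0
    output_dir: str = "results"

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; an empty/missing-keys file yields all defaults.

    Invalid or unknown keys raise :class:`ConfigError` naming the key.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data)}")
    try:
        return RunConfig(**data)
    except ValidationError as err:
        keys = ", ".join(
            ".".join(str(p) for p in e["loc"]) or "<root>" for e in err.errors()
        )
        raise ConfigError(f"invalid configuration key(s): {keys}\n{err}") from err


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
    return path
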