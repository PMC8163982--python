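"""Validated run configuration for the command-line pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, field_validator

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    """Configuration for a full pipeline run.

    The pathway pair is ordered: positive ΔΔlog means bias toward the
    first-listed pathway.
    """

    input: Path | None = None
    dialect: Literal["nanobit", "deret", "fret"] = "nanobit"
    baseline_end: float = 5.0
    stim_end: float = 35.0
    vehicle_mode: Literal["divide", "subtract"] = "divide"
    pathways: tuple[str, str] = ("mini-Gs", "barr2")
    reference: str = "reference"
    metrics: tuple[str, ...] = ("log_max_ec50",)
    seed: int = 0
    outdir: Path = Path("gpcrbias_out")

    @field_validator("pathways")
    @classmethod
    def _two_pathways(cls, v):
        if len(v) != 2 or v[0] == v[1]:
            raise ValueError("pathway pair must have exactly 2 distinct members")
        return v

    @field_validator("metrics")
    @classmethod
    def _known_metrics(cls, v):
        unknown = set(v) - {"log_max_ec50", "log_ktau"}
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        if not v:
            raise ValueError("at least one metric required")
        return v

    @field_validator("baseline_end", "stim_end")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("time windows must be positive")
        return v


def load_config(path) -> RunConfig:
    """Load a YAML run configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)
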