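"""Run configuration: validated YAML schema and the published/desk presets."""

from __future__ import annotations

import os
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = ["DesignBlock", "StandBlock", "LightBlock", "RunConfig",
           "paper_preset", "desk_preset", "load_config"]


class DesignBlock(BaseModel):
    strategy_grid: list[float] = Field(default_factory=lambda:
                                       [round(0.1 * i, 10) for i in range(8)])
    densities: list[float] = [100.0, 400.0, 711.0, 1600.0, 6400.0]
    scenarios: list[float] = [2.0, 1.0, 4.0]   # Average, Weak, Strong (n)
    replicates: int = 20
    days: int = 46

    @field_validator("densities")
    @classmethod
    def _positive_density(cls, v):
        if any(d <= 0 for d in v):
            raise ValueError("density must be > 0")
        return v

    @field_validator("replicates", "days")
    @classmethod
    def _positive(cls, v):
        if v < 1:
            raise ValueError("must be >= 1")
        return v

    @property
    def n_matrix_cells(self) -> int:
        return len(self.strategy_grid) ** 2

    @property
    def n_runs(self) -> int:
        return (self.n_matrix_cells * self.replicates
                * len(self.densities) * len(self.scenarios))


class StandBlock(BaseModel):
    rows: int = 7
    cols: int = 7
    tile_extent: int = 20

    @model_validator(mode="after")
    def _enough_plants(self):
        if self.rows * self.cols < 9:
            raise ValueError("rows*cols must be >= 9 (focal plant needs a "
                             "full neighbour ring)")
        return self


class LightBlock(BaseModel):
    par_intensity: float = 220.0
    rfr_ratio: float = 2.3
    photoperiod: float = 9.0
    ray_count: int = 20000
    max_bounces: int = 2

    @field_validator("par_intensity", "rfr_ratio", "photoperiod")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("must be >= 0")
        return v

    @field_validator("ray_count")
    @classmethod
    def _rays(cls, v):
        if v < 1:
            raise ValueError("ray_count must be >= 1")
        return v


class RunConfig(BaseModel):
    """Full experiment configuration; ``preset`` fills published defaults."""

    name: str = "experiment"
    preset: Literal["paper", "desk", "custom"] = "custom"
    design: DesignBlock = Field(default_factory=DesignBlock)
    stand: StandBlock = Field(default_factory=StandBlock)
    light: LightBlock = Field(default_factory=LightBlock)
    physiology_file: str | None = None
    seed: int = 0
    output_dir: str = "results"

    @property
    def n_runs(self) -> int:
        return self.design.n_runs

    @property
    def n_tiles(self) -> int:
        """Replicated canopy count of the border-effect removal (per stand)."""
        return self.stand.tile_extent ** 2

    def echo_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def paper_preset(**overrides) -> RunConfig:
    """The published design: 8 strategies x 8 residents x 20 replicates x
    5 densities x 3 scenarios, 46 days, 20x20 tiling."""
    cfg = RunConfig(name="paper", preset="paper")
    return cfg.model_copy(update=overrides)


def desk_preset(**overrides) -> RunConfig:
    """Scaled-down configuration for desk-scale reruns: 4 strategies,
    3 densities, 5 replicates, 5x5 stands, reduced ray budget."""
    cfg = RunConfig(
        name="desk", preset="desk",
        design=DesignBlock(strategy_grid=[0.0, 0.2, 0.4, 0.6],
                           densities=[100.0, 1600.0, 6400.0],
                           scenarios=[2.0], replicates=5, days=46),
        stand=StandBlock(rows=5, cols=5),
        light=LightBlock(ray_count=1200),
    )
    return cfg.model_copy(update=overrides)


def load_config(path: str) -> RunConfig:
    """Read and validate a YAML config; raises with the offending field named."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    preset = raw.pop("preset", "custom")
    if preset == "paper":
        base = paper_preset().model_dump()
    elif preset == "desk":
        base = desk_preset().model_dump()
    else:
        base = {}
    for key, val in raw.items():
        if isinstance(val, dict) and key in base and isinstance(base[key], dict):
            base[key].update(val)
        else:
            base[key] = val
    base["preset"] = preset
    return RunConfig.model_validate(base)
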