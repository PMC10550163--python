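"""YAML pipeline configuration, validated with pydantic."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .types import EXPRESSIONS


class StudySection(BaseModel):
    n_participants: int = Field(8, ge=1)
    n_actors: int = Field(8, ge=1)
    with_trajectories: bool = True
    effect_scale: float = Field(1.0, ge=0)
    parts: list[int] = [1, 2]


class ScreenSection(BaseModel):
    width: int = Field(1920, gt=0)
    height: int = Field(1080, gt=0)
    origin: tuple[float, float] = (660.0, 140.0)
    canvas: tuple[int, int] = (600, 800)

    @model_validator(mode="after")
    def _stimulus_inside_screen(self):
        ox, oy = self.origin
        if ox < 0 or oy < 0 or ox + self.canvas[0] > self.width or oy + self.canvas[1] > self.height:
            raise ValueError("origin: stimulus rectangle must fit inside the screen")
        return self


class PreprocessSection(BaseModel):
    sigma_px: float = Field(10.0, gt=0)


class ModelSection(BaseModel):
    variant: Literal["A", "B", "C"] = "A"
    conditions: Optional[list[str]] = None
    part: Optional[int] = None
    chains: int = Field(4, ge=1)
    warmup: int = Field(1000, ge=0)
    iterations: int = Field(2000, gt=0)
    fixed_effect_sd: float = Field(10.0, gt=0)
    random_scale_shape: float = Field(10.0, gt=0)
    random_scale_rate: float = Field(10.0, gt=0)
    phi_prior_shape: float = Field(2.0, gt=0)
    phi_prior_rate: float = Field(0.1, gt=0)
    target_accept: float = Field(0.85, gt=0, lt=1)
    max_leapfrog: int = Field(32, ge=1)

    @model_validator(mode="after")
    def _checks(self):
        if self.iterations <= self.warmup:
            raise ValueError("iterations: must exceed warmup")
        for c in self.conditions or []:
            if c not in EXPRESSIONS:
                raise ValueError(f"conditions: unknown expression {c!r}")
        return self


class PipelineConfig(BaseModel):
    study: StudySection = StudySection()
    screen: ScreenSection = ScreenSection()
    preprocess: PreprocessSection = PreprocessSection()
    model: ModelSection = ModelSection()


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; errors name the offending field."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)
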