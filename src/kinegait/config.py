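"""Validated, serialisable run configuration.

Every CLI run writes its resolved configuration next to its outputs, so a
pipeline is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator


class PreprocessConfig(BaseModel):
    k_sd: float = Field(1.0, gt=0)
    scale: str = "mad"
    sg_order: int = Field(2, ge=0)
    sg_window: int = Field(25, ge=3)

    @field_validator("scale")
    @classmethod
    def _scale(cls, v):
        if v not in ("mad", "sd"):
            raise ValueError("scale must be 'mad' or 'sd'")
        return v

    @field_validator("sg_window")
    @classmethod
    def _odd(cls, v):
        if v % 2 == 0:
            raise ValueError("sg_window must be odd")
        return v

    @property
    def sg_half_window(self) -> int:
        return self.sg_window // 2


class PeakConfig(BaseModel):
    min_prominence: float = Field(0.05, gt=0)
    min_separation: int = Field(10, ge=1)
    trim_radius: int = Field(15, ge=0)
    min_span: int = Field(30, ge=2)


class ClassifyConfig(BaseModel):
    model: str = "threshold"
    features: tuple[str, ...] = ("sl_m", "gv_mps")
    hidden: int = Field(4, ge=1)
    centres: int = Field(18, ge=1)
    spread: float = Field(0.1, gt=0)
    folds: int | None = None  # None = leave-one-out
    seed: int = 0

    @field_validator("model")
    @classmethod
    def _model(cls, v):
        if v not in ("threshold", "mlp", "rbfn", "perceptron"):
            raise ValueError(f"unknown model {v!r}")
        return v


class SimulateConfig(BaseModel):
    n_pd: int = Field(18, ge=0)
    n_norm: int = Field(18, ge=0)
    n_stud: int = Field(15, ge=0)
    noise_sd: float = Field(0.005, ge=0)
    outlier_rate: float = Field(0.01, ge=0, lt=1)
    seed: int = 0
    dialect: str = "long"


class RunConfig(BaseModel):
    preprocess: PreprocessConfig = PreprocessConfig()
    peaks: PeakConfig = PeakConfig()
    classify: ClassifyConfig = ClassifyConfig()
    simulate: SimulateConfig = SimulateConfig()

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.model_dump_json(indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))
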