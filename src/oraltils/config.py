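"""Run configuration: YAML schema, validation and defaults.

The default values mirror the published training recipe (Adam, learning
rate 0.001, stage-I batch 8 / fine-tune and stage-II batch 16, early-
stopping patience 8, confidence threshold 0.95, last 20 layers unfrozen)
while the problem sizes default to a demo profile small enough to run the
whole two-stage pipeline on one CPU in minutes.  Unknown keys and
out-of-range values fail validation with the offending field named.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["RunConfig", "Stage1Config", "Stage2Config", "validate_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LossSettings(_Strict):
    lambda1: float = Field(1.0, ge=0)
    lambda2: float = Field(1.0, ge=0)
    focal_gamma: float = Field(2.0, ge=0)
    focal_alpha: float = Field(0.25, gt=0)
    dice_smooth: float = Field(1e-6, gt=0)


class Stage1Config(_Strict):
    tile_size: int = Field(64, ge=32)
    input_size: int = Field(64, ge=32)
    encoder_variant: str = "micro"
    n_train: int = Field(160, ge=8)
    n_val: int = Field(16, ge=0)
    epochs: int = Field(5, ge=1)
    batch_size: int = Field(8, ge=1)
    optimizer: str = "adam"
    learning_rate: float = Field(0.001, gt=0)
    patience: int = Field(8, ge=0)
    loss: LossSettings = LossSettings()
    confidence_tau: float = Field(0.95, gt=0, lt=1)
    min_cellular_fraction: float = Field(0.01, ge=0, le=1)
    unfreeze_last_n: int = Field(20, ge=0)
    finetune_epochs: int = Field(3, ge=0)
    finetune_batch_size: int = Field(16, ge=1)

    @field_validator("input_size")
    @classmethod
    def _divisible(cls, v: int) -> int:
        if v % 32:
            raise ValueError("input_size must be a multiple of 32")
        return v

    @field_validator("optimizer")
    @classmethod
    def _opt(cls, v: str) -> str:
        if v.lower() not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        return v.lower()


class Stage2Config(_Strict):
    fov_size: int = Field(128, ge=64)
    input_size: int = Field(32, ge=32)
    encoder_variant: str = "micro"
    n_per_class: int = Field(12, ge=2)
    test_fraction: float = Field(0.25, gt=0, lt=1)
    epochs: int = Field(8, ge=1)
    batch_size: int = Field(16, ge=1)
    optimizer: str = "adam"
    learning_rate: float = Field(0.001, gt=0)
    dropout_rate: float = Field(0.3, ge=0, lt=1)
    augment: bool = False

    _opt = field_validator("optimizer")(Stage1Config._opt.__func__)


class RunConfig(_Strict):
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "artifacts"
    stage1: Stage1Config = Stage1Config()
    stage2: Stage2Config = Stage2Config()

    @field_validator("log_level")
    @classmethod
    def _level(cls, v: str) -> str:
        if v.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError("log_level must be DEBUG/INFO/WARNING/ERROR")
        return v.upper()


def validate_config(path: str | Path | None = None) -> RunConfig:
    """Load and schema-check a YAML run config; ``None``/empty -> defaults."""
    if path is None:
        return RunConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
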