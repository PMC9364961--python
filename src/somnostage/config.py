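"""Structured run configuration with strict validation.

A single YAML file drives the full pipeline.  Unknown keys are rejected
with their names (so typos fail before any computation) and a loaded
configuration round-trips losslessly through ``to_yaml``/``from_yaml``.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .model import ModelConfig
from .stages import StageLabel
from .training import ResamplePolicy, TrainSchedule

__all__ = ["RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneratorSettings(_Strict):
    subjects: int = 4
    nights_per_subject: int = 1
    epochs_per_night: int = 120
    fs_hz: float = 100.0


class ModelSettings(_Strict):
    input_len: int = 300
    input_channels: int = 2
    lstm_units: int = 64
    lstm_layers: int = 2
    conv_specs: list[tuple[int, int]] = Field(
        default_factory=lambda: [(64, 5), (32, 5)]
    )
    pool_size: int = 3
    fc_sizes: list[int] = Field(default_factory=lambda: [64, 32])
    n_classes: int = 5
    dropout_conv: float = 0.20
    dropout_fc: float = 0.50
    batchnorm: bool = True
    use_attention_pool: bool = False
    input_scale_uv: float = 100.0

    def to_model_config(self) -> ModelConfig:
        return ModelConfig(
            input_len=self.input_len,
            input_channels=self.input_channels,
            lstm_units=self.lstm_units,
            lstm_layers=self.lstm_layers,
            conv_specs=tuple(tuple(p) for p in self.conv_specs),
            pool_size=self.pool_size,
            fc_sizes=tuple(self.fc_sizes),
            n_classes=self.n_classes,
            dropout_conv=self.dropout_conv,
            dropout_fc=self.dropout_fc,
            batchnorm=self.batchnorm,
            use_attention_pool=self.use_attention_pool,
            input_scale_uv=self.input_scale_uv,
        )


class ResampleSettings(_Strict):
    enabled: bool = True
    cap_per_stage_per_night: int = 200
    oversample_stages: list[str] = Field(
        default_factory=lambda: ["W", "N1", "N3", "REM"]
    )
    undersample_stages: list[str] = Field(default_factory=lambda: ["N2"])

    def to_policy(self) -> ResamplePolicy:
        return ResamplePolicy(
            cap_per_stage_per_night=self.cap_per_stage_per_night,
            oversample_stages=frozenset(
                StageLabel.from_name(s) for s in self.oversample_stages
            ),
            undersample_stages=frozenset(
                StageLabel.from_name(s) for s in self.undersample_stages
            ),
        )


class ScheduleSettings(_Strict):
    epochs: int = 100
    batch_size: int = 10
    lr_init: float = 0.015
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 20
    clip_grad_norm: float | None = 5.0

    def to_schedule(self, seed: int) -> TrainSchedule:
        return TrainSchedule(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr_init=self.lr_init,
            lr_decay_factor=self.lr_decay_factor,
            lr_decay_every=self.lr_decay_every,
            clip_grad_norm=self.clip_grad_norm,
            seed=seed,
        )


class SplitSettings(_Strict):
    #: explicit test subject ids; when empty, the last ``n_test_subjects``
    #: generated subjects are held out
    test_subjects: list[str] = Field(default_factory=list)
    n_test_subjects: int = 1
    validation_folds: int = 12


class EvaluationSettings(_Strict):
    include_absent_classes: bool = True


class RunConfig(_Strict):
    """Top-level configuration for the simulate/train/evaluate pipeline."""

    seed: int = 0
    out_dir: str = "somnostage_run"
    reuse_existing: bool = False
    generator: GeneratorSettings = Field(default_factory=GeneratorSettings)
    model: ModelSettings = Field(default_factory=ModelSettings)
    resample: ResampleSettings = Field(default_factory=ResampleSettings)
    schedule: ScheduleSettings = Field(default_factory=ScheduleSettings)
    split: SplitSettings = Field(default_factory=SplitSettings)
    evaluation: EvaluationSettings = Field(default_factory=EvaluationSettings)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
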