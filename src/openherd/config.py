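"""Validated YAML run configuration.

One YAML file describes a full reproducible experiment: the synthetic-herd
generator, the backbone, the loss hyperparameters, the training protocol and
the evaluation conventions, all hanging off a single global seed that is
expanded per trial.  Unknown keys are rejected so that typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from openherd.backbone import FeatureExtractorSpec
from openherd.synthetic import NuisanceConfig, SESSIONS
from openherd.training import AugmentConfig, TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticBlock(_Strict):
    n_ids: int = 17
    sigma_id: float = 1.0
    per_id_per_session: int = 24
    sessions: tuple[str, ...] = SESSIONS
    days: tuple[str, ...] = ("day1", "day2")
    image_size: int = 64
    rgb: bool = False
    # nuisance magnitudes (mirror NuisanceConfig)
    rotation_range: float = 15.0
    illumination_range: tuple[float, float] = (0.7, 1.3)
    fog_level: float = 0.2
    partial_crop_prob: float = 0.1
    occlusion_prob: float = 0.1
    scale_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.05
    session_illumination: dict[str, float] | None = None

    def nuisance(self) -> NuisanceConfig:
        return NuisanceConfig(
            rotation_range=self.rotation_range,
            illumination_range=tuple(self.illumination_range),
            fog_level=self.fog_level,
            partial_crop_prob=self.partial_crop_prob,
            occlusion_prob=self.occlusion_prob,
            scale_range=tuple(self.scale_range),
            noise_sd=self.noise_sd,
        )


class BackboneBlock(_Strict):
    input_size: int = 64
    embed_dim: int = 128
    architecture: str = "smallconv"
    channels: tuple[int, ...] = (8, 16, 32, 64)
    embed_norm: float | None = 8.0
    pretrained: str | None = None

    def spec(self) -> FeatureExtractorSpec:
        return FeatureExtractorSpec(
            input_size=self.input_size, embed_dim=self.embed_dim,
            architecture=self.architecture, channels=tuple(self.channels),
            embed_norm=self.embed_norm, pretrained=self.pretrained,
        )


class LossBlock(_Strict):
    s: float = 10.0
    m: float = 0.5
    lambda_amc: float = 0.1
    lambda_rp_ce: float = 1.0
    gamma: float = 0.03
    predict_from: str = "am_head"

    @field_validator("predict_from")
    @classmethod
    def _check_head(cls, v: str) -> str:
        if v not in ("am_head", "rp_distance"):
            raise ValueError("predict_from must be 'am_head' or 'rp_distance'")
        return v


class AugmentBlock(_Strict):
    rotation_deg: float = 15.0
    brightness: float = 0.3
    crop_frac: float = 0.2
    noise_sd: float = 0.05
    prob: float = 0.7


class TrainBlock(_Strict):
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    points_lr: float = 0.05
    optimizer: str = "adam"
    train_day: str = "day1"
    augment: AugmentBlock = Field(default_factory=AugmentBlock)


class ProtocolBlock(_Strict):
    n_known: int = 10
    n_trials: int = 5


class EvalBlock(_Strict):
    test_day: str = "day2"
    openness_variant: str = "sqrt"
    sd_convention: str = "sample"
    export_curves: bool = False

    @field_validator("openness_variant")
    @classmethod
    def _check_variant(cls, v: str) -> str:
        if v not in ("ratio", "sqrt"):
            raise ValueError("openness_variant must be 'ratio' or 'sqrt'")
        return v

    @field_validator("sd_convention")
    @classmethod
    def _check_sd(cls, v: str) -> str:
        if v not in ("sample", "population"):
            raise ValueError("sd_convention must be 'sample' or 'population'")
        return v


class RunConfig(_Strict):
    """Schema of one experiment; see the block classes for field meanings."""

    seed: int = 0
    synthetic: SyntheticBlock = Field(default_factory=SyntheticBlock)
    backbone: BackboneBlock = Field(default_factory=BackboneBlock)
    loss: LossBlock = Field(default_factory=LossBlock)
    train: TrainBlock = Field(default_factory=TrainBlock)
    protocol: ProtocolBlock = Field(default_factory=ProtocolBlock)
    eval: EvalBlock = Field(default_factory=EvalBlock)

    def train_config(self, trial_seed: int | None = None) -> TrainConfig:
        return TrainConfig(
            epochs=self.train.epochs,
            batch_size=self.train.batch_size,
            learning_rate=self.train.learning_rate,
            points_lr=self.train.points_lr,
            optimizer=self.train.optimizer,
            s=self.loss.s,
            m=self.loss.m,
            lambda_amc=self.loss.lambda_amc,
            lambda_rp_ce=self.loss.lambda_rp_ce,
            gamma=self.loss.gamma,
            predict_from=self.loss.predict_from,
            train_day=self.train.train_day,
            augment=AugmentConfig(**self.train.augment.model_dump()),
            seed=self.seed if trial_seed is None else trial_seed,
        )


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration (defaults included) to YAML."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
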