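"""Pipeline configuration: schema-validated YAML with reference defaults.

Every default that the reference protocol fixes is fixed here too: 250 Hz
sampling, 19-channel 10-20 montage, 10 non-overlapping 4-s segments, the
five canonical bands, learning rate 0.0005, 100 epochs, batch size 4 and
ten-fold subject-wise cross-validation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .constants import BAND_EDGES, DEFAULT_FS, MONTAGE_19
from .model import AttentionConfig, ModelConfig
from .synthetic import CohortConfig
from .train_eval import TrainConfig

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


class ModelSettings(BaseModel):
    feature_dim: int = 128
    patch_len: int = 100
    embed_dim: int = 128
    n_heads: int = 4
    encoder_depth: int = 2
    ffn_mult: int = 2
    cnn_channels: tuple[int, ...] = (8, 16, 32)
    cnn_time_pool: int = 4
    cnn_time_downsample: int = 1
    cnn_norm: str = "none"
    filter_reduction: int = 8
    spatial_kernel: int = 7
    use_filter: bool = True
    classifier_hidden: int = 64
    branches: str = "vit_cnn"

    def to_model_config(self, n_channels: int = 19) -> ModelConfig:
        return ModelConfig(
            n_channels=n_channels,
            feature_dim=self.feature_dim,
            attention=AttentionConfig(
                n_heads=self.n_heads,
                patch_len=self.patch_len,
                embed_dim=self.embed_dim,
                encoder_depth=self.encoder_depth,
                ffn_mult=self.ffn_mult,
            ),
            cnn_channels=self.cnn_channels,
            cnn_time_pool=self.cnn_time_pool,
            cnn_time_downsample=self.cnn_time_downsample,
            cnn_norm=self.cnn_norm,
            filter_reduction=self.filter_reduction,
            spatial_kernel=self.spatial_kernel,
            use_filter=self.use_filter,
            classifier_hidden=self.classifier_hidden,
            branches=self.branches,
        )


class TrainSettings(BaseModel):
    learning_rate: float = 0.0005
    max_epochs: int = 100
    batch_size: int = 4
    k_folds: int = 10
    optimizer: str = "adam"
    augment_time_shift: bool = True

    def to_train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            k_folds=self.k_folds,
            seed=seed,
            optimizer=self.optimizer,
            augment_time_shift=self.augment_time_shift,
        )


class TwoFactorSettings(BaseModel):
    strategy: str = "pairwise_probs"
    thresholds: tuple[int, int] = (10, 27)
    preset: str = "as_printed"


class SyntheticSettings(BaseModel):
    n_per_class: int = 5
    duration_s: float = 40.0
    noise_sd: float = 0.1
    contrast: float = 1.0

    def to_cohort_config(self, fs: float, n_channels: int) -> CohortConfig:
        return CohortConfig(
            duration_s=self.duration_s,
            fs=fs,
            n_channels=n_channels,
            noise_sd=self.noise_sd,
            contrast=self.contrast,
        )


class PipelineConfig(BaseModel):
    """Top-level, schema-validated pipeline settings."""

    fs: float = DEFAULT_FS
    montage: tuple[str, ...] = MONTAGE_19
    band_edges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(BAND_EDGES)
    )
    window_s: float = 4.0
    n_segments: int = 10
    normalize: bool = True
    band_decimate: int = 1
    model: ModelSettings = Field(default_factory=ModelSettings)
    train: TrainSettings = Field(default_factory=TrainSettings)
    two_factor: TwoFactorSettings = Field(default_factory=TwoFactorSettings)
    synthetic: SyntheticSettings = Field(default_factory=SyntheticSettings)
    seed: int = 0

    @field_validator("fs")
    @classmethod
    def _fs_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("sampling rate must be positive")
        return v

    @field_validator("band_edges")
    @classmethod
    def _edges_ordered(cls, v: dict) -> dict:
        for name, (lo, hi) in v.items():
            if not 0 <= lo < hi:
                raise ValueError(f"band {name}: edges must satisfy 0 <= low < high")
        return v


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load and validate a YAML config; keyword overrides take precedence."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in overrides.items():
        if value is None:
            continue
        if "." in key:
            section, leaf = key.split(".", 1)
            data.setdefault(section, {})[leaf] = value
        else:
            data[key] = value
    return PipelineConfig.model_validate(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(json.loads(cfg.model_dump_json()), sort_keys=False))
    return path


def config_hash(cfg: PipelineConfig) -> str:
    """Short stable hash identifying a configuration (for run stamping)."""
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:12]
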