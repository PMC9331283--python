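"""One human-readable configuration object for the whole pipeline.

A ``PipelineConfig`` carries every tunable constant — speech framing, mel
analysis, head-trajectory binarization, fluency-image geometry, STFT
segmentation (3 s segments hopped every 1 s), the backbone and
head-training recipe (mini-batch 10, 140 epochs, learning rate 1e-4) and
the cross-validation protocol — and round-trips losslessly through YAML.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .evaluate import CVConfig
from .rrf import BackboneSpec, TrainConfig

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    # speech framing / intensity
    frame_s: float = 0.025
    hop_s: float = 0.010
    intensity_convention: str = "power"
    # mel analysis
    n_mel_filters: int = 12
    n_mfcc: int = 12
    # head trajectory
    dead_band_px: float = 0.2
    min_run_frames: int = 3
    # fluency images
    image_side: int = 224
    stft_segment_s: float = 3.0
    stft_hop_s: float = 1.0
    # learning
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_s <= 0 or not 0 < self.hop_s <= self.frame_s:
            raise ValueError("need 0 < hop_s <= frame_s")
        if self.n_mel_filters < 1 or self.n_mfcc < 1 or self.n_mfcc > self.n_mel_filters:
            raise ValueError("need 1 <= n_mfcc <= n_mel_filters")
        if self.image_side < 8:
            raise ValueError("image_side too small")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "backbone" in data and isinstance(data["backbone"], dict):
            data["backbone"] = BackboneSpec(**data["backbone"])
        if "train" in data and isinstance(data["train"], dict):
            data["train"] = TrainConfig(**data["train"])
        if "cv" in data and isinstance(data["cv"], dict):
            data["cv"] = CVConfig(**data["cv"])
        return cls(**data)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))
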