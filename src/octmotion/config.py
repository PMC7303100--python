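"""Project configuration: one YAML document drives a whole experiment.

Every randomized stage (phantom texture, trajectories, weight init, batch
order, distortion draws) derives its stream from the single global seed, so
re-running a config reproduces every artifact bit-for-bit.  Two built-in
profiles set the experiment scale: ``desk`` (CPU-friendly) and ``full``
(full-scale protocol: 40 ROIs x 200 patterns, 150 epochs, batch 50,
30/5/5 ROI split).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import List, Tuple

import yaml

from .nets import ModelConfig
from .phantom import TextureParams
from .training import LossConfig, TrainConfig

__all__ = ["DataConfig", "EvalConfig", "ProjectConfig", "desk_profile",
           "full_profile", "load_config", "save_config"]


@dataclass(frozen=True)
class DataConfig:
    """Simulation block: phantom texture, ROI/pattern counts, trajectory."""

    n_rois: int = 8
    n_patterns: int = 25
    n_test_rois: int = 2
    n_val_rois: int = 2
    grid_size: Tuple[int, int, int] = (96, 96, 96)
    magnitude_range_mm: Tuple[float, float] = (0.2, 2.4)
    texture: TextureParams = field(default_factory=TextureParams)


@dataclass(frozen=True)
class EvalConfig:
    n_bins: int = 4
    alpha: float = 0.05


@dataclass
class ProjectConfig:
    seed: int = 0
    data: DataConfig = field(default_factory=DataConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    archs: List[str] = field(default_factory=lambda: ["two_path_3d",
                                                      "five_path_4d"])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectConfig":
        d = dict(d)
        if "data" in d:
            dd = dict(d["data"])
            if "texture" in dd:
                dd["texture"] = TextureParams(**dd["texture"])
            for k in ("grid_size", "magnitude_range_mm"):
                if k in dd:
                    dd[k] = tuple(dd[k])
            d["data"] = DataConfig(**dd)
        if "model" in d:
            d["model"] = ModelConfig.from_dict(d["model"])
        if "training" in d:
            d["training"] = TrainConfig(**d["training"])
        if "loss" in d:
            d["loss"] = LossConfig(**d["loss"])
        if "evaluation" in d:
            d["evaluation"] = EvalConfig(**d["evaluation"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def desk_profile(seed: int = 0) -> ProjectConfig:
    """CPU-friendly experiment scale (reduced width, strided stems)."""
    return ProjectConfig(
        seed=seed,
        data=DataConfig(n_rois=20, n_patterns=50, n_test_rois=2, n_val_rois=2),
        model=ModelConfig(initial_channels=(8, 16, 24),
                          stem_strides=(2, 2, 2), activation="leaky_relu",
                          temporal_kernel=3),
        training=TrainConfig(epochs=18, batch_size=5, learning_rate=3e-3,
                             seed=seed, lr_schedule="cosine", average_tail=4),
    )


def full_profile(seed: int = 0) -> ProjectConfig:
    """Full-scale protocol (40 ROIs x 200 patterns, 150 epochs, batch 50)."""
    return ProjectConfig(
        seed=seed,
        data=DataConfig(n_rois=40, n_patterns=200, n_test_rois=5,
                        n_val_rois=5, grid_size=(128, 128, 96)),
        model=ModelConfig(),
        training=TrainConfig(epochs=150, batch_size=50, learning_rate=1e-3,
                             seed=seed),
    )


def load_config(path) -> ProjectConfig:
    with open(path) as fh:
        return ProjectConfig.from_dict(yaml.safe_load(fh))


def save_config(cfg: ProjectConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
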