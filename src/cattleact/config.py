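"""Run configuration: nested dataclasses bound to a YAML file.

Two presets are provided.  ``full_scale`` carries the reference training
protocol (batch 4, learning rate 3e-5, momentum 0.9, weight decay 1e-4,
up to 100 epochs, full-width depth-50/101 backbones).  ``tiny`` is the
CPU-scale preset used by the test-suite and the worked examples: one block
per stage, 8-channel stem, 32x32 inputs, and a larger learning rate suited
to the much smaller parameter count.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .head import HeadConfig
from .losses import LossConfig, default_loss_config
from .sampler import AugmentConfig, OversampleConfig

__all__ = ["OptimizerConfig", "DataConfig", "RunConfig",
           "full_scale_config", "tiny_run_config"]


@dataclass(frozen=True)
class OptimizerConfig:
    batch_size: int = 4
    learning_rate: float = 3e-5
    momentum: float = 0.9
    weight_decay: float = 1e-4
    max_epochs: int = 100
    lr_schedule: str = "constant"  # "constant" (reference protocol) | "cosine"

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")


@dataclass(frozen=True)
class DataConfig:
    target_size: tuple[int, int] = (224, 224)
    fps: int = 30


@dataclass
class RunConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    loss_name: str = "dfl"
    loss: LossConfig = field(default_factory=default_loss_config)
    oversample: OversampleConfig = field(default_factory=OversampleConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    data: DataConfig = field(default_factory=DataConfig)
    enable_baf: bool = True
    seed: int = 0
    device: str = "cpu"

    # ------------------------------------------------------------- (de)serde
    def to_dict(self) -> dict:
        d = {
            "backbone": asdict(self.backbone),
            "head": asdict(self.head),
            "loss_name": self.loss_name,
            "loss": asdict(self.loss),
            "oversample": asdict(self.oversample),
            "augment": asdict(self.augment),
            "optimizer": asdict(self.optimizer),
            "data": asdict(self.data),
            "enable_baf": self.enable_baf,
            "seed": self.seed,
            "device": self.device,
        }
        d["backbone"]["stage_blocks"] = (
            list(self.backbone.stage_blocks)
            if self.backbone.stage_blocks else None)
        d["data"]["target_size"] = list(self.data.target_size)
        d["loss"]["class_weights"] = list(self.loss.class_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        bk = dict(d.get("backbone", {}))
        if bk.get("stage_blocks") is not None:
            bk["stage_blocks"] = tuple(bk["stage_blocks"])
        ls = dict(d.get("loss", {}))
        if "class_weights" in ls:
            ls["class_weights"] = tuple(ls["class_weights"])
        da = dict(d.get("data", {}))
        if "target_size" in da:
            da["target_size"] = tuple(da["target_size"])
        return cls(
            backbone=BackboneConfig(**bk),
            head=HeadConfig(**d.get("head", {})),
            loss_name=d.get("loss_name", "dfl"),
            loss=LossConfig(**ls),
            oversample=OversampleConfig(**d.get("oversample", {})),
            augment=AugmentConfig(**d.get("augment", {})),
            optimizer=OptimizerConfig(**d.get("optimizer", {})),
            data=DataConfig(**da),
            enable_baf=bool(d.get("enable_baf", True)),
            seed=int(d.get("seed", 0)),
            device=d.get("device", "cpu"),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def full_scale_config(depth: int = 50) -> RunConfig:
    """Reference training protocol at full model width (GPU-scale)."""
    return RunConfig(backbone=BackboneConfig(depth=depth))


def tiny_run_config(seed: int = 0, **optimizer_overrides) -> RunConfig:
    """CPU-scale preset for desk experiments and the test-suite."""
    from .backbone import tiny_config

    opt = dict(batch_size=4, learning_rate=0.02, momentum=0.9,
               weight_decay=1e-4, max_epochs=10)
    opt.update(optimizer_overrides)
    return RunConfig(
        backbone=tiny_config(),
        head=HeadConfig(hidden_dim=32, roi_resolution=3, dropout=0.2,
                        norm="layer"),
        optimizer=OptimizerConfig(**opt),
        data=DataConfig(target_size=(32, 32), fps=8),
        # at 32x32 a full-size occluder would often erase the appendage (the
        # class cue itself); keep the 30% trigger rate but shrink the patch
        augment=AugmentConfig(occlusion_area_frac=0.03),
        seed=seed,
    )
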