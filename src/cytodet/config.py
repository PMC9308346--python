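"""Experiment configuration: a single YAML-serializable record that fixes
the backbone plan, pyramid selection, anchors, loss and optimizer settings.

``load(serialize(config))`` reproduces the config exactly; every run and
checkpoint carries its config so results are reproducible from the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .backbone import BackboneConfig, StageSpec, default_config
from .losses import LossParams
from .synthetic import SceneConfig


@dataclass(frozen=True)
class OptimizerConfig:
    algorithm: str = "sgd"
    batch_size: int = 32
    base_lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0
    epochs: int = 1000
    lr_drops: tuple[int, ...] = ()


#: detector-stage defaults: small batches, low rate, two late drops
DETECTOR_OPT = OptimizerConfig(batch_size=6, base_lr=0.00125,
                               weight_decay=0.001, epochs=24,
                               lr_drops=(16, 22))


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    scene: SceneConfig = field(default_factory=SceneConfig)
    backbone: BackboneConfig = field(default_factory=default_config)
    pyramid_levels: tuple[int, ...] = (1, 2, 3, 4, 5)
    pyramid_channels: int = 256
    anchor_k: int = 15
    loss: LossParams = field(default_factory=LossParams)
    backbone_opt: OptimizerConfig = field(default_factory=OptimizerConfig)
    detector_opt: OptimizerConfig = field(default_factory=lambda: DETECTOR_OPT)
    epoch_scale: float = 1.0  # desk-scale shrink factor for smoke runs


def _loss_dict(p: LossParams) -> dict:
    return {"lam": p.lam, "alpha": p.alpha, "gamma": p.gamma,
            "kernel": p.kernel}


def serialize(config: ExperimentConfig) -> str:
    doc = {
        "seed": config.seed,
        "scene": asdict(config.scene),
        "backbone": {
            "stem_channels": config.backbone.stem_channels,
            "stages": [asdict(s) for s in config.backbone.stages],
            "head_dims": list(config.backbone.head_dims),
            "dropout": config.backbone.dropout,
            "input_size": config.backbone.input_size,
            "input_mean": list(config.backbone.input_mean),
            "input_std": list(config.backbone.input_std),
        },
        "pyramid_levels": list(config.pyramid_levels),
        "pyramid_channels": config.pyramid_channels,
        "anchor_k": config.anchor_k,
        "loss": _loss_dict(config.loss),
        "backbone_opt": asdict(config.backbone_opt),
        "detector_opt": asdict(config.detector_opt),
        "epoch_scale": config.epoch_scale,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: tuple(v) if k in keys and isinstance(v, list) else v
            for k, v in d.items()}


def deserialize(text: str) -> ExperimentConfig:
    doc = yaml.safe_load(text)
    bb = doc["backbone"]
    backbone = BackboneConfig(
        stem_channels=bb["stem_channels"],
        stages=tuple(StageSpec(**_tupled(s, ("channels",)))
                     for s in bb["stages"]),
        head_dims=tuple(bb["head_dims"]),
        dropout=bb["dropout"],
        input_size=bb["input_size"],
        input_mean=tuple(bb["input_mean"]),
        input_std=tuple(bb["input_std"]),
    )
    scene = SceneConfig(**_tupled(doc["scene"], (
        "cell_radius_range", "aspect_range", "normal_ratio_range",
        "abnormal_ratio_range")))
    return ExperimentConfig(
        seed=doc["seed"], scene=scene, backbone=backbone,
        pyramid_levels=tuple(doc["pyramid_levels"]),
        pyramid_channels=doc["pyramid_channels"],
        anchor_k=doc["anchor_k"],
        loss=LossParams(**doc["loss"]),
        backbone_opt=OptimizerConfig(**_tupled(doc["backbone_opt"],
                                               ("lr_drops",))),
        detector_opt=OptimizerConfig(**_tupled(doc["detector_opt"],
                                               ("lr_drops",))),
        epoch_scale=doc["epoch_scale"],
    )


def save(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(serialize(config))


def load(path: str | Path) -> ExperimentConfig:
    return deserialize(Path(path).read_text())
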