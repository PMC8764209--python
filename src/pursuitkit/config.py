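"""Serializable configuration bundle for the whole pipeline.

Every knob that affects behavior lives here; a round-tripped YAML file
fully determines simulation and analysis output (given the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .geometry import TaskConfig
from .headpose import CameraModel, NoiseConfig, default_camera
from .segmentation import SegmentationConfig
from .synth.camera import PoseDriftParams
from .synth.gaze import OculomotorParams
from .synth.response import ResponseParams

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    oculomotor: OculomotorParams = field(default_factory=OculomotorParams)
    response: ResponseParams = field(default_factory=ResponseParams)
    pose_drift: PoseDriftParams = field(default_factory=PoseDriftParams)
    uks_noise: NoiseConfig = field(default_factory=NoiseConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    camera: CameraModel = field(default_factory=default_camera)
    confidence_threshold: float = 0.8

    def to_dict(self) -> dict:
        return {
            "task": self.task.to_dict(),
            "oculomotor": self.oculomotor.to_dict(),
            "response": self.response.to_dict(),
            "pose_drift": self.pose_drift.to_dict(),
            "uks_noise": {
                "pos_rate": self.uks_noise.pos_rate,
                "rot_rate": self.uks_noise.rot_rate,
                "obs_sd": self.uks_noise.obs_sd,
                "mode": self.uks_noise.mode,
            },
            "segmentation": {
                "penalty": self.segmentation.penalty,
                "penalty_factor": self.segmentation.penalty_factor,
                "min_samples": self.segmentation.min_samples,
                "max_gap": self.segmentation.max_gap,
            },
            "camera": {
                "focal": self.camera.focal,
                "principal_point": list(self.camera.principal_point),
                "resolution": list(self.camera.resolution),
            },
            "confidence_threshold": self.confidence_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        if "task" in d:
            kwargs["task"] = TaskConfig.from_dict(d["task"])
        if "oculomotor" in d:
            kwargs["oculomotor"] = OculomotorParams.from_dict(d["oculomotor"])
        if "response" in d:
            kwargs["response"] = ResponseParams.from_dict(d["response"])
        if "pose_drift" in d:
            kwargs["pose_drift"] = PoseDriftParams.from_dict(d["pose_drift"])
        if "uks_noise" in d:
            kwargs["uks_noise"] = NoiseConfig(**d["uks_noise"])
        if "segmentation" in d:
            kwargs["segmentation"] = SegmentationConfig(**d["segmentation"])
        if "camera" in d:
            c = d["camera"]
            kwargs["camera"] = CameraModel(
                focal=c["focal"],
                principal_point=tuple(c["principal_point"]),
                resolution=tuple(c["resolution"]),
            )
        if "confidence_threshold" in d:
            kwargs["confidence_threshold"] = d["confidence_threshold"]
        return cls(**kwargs)


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))
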