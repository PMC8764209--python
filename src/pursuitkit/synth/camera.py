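"""Synthetic scene-camera stream: head-pose drift and marker detections.

The head (scene camera) follows a slow random walk around a seated resting
pose; the four screen-corner markers are projected through the pinhole
model with isotropic pixel noise, and a configurable fraction of markers
drop out per frame (emulating markers leaving the camera's field of view
or failed detections).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np
import pandas as pd

from ..geometry import TaskConfig
from ..headpose import CameraModel, default_camera, marker_layout, project_points

__all__ = ["PoseDriftParams", "simulate_camera"]


@dataclass
class PoseDriftParams:
    """Head-pose random-walk and marker-observation noise parameters."""

    base_position: Tuple[float, float, float] = (0.0, 0.0, 1.24)  # screen heights
    base_rotation: Tuple[float, float, float] = (0.0, 0.0, 0.0)   # radians
    pos_walk_sd: float = 0.01    # screen heights per sqrt(s), per axis
    rot_walk_sd: float = 0.01    # radians per sqrt(s), per axis
    obs_noise_px: float = 1.0    # pixel SD per corner coordinate
    dropout: float = 0.02        # per-marker per-frame drop probability
    frame_rate: float = 60.0     # Hz
    marker_size: float = 0.08    # screen heights

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PoseDriftParams":
        d = dict(d)
        for key in ("base_position", "base_rotation"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def simulate_camera(
    duration: float,
    pose_params: PoseDriftParams,
    cam: CameraModel,
    cfg: TaskConfig,
    seed=None,
):
    """Simulate marker-corner observations and the true pose trajectory.

    Returns
    -------
    markers : DataFrame (t, marker_id, corner_id, u_px, v_px); rows for
        dropped markers are absent.
    true_pose : DataFrame (t, x, y, z, yaw, pitch, roll)
    """
    if cam.focal <= 0:
        raise ValueError("invalid camera intrinsics")
    rng = np.random.default_rng(seed)
    dt = 1.0 / pose_params.frame_rate
    n = int(math.floor(duration / dt))
    times = np.arange(n) * dt

    base = np.array([*pose_params.base_position, *pose_params.base_rotation])
    steps = np.column_stack([
        rng.normal(0.0, pose_params.pos_walk_sd * math.sqrt(dt), (n, 3)),
        rng.normal(0.0, pose_params.rot_walk_sd * math.sqrt(dt), (n, 3)),
    ])
    steps[0] = 0.0
    poses = base + np.cumsum(steps, axis=0)

    layout = marker_layout(cfg, pose_params.marker_size)
    rows = []
    for i in range(n):
        for mid, corners in layout.items():
            if rng.random() < pose_params.dropout:
                continue
            uv, valid = project_points(poses[i], cam, corners)
            uv = uv + rng.normal(0.0, pose_params.obs_noise_px, uv.shape)
            for cid in range(4):
                if valid[cid]:
                    rows.append((times[i], mid, cid, uv[cid, 0], uv[cid, 1]))
    markers = pd.DataFrame(rows, columns=["t", "marker_id", "corner_id",
                                          "u_px", "v_px"])
    true_pose = pd.DataFrame(
        np.column_stack([times, poses]),
        columns=["t", "x", "y", "z", "yaw", "pitch", "roll"],
    )
    return markers, true_pose
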