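"""Deterministic model of the circular tracking task.

Defines the task configuration (trajectory and trial-schedule parameters),
the target's motion on the circle, conversions between screen pixels and
visual degrees, and the polar (phase/radius) decomposition of gaze positions
relative to the trajectory.

Conventions
-----------
* Screen coordinates in degrees have their origin at the circle/screen
  center, x rightward, y upward.
* The target moves clockwise; *phase* is measured in turns along the
  direction of motion, so phase increases as the standard mathematical
  angle decreases. Phase 0 lies on the positive x-axis.
* Pixel-to-degree conversion is the flat linear scaling ``px_to_deg``
  about the screen center (a deliberate small-angle approximation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Tuple

import numpy as np

__all__ = [
    "TaskConfig",
    "PolarPoint",
    "PolarDifference",
    "object_position",
    "object_phase",
    "tangential_speed",
    "px_to_degrees",
    "degrees_to_px",
    "polar_decompose",
    "polar_to_cartesian",
    "wrap_phase_diff",
    "polar_difference",
    "hypothetical_trajectory",
]


@dataclass(frozen=True)
class TaskConfig:
    """Trajectory geometry and trial-schedule timing.

    Defaults reproduce the reference task: a 13.5 degree radius circle
    traversed clockwise at 0.25 turns/s, visible durations uniform on
    [1, 2] s, occlusions uniform on [0, 3] s, a 0.05 s probe and a 1 s
    feedback period, on a 1920x1080 screen spanning 80 degrees
    horizontally.
    """

    radius: float = 13.5               # degrees
    angular_rate: float = 0.25         # turns per second
    center: Tuple[float, float] = (0.0, 0.0)  # degrees
    px_to_deg: float = 80.0 / 1920.0   # degrees per pixel
    screen_px: Tuple[int, int] = (1920, 1080)
    visible_range: Tuple[float, float] = (1.0, 2.0)    # seconds
    occlusion_range: Tuple[float, float] = (0.0, 3.0)  # seconds
    probe_duration: float = 0.05       # seconds
    feedback_duration: float = 1.0     # seconds
    phase0: float = 0.0                # turns, phase at t = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.angular_rate <= 0:
            raise ValueError("angular_rate must be positive")
        if self.px_to_deg <= 0:
            raise ValueError("px_to_deg must be positive")
        if self.occlusion_range[0] < 0:
            raise ValueError("occlusion_range lower bound must be >= 0")
        if self.visible_range[0] > self.visible_range[1]:
            raise ValueError("visible_range must be ordered")
        if self.occlusion_range[0] > self.occlusion_range[1]:
            raise ValueError("occlusion_range must be ordered")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        for key in ("center", "screen_px", "visible_range", "occlusion_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class PolarPoint:
    """Position in trajectory-polar coordinates.

    ``phase`` is in turns in [0, 1), measured along the direction of motion
    from the reference on the positive x-axis; NaN flags an undefined phase
    (point at the circle center). ``radius`` is degrees from the center.
    """

    phase: float
    radius: float


@dataclass(frozen=True)
class PolarDifference:
    """Gaze-minus-object error decomposed into polar components.

    ``phase_diff`` in turns, wrapped to (-0.5, 0.5]; positive means gaze is
    ahead of the object along the direction of motion. ``radius_diff`` in
    degrees, positive means gaze outside the circle. ``euclidean`` is the
    angular displacement between the Cartesian positions.
    """

    phase_diff: float
    radius_diff: float
    euclidean: float


def object_phase(t, cfg: TaskConfig):
    """Target phase (turns in [0, 1)) at time(s) ``t``."""
    return np.mod(cfg.phase0 + cfg.angular_rate * np.asarray(t, dtype=float), 1.0)


def object_position(t, cfg: TaskConfig):
    """Target screen position (degrees) and phase at time(s) ``t``.

    Returns ``(xy, phase)`` where xy has shape (..., 2). Clockwise motion:
    the Cartesian angle is minus the phase angle.
    """
    phase = object_phase(t, cfg)
    ang = 2.0 * math.pi * phase
    xy = np.stack(
        [
            cfg.center[0] + cfg.radius * np.cos(ang),
            cfg.center[1] - cfg.radius * np.sin(ang),
        ],
        axis=-1,
    )
    return xy, phase


def tangential_speed(cfg: TaskConfig) -> float:
    """Vectorial speed of the target along the circle, degrees per second."""
    return 2.0 * math.pi * cfg.radius * cfg.angular_rate


def px_to_degrees(px, cfg: TaskConfig):
    """Convert screen pixel coordinates to degrees about the screen center.

    Pixel origin is the top-left corner with v increasing downward; degree
    coordinates have y upward.
    """
    px = np.asarray(px, dtype=float)
    w, h = cfg.screen_px
    out = np.empty_like(px)
    out[..., 0] = (px[..., 0] - w / 2.0) * cfg.px_to_deg
    out[..., 1] = (h / 2.0 - px[..., 1]) * cfg.px_to_deg
    return out


def degrees_to_px(deg, cfg: TaskConfig):
    """Inverse of :func:`px_to_degrees`."""
    deg = np.asarray(deg, dtype=float)
    w, h = cfg.screen_px
    out = np.empty_like(deg)
    out[..., 0] = deg[..., 0] / cfg.px_to_deg + w / 2.0
    out[..., 1] = h / 2.0 - deg[..., 1] / cfg.px_to_deg
    return out


def polar_decompose(g, cfg: TaskConfig):
    """Decompose screen position(s) in degrees into (phase, radius) arrays.

    Phase follows the clockwise direction-of-motion convention. Points at
    the exact center get radius 0 and NaN phase (propagated as missing).
    """
    g = np.asarray(g, dtype=float)
    dx = g[..., 0] - cfg.center[0]
    dy = g[..., 1] - cfg.center[1]
    radius = np.hypot(dx, dy)
    with np.errstate(invalid="ignore"):
        phase = np.mod(-np.arctan2(dy, dx) / (2.0 * math.pi), 1.0)
    phase = np.where(radius == 0.0, np.nan, phase)
    return phase, radius


def polar_to_cartesian(phase, radius, cfg: TaskConfig):
    """Map (phase, radius) back to screen degrees."""
    ang = 2.0 * math.pi * np.asarray(phase, dtype=float)
    radius = np.asarray(radius, dtype=float)
    return np.stack(
        [
            cfg.center[0] + radius * np.cos(ang),
            cfg.center[1] - radius * np.sin(ang),
        ],
        axis=-1,
    )


def wrap_phase_diff(d):
    """Wrap phase difference(s) in turns to the interval (-0.5, 0.5]."""
    d = np.asarray(d, dtype=float)
    w = np.mod(d + 0.5, 1.0) - 0.5
    w = np.where(w == -0.5, 0.5, w)
    if w.ndim == 0:
        return float(w)
    return w


def polar_difference(gaze: PolarPoint, obj: PolarPoint, cfg: TaskConfig) -> PolarDifference:
    """Gaze-minus-object error in polar components.

    The Euclidean component is computed from the Cartesian positions, not
    from the polar residuals. An undefined gaze phase propagates to a NaN
    phase difference while the Euclidean error is still computed (gaze at
    center is a definite position).
    """
    radius_diff = gaze.radius - obj.radius
    if np.isnan(gaze.phase) or np.isnan(obj.phase):
        phase_diff = float("nan")
        g_xy = np.array([cfg.center]) if np.isnan(gaze.phase) else polar_to_cartesian(
            gaze.phase, gaze.radius, cfg
        )
    else:
        phase_diff = wrap_phase_diff(gaze.phase - obj.phase)
        g_xy = polar_to_cartesian(gaze.phase, gaze.radius, cfg)
    o_xy = polar_to_cartesian(obj.phase, obj.radius, cfg)
    euclidean = float(np.linalg.norm(np.asarray(g_xy) - np.asarray(o_xy)))
    return PolarDifference(phase_diff=float(phase_diff), radius_diff=float(radius_diff),
                           euclidean=euclidean)


HypotheticalKind = Literal["tangent", "stay", "center"]


def hypothetical_trajectory(
    kind: HypotheticalKind,
    times,
    cfg: TaskConfig,
    t_disappear: float = 0.0,
):
    """Baseline gaze trajectories for comparison with real occluded tracking.

    Parameters
    ----------
    kind:
        ``tangent`` — gaze continues along the straight path tangential to
        the motion at disappearance, at the tangential speed;
        ``stay`` — gaze remains at the disappearance point;
        ``center`` — gaze shifts to (and stays at) the circle center.
    times:
        Occlusion times in seconds relative to disappearance (>= 0).
    t_disappear:
        Absolute task time of disappearance (sets the disappearance phase).

    Returns
    -------
    positions : ndarray (n, 2)
        Hypothetical gaze positions in degrees.
    error : ndarray (n,)
        Distance to the (invisible) target at each time.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("occlusion times must be >= 0")
    p0, phase0 = object_position(t_disappear, cfg)
    if kind == "tangent":
        # instantaneous velocity at disappearance (clockwise)
        ang = 2.0 * math.pi * phase0
        v = 2.0 * math.pi * cfg.angular_rate * cfg.radius * np.array(
            [-math.sin(ang), -math.cos(ang)]
        )
        pos = p0[None, :] + times[:, None] * v[None, :]
    elif kind == "stay":
        pos = np.broadcast_to(p0, (times.size, 2)).copy()
    elif kind == "center":
        pos = np.broadcast_to(np.asarray(cfg.center, dtype=float), (times.size, 2)).copy()
    else:
        raise ValueError(f"unknown hypothetical trajectory kind: {kind!r}")
    target, _ = object_position(t_disappear + times, cfg)
    error = np.linalg.norm(pos - target, axis=-1)
    return pos, error
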