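"""Scene-camera pose estimation from fiducial-marker corners.

The forward-facing camera's pose is represented as a position ``[x, y, z]``
in screen heights relative to the screen center and a rotation
``[yaw, pitch, roll]`` in radians about the camera's optical center. The
observation model projects known marker corners on the screen plane through
a pinhole camera; pose over time is estimated with a forward unscented
Kalman filter followed by a backward (RTS) smoothing pass, using a
random-walk transition scaled by the frame interval.

World frame: origin at the screen center, x rightward, y upward, z out of
the screen toward the viewer; the screen is the plane z = 0. With identity
rotation the camera looks straight at the screen (camera z = world -z,
image v axis = world -y).

Smoothed poses are then used to map eye-tracker gaze points (in scene-
camera image pixels) to screen coordinates by ray/plane intersection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .geometry import TaskConfig

__all__ = [
    "PoseState",
    "CameraModel",
    "NoiseConfig",
    "default_camera",
    "marker_layout",
    "pose_matrices",
    "project_points",
    "project_markers",
    "fit_pose_frame",
    "ukf_filter",
    "uks_smooth",
    "frames_from_dataframe",
    "project_screen_point_to_camera",
    "map_gaze_to_screen",
    "screen_sh_to_px",
    "screen_px_to_sh",
]

logger = logging.getLogger(__name__)

_BASE = np.diag([1.0, -1.0, -1.0])  # camera->world axes at identity rotation


@dataclass(frozen=True)
class PoseState:
    """Camera pose: position (screen heights) and yaw/pitch/roll (radians)."""

    p: Tuple[float, float, float]
    rot: Tuple[float, float, float]

    def as_vector(self) -> np.ndarray:
        return np.array([*self.p, *self.rot], dtype=float)

    @classmethod
    def from_vector(cls, x) -> "PoseState":
        x = np.asarray(x, dtype=float)
        rot = tuple(float(_wrap_angle(a)) for a in x[3:6])
        return cls(p=tuple(float(v) for v in x[:3]), rot=rot)


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics in pixels."""

    focal: float
    principal_point: Tuple[float, float]
    resolution: Tuple[int, int]

    def __post_init__(self) -> None:
        if self.focal <= 0:
            raise ValueError("focal must be positive")


@dataclass(frozen=True)
class NoiseConfig:
    """UKS noise terms as printed: position/rotation transition rates and a
    spherical observation term.

    ``mode='sd'`` (default) reads the printed numbers as standard
    deviations (transition SD per sqrt-second); ``mode='var'`` reads them
    as variances per second.
    """

    pos_rate: float = 0.01    # screen heights (per axis, per s)
    rot_rate: float = 1.0     # radians (per axis, per s)
    obs_sd: float = 0.05      # screen heights (spherical), normalized image units
    mode: str = "sd"

    def __post_init__(self) -> None:
        if min(self.pos_rate, self.rot_rate, self.obs_sd) <= 0:
            raise ValueError("noise terms must be positive")
        if self.mode not in ("sd", "var"):
            raise ValueError("mode must be 'sd' or 'var'")

    def q_diag(self, dt: float) -> np.ndarray:
        if self.mode == "sd":
            return np.array([self.pos_rate ** 2] * 3 + [self.rot_rate ** 2] * 3) * dt
        return np.array([self.pos_rate] * 3 + [self.rot_rate] * 3) * dt

    @property
    def obs_var(self) -> float:
        return self.obs_sd ** 2 if self.mode == "sd" else self.obs_sd


def default_camera() -> CameraModel:
    """Synthetic scene-camera intrinsics: 60 deg horizontal FOV at 1280x720."""
    w, h = 1280, 720
    focal = (w / 2.0) / math.tan(math.radians(30.0))
    return CameraModel(focal=focal, principal_point=(w / 2.0, h / 2.0),
                       resolution=(w, h))


def marker_layout(cfg: TaskConfig, marker_size: float = 0.08) -> Dict[int, np.ndarray]:
    """World positions (screen heights, z=0) of the four corner markers.

    Marker centers sit at the four screen corners; each marker is a square
    of side ``marker_size`` with corners ordered 0..3 counterclockwise from
    the lower-left.
    """
    w_px, h_px = cfg.screen_px
    half_w = 0.5 * w_px / h_px
    s = marker_size / 2.0
    offsets = np.array([[-s, -s], [s, -s], [s, s], [-s, s]])
    centers = {
        0: (-half_w, -0.5),
        1: (half_w, -0.5),
        2: (half_w, 0.5),
        3: (-half_w, 0.5),
    }
    return {mid: np.column_stack([offsets + np.array(c), np.zeros(4)])
            for mid, c in centers.items()}


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def _rot_ypr(yaw: float, pitch: float, roll: float) -> np.ndarray:
    cy, sy = math.cos(yaw), math.sin(yaw)
    cp, sp = math.cos(pitch), math.sin(pitch)
    cr, sr = math.cos(roll), math.sin(roll)
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[1, 0, 0], [0, cp, -sp], [0, sp, cp]])
    rz = np.array([[cr, -sr, 0], [sr, cr, 0], [0, 0, 1]])
    return ry @ rx @ rz


def pose_matrices(x: np.ndarray):
    """Camera-to-world rotation and camera position from a pose vector."""
    c2w = _BASE @ _rot_ypr(x[3], x[4], x[5])
    return c2w, np.asarray(x[:3], dtype=float)


def project_points(x: np.ndarray, cam: CameraModel, world_pts: np.ndarray,
                   min_depth: float = 1e-6):
    """Pinhole projection of world points under a pose vector.

    Returns (uv pixels (m, 2), valid mask); points at or behind the
    projection plane are flagged invalid.
    """
    c2w, p = pose_matrices(np.asarray(x, dtype=float))
    pc = (np.asarray(world_pts, dtype=float) - p) @ c2w  # world->camera
    z = pc[:, 2]
    valid = z > min_depth
    zs = np.where(valid, z, min_depth)
    u = cam.focal * pc[:, 0] / zs + cam.principal_point[0]
    v = cam.focal * pc[:, 1] / zs + cam.principal_point[1]
    return np.column_stack([u, v]), valid


def project_markers(pose: PoseState, cam: CameraModel, marker_corners) :
    """Project marker corners (screen-plane points, screen heights) to image
    pixels. ``marker_corners`` may be (m, 2) on the z=0 plane or (m, 3)."""
    pts = np.asarray(marker_corners, dtype=float)
    if pts.shape[-1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    return project_points(pose.as_vector(), cam, pts)


def _normalized(uv: np.ndarray, cam: CameraModel) -> np.ndarray:
    return (uv - np.asarray(cam.principal_point)) / cam.focal


def fit_pose_frame(world_pts: np.ndarray, image_px: np.ndarray,
                   cam: CameraModel, x0: Optional[np.ndarray] = None) -> np.ndarray:
    """Least-squares single-frame pose fit (per-frame baseline, no smoothing)."""
    if x0 is None:
        x0 = np.array([0.0, 0.0, 1.2, 0.0, 0.0, 0.0])
    target = _normalized(np.asarray(image_px, dtype=float), cam).ravel()

    def resid(x):
        uv, valid = project_points(x, cam, world_pts)
        r = (_normalized(uv, cam).ravel() - target)
        return np.where(np.repeat(valid, 2), r, 1e3)

    sol = least_squares(resid, x0, method="lm", max_nfev=200)
    return sol.x


def _merwe_weights(n: int, alpha: float, beta: float, kappa: float):
    lam = alpha ** 2 * (n + kappa) - n
    wm = np.full(2 * n + 1, 0.5 / (n + lam))
    wc = wm.copy()
    wm[0] = lam / (n + lam)
    wc[0] = lam / (n + lam) + (1.0 - alpha ** 2 + beta)
    return lam, wm, wc


def _sigma_points(x: np.ndarray, P: np.ndarray, lam: float) -> np.ndarray:
    n = len(x)
    try:
        S = np.linalg.cholesky((n + lam) * P)
    except np.linalg.LinAlgError:
        # symmetrize and add jitter
        Pj = (P + P.T) / 2 + 1e-12 * np.eye(n)
        S = np.linalg.cholesky((n + lam) * Pj)
    pts = np.empty((2 * n + 1, n))
    pts[0] = x
    pts[1:n + 1] = x + S.T
    pts[n + 1:] = x - S.T
    return pts


def ukf_filter(
    frame_times: np.ndarray,
    frame_obs: Sequence[Optional[Tuple[np.ndarray, np.ndarray]]],
    noise: NoiseConfig,
    cam: CameraModel,
    x0: Optional[np.ndarray] = None,
    P0: Optional[np.ndarray] = None,
    alpha: float = 1e-3,
    beta: float = 2.0,
    kappa: float = 0.0,
):
    """Forward unscented Kalman filter over marker-corner observations.

    ``frame_obs[k]`` is ``(world_pts, image_px)`` for frame k, or None for a
    frame with no usable observations (prediction only). Returns filtered
    means, covariances, and one-step-ahead predicted means/covariances
    (needed by the smoother).
    """
    times = np.asarray(frame_times, dtype=float)
    if len(times) == 0 or all(o is None for o in frame_obs):
        raise ValueError("need at least one frame with observations")
    if np.any(np.diff(times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    n = 6
    lam, wm, wc = _merwe_weights(n, alpha, beta, kappa)
    if x0 is None:
        first = next(o for o in frame_obs if o is not None)
        x0 = fit_pose_frame(first[0], first[1], cam)
    if P0 is None:
        P0 = np.diag([0.05 ** 2] * 3 + [0.05 ** 2] * 3)
    x = np.asarray(x0, dtype=float).copy()
    P = np.asarray(P0, dtype=float).copy()

    nf = len(times)
    xf = np.empty((nf, n))
    Pf = np.empty((nf, n, n))
    xp = np.empty((nf, n))
    Pp = np.empty((nf, n, n))

    for k in range(nf):
        if k > 0:
            dt = times[k] - times[k - 1]
            P = P + np.diag(noise.q_diag(dt))
        xp[k] = x
        Pp[k] = P
        obs = frame_obs[k]
        if obs is not None:
            world_pts, image_px = obs
            finite = np.all(np.isfinite(image_px), axis=1)
            if not np.all(finite):
                logger.warning("frame %d: dropping %d non-finite observations",
                               k, int((~finite).sum()))
                world_pts, image_px = world_pts[finite], image_px[finite]
            if len(world_pts) > 0:
                z = _normalized(np.asarray(image_px, dtype=float), cam).ravel()
                chi = _sigma_points(x, P, lam)
                Z = np.empty((len(chi), 2 * len(world_pts)))
                for j, s in enumerate(chi):
                    uv, _ = project_points(s, cam, world_pts)
                    Z[j] = _normalized(uv, cam).ravel()
                zhat = wm @ Z
                dz = Z - zhat
                dx = chi - (wm @ chi)
                S = (dz.T * wc) @ dz + noise.obs_var * np.eye(len(z))
                Pxz = (dx.T * wc) @ dz
                K = np.linalg.solve(S.T, Pxz.T).T
                x = x + K @ (z - zhat)
                P = P - K @ S @ K.T
                P = (P + P.T) / 2
        xf[k] = x
        Pf[k] = P
    return xf, Pf, xp, Pp


def uks_smooth(
    frame_times: np.ndarray,
    frame_obs: Sequence[Optional[Tuple[np.ndarray, np.ndarray]]],
    noise: NoiseConfig,
    cam: CameraModel,
    **kwargs,
):
    """Unscented Kalman smoother: forward filter + backward RTS pass.

    With the identity random-walk transition the backward recursion is the
    linear Rauch-Tung-Striebel form. Returns (means (nf, 6), covariances
    (nf, 6, 6)); means are the per-frame pose estimates used downstream.
    """
    xf, Pf, xp, Pp = ukf_filter(frame_times, frame_obs, noise, cam, **kwargs)
    nf = len(xf)
    xs = xf.copy()
    Ps = Pf.copy()
    for k in range(nf - 2, -1, -1):
        G = np.linalg.solve(Pp[k + 1].T, Pf[k].T).T  # Pf[k] @ inv(Pp[k+1])
        xs[k] = xf[k] + G @ (xs[k + 1] - xp[k + 1])
        Ps[k] = Pf[k] + G @ (Ps[k + 1] - Pp[k + 1]) @ G.T
    return xs, Ps


def trajectory_log_likelihood(
    states: np.ndarray,
    frame_times: np.ndarray,
    frame_obs: Sequence[Optional[Tuple[np.ndarray, np.ndarray]]],
    noise: NoiseConfig,
    cam: CameraModel,
) -> float:
    """Joint log density of a pose trajectory and the observations under
    the random-walk transition and pinhole observation model (additive
    constants included, so values are comparable across trajectories)."""
    states = np.asarray(states, dtype=float)
    total = 0.0
    obs_var = noise.obs_var
    for k in range(len(states)):
        if k > 0:
            dt = frame_times[k] - frame_times[k - 1]
            q = noise.q_diag(dt)
            d = states[k] - states[k - 1]
            total += float(-0.5 * np.sum(d * d / q + np.log(2 * math.pi * q)))
        ob = frame_obs[k]
        if ob is None:
            continue
        world_pts, image_px = ob
        uv, valid = project_points(states[k], cam, world_pts)
        z = _normalized(np.asarray(image_px, dtype=float), cam)[valid]
        zh = _normalized(uv, cam)[valid]
        r = (z - zh).ravel()
        total += float(-0.5 * np.sum(r * r / obs_var
                                     + np.log(2 * math.pi * obs_var)))
    return total


def frames_from_dataframe(
    df: pd.DataFrame,
    layout: Dict[int, np.ndarray],
    frame_times: Optional[np.ndarray] = None,
):
    """Build per-frame observation tuples from a marker-observation table.

    ``df`` columns: t, marker_id, corner_id, u_px, v_px; missing rows are
    dropped corners. Returns (times, list of (world_pts, image_px) or None).
    """
    required = {"t", "marker_id", "corner_id", "u_px", "v_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker table must have columns {sorted(required)}")
    if frame_times is None:
        frame_times = np.array(sorted(df["t"].unique()), dtype=float)
    groups = {t: g for t, g in df.groupby("t")}
    obs = []
    for t in frame_times:
        g = groups.get(t)
        if g is None or len(g) == 0:
            obs.append(None)
            continue
        ids = g[["marker_id", "corner_id"]].to_numpy(dtype=int)
        keep = np.array([mid in layout for mid in ids[:, 0]])
        if not keep.any():
            obs.append(None)
            continue
        world = np.array([layout[mid][cid] for mid, cid in ids[keep]])
        image = g[["u_px", "v_px"]].to_numpy(dtype=float)[keep]
        obs.append((world, image))
    return np.asarray(frame_times, dtype=float), obs


def map_gaze_to_screen(gaze_px: np.ndarray, poses: np.ndarray,
                       cam: CameraModel, cfg: TaskConfig):
    """Map gaze image points to screen pixel coordinates via ray casting.

    Each gaze point is back-projected to a ray in camera coordinates,
    transformed to the world with the per-sample pose, and intersected with
    the screen plane z=0. Rays parallel to or pointing away from the screen
    are flagged invalid.

    Parameters
    ----------
    gaze_px : (n, 2) gaze points in scene-camera pixels
    poses : (n, 6) pose vectors, one per sample

    Returns
    -------
    screen_px : (n, 2) screen pixel coordinates (NaN where invalid)
    valid : (n,) boolean mask
    """
    gaze_px = np.atleast_2d(np.asarray(gaze_px, dtype=float))
    poses = np.atleast_2d(np.asarray(poses, dtype=float))
    n = len(gaze_px)
    out = np.full((n, 2), np.nan)
    valid = np.zeros(n, dtype=bool)
    d_cam = np.column_stack([_normalized(gaze_px, cam), np.ones(n)])
    for i in range(n):
        c2w, p = pose_matrices(poses[i])
        d = c2w @ d_cam[i]
        if abs(d[2]) < 1e-12:
            continue
        s = -p[2] / d[2]
        if s <= 0:
            continue
        hit = p + s * d
        out[i] = hit[:2]
        valid[i] = True
    return screen_sh_to_px(out, cfg), valid


def project_screen_point_to_camera(xy_sh: np.ndarray, pose: np.ndarray,
                                   cam: CameraModel):
    """Forward counterpart of :func:`map_gaze_to_screen` (screen-height
    coordinates on the z=0 plane to camera pixels)."""
    pts = np.atleast_2d(np.asarray(xy_sh, dtype=float))
    world = np.column_stack([pts, np.zeros(len(pts))])
    return project_points(np.asarray(pose, dtype=float), cam, world)


def screen_sh_to_px(xy_sh: np.ndarray, cfg: TaskConfig) -> np.ndarray:
    """Screen-height plane coordinates (origin center, y up) to pixels."""
    xy_sh = np.asarray(xy_sh, dtype=float)
    w, h = cfg.screen_px
    out = np.empty_like(xy_sh)
    out[..., 0] = xy_sh[..., 0] * h + w / 2.0
    out[..., 1] = h / 2.0 - xy_sh[..., 1] * h
    return out


def screen_px_to_sh(xy_px: np.ndarray, cfg: TaskConfig) -> np.ndarray:
    xy_px = np.asarray(xy_px, dtype=float)
    w, h = cfg.screen_px
    out = np.empty_like(xy_px)
    out[..., 0] = (xy_px[..., 0] - w / 2.0) / h
    out[..., 1] = (h / 2.0 - xy_px[..., 1]) / h
    return out
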