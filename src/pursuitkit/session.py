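"""Session file formats and synthetic-session generation.

Native formats (all times in float seconds on a single session clock):

* ``gaze.csv`` — t, u_px, v_px, confidence. The frame of u/v is recorded
  in ``events.json`` meta: ``screen`` (screen pixels, head-pose stage not
  needed) or ``camera`` (scene-camera pixels, mapped to the screen via the
  smoothed pose).
* ``markers.csv`` — t, marker_id, corner_id, u_px, v_px; missing rows are
  dropped corners.
* ``events.json`` — trial records plus meta (participant id, gaze frame).
* ``ground_truth.json`` — synthetic sessions only: true oculomotor events,
  true pose trajectory, per-trial internal drift rates.
* ``config.yaml`` — the full pipeline configuration.

A documented adapter for externally deposited raw-data layouts can map
onto this schema; only the native schema is handled here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig, load_config, save_config
from .geometry import degrees_to_px, object_position, px_to_degrees
from .headpose import project_screen_point_to_camera, screen_px_to_sh
from .synth import (
    OculomotorParams,
    PoseDriftParams,
    TrialRecord,
    generate_schedule,
    session_duration,
    simulate_camera,
    simulate_gaze,
    simulate_response,
)

__all__ = ["SessionBundle", "simulate_session", "write_session", "read_session"]


@dataclass
class SessionBundle:
    """In-memory typed contents of one recorded or synthetic session."""

    gaze: pd.DataFrame                  # t, u_px, v_px, confidence
    trials: List[TrialRecord]
    config: PipelineConfig
    participant_id: str = "p0"
    gaze_frame: str = "screen"          # "screen" | "camera"
    markers: Optional[pd.DataFrame] = None
    truth: Optional[dict] = None


def simulate_session(
    n_trials: int,
    config: Optional[PipelineConfig] = None,
    seed=0,
    participant_id: str = "p0",
    camera: bool = False,
) -> SessionBundle:
    """Generate a full synthetic session.

    With ``camera=True`` the gaze stream is expressed in scene-camera
    pixels (projected through a drifting head pose) and a marker stream is
    attached, exercising the head-pose stage; otherwise gaze is written
    directly in screen pixels.
    """
    config = config or PipelineConfig()
    cfg = config.task
    rng = np.random.default_rng(seed)
    trials = generate_schedule(n_trials, cfg, rng)
    samples, truth = simulate_gaze(trials, config.oculomotor, cfg, rng)

    # responses from the true gaze error at reappearance
    t = samples["t"].to_numpy()
    xy = samples[["x_deg", "y_deg"]].to_numpy()
    for tr in trials:
        i = min(np.searchsorted(t, tr.t_reappear), len(t) - 1)
        target, _ = object_position(tr.t_reappear, cfg)
        err = float(np.linalg.norm(xy[i] - target))
        simulate_response(tr, err, config.response, rng)

    screen_px = degrees_to_px(xy, cfg)
    markers = None
    gaze_frame = "screen"
    if camera:
        duration = session_duration(trials, cfg)
        markers, true_pose = simulate_camera(
            duration, config.pose_drift, config.camera, cfg, rng)
        truth["pose"] = true_pose.to_dict(orient="list")
        # express gaze in scene-camera pixels through the true pose
        pose_t = true_pose["t"].to_numpy()
        pose_v = true_pose[["x", "y", "z", "yaw", "pitch", "roll"]].to_numpy()
        gaze_sh = screen_px_to_sh(screen_px, cfg)
        cam_px = np.empty_like(screen_px)
        for i in range(len(t)):
            k = np.clip(np.searchsorted(pose_t, t[i]) - 1, 0, len(pose_t) - 1)
            # linear pose interpolation between camera frames
            if k + 1 < len(pose_t) and pose_t[k + 1] > pose_t[k]:
                u = (t[i] - pose_t[k]) / (pose_t[k + 1] - pose_t[k])
                u = min(max(u, 0.0), 1.0)
                pose = pose_v[k] * (1 - u) + pose_v[k + 1] * u
            else:
                pose = pose_v[k]
            uv, _ = project_screen_point_to_camera(gaze_sh[i], pose, config.camera)
            cam_px[i] = uv[0]
        screen_px = cam_px
        gaze_frame = "camera"

    gaze = pd.DataFrame({
        "t": t,
        "u_px": screen_px[:, 0],
        "v_px": screen_px[:, 1],
        "confidence": samples["confidence"].to_numpy(),
    })
    return SessionBundle(gaze=gaze, trials=trials, config=config,
                         participant_id=participant_id, gaze_frame=gaze_frame,
                         markers=markers, truth=truth)


def write_session(bundle: SessionBundle, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.gaze.to_csv(out / "gaze.csv", index=False)
    events = {
        "meta": {
            "participant_id": bundle.participant_id,
            "gaze_frame": bundle.gaze_frame,
        },
        "trials": [tr.to_dict() for tr in bundle.trials],
    }
    (out / "events.json").write_text(json.dumps(events, indent=1))
    if bundle.markers is not None:
        bundle.markers.to_csv(out / "markers.csv", index=False)
    if bundle.truth is not None:
        (out / "ground_truth.json").write_text(
            json.dumps(bundle.truth, indent=1, default=float))
    save_config(bundle.config, out / "config.yaml")
    return out


def _read_numeric_csv(path: Path, columns) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at data row "
                f"{row + 1}: {df[col].iloc[row]!r}")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise ValueError(f"{path}: empty value in column {col!r} at data "
                             f"row {row + 1}")
        df[col] = coerced
    return df


def read_session(session_dir) -> SessionBundle:
    """Load and validate a session directory in the native schema."""
    d = Path(session_dir)
    gaze = _read_numeric_csv(d / "gaze.csv", ["t", "u_px", "v_px", "confidence"])
    if len(gaze) == 0:
        raise ValueError(f"{d / 'gaze.csv'}: empty gaze stream")
    t = gaze["t"].to_numpy()
    if np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise ValueError(f"{d / 'gaze.csv'}: non-monotone timestamps at data "
                         f"row {row + 2}")
    events = json.loads((d / "events.json").read_text())
    trials = [TrialRecord.from_dict(tr) for tr in events["trials"]]
    for tr in trials:
        if not (tr.t_visible_on < tr.t_occl_on <= tr.t_reappear):
            raise ValueError(f"events.json: ill-ordered windows in trial "
                             f"{tr.trial_id}")
    meta = events.get("meta", {})
    markers = None
    markers_path = d / "markers.csv"
    if markers_path.exists():
        markers = _read_numeric_csv(
            markers_path, ["t", "marker_id", "corner_id", "u_px", "v_px"])
    truth = None
    truth_path = d / "ground_truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
    config = load_config(d / "config.yaml") if (d / "config.yaml").exists() \
        else PipelineConfig()
    return SessionBundle(
        gaze=gaze, trials=trials, config=config,
        participant_id=str(meta.get("participant_id", "p0")),
        gaze_frame=str(meta.get("gaze_frame", "screen")),
        markers=markers, truth=truth,
    )
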