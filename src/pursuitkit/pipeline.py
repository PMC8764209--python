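"""End-to-end analysis: head pose -> gaze mapping -> degrees -> filtering ->
segmentation -> classification -> visibility -> metrics.

Each stage's output can be persisted; the run is deterministic given the
session contents and configuration.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import px_to_degrees
from .headpose import (
    frames_from_dataframe,
    map_gaze_to_screen,
    marker_layout,
    uks_smooth,
)
from .metrics import (
    add_occlusion_relative_times,
    cumulative_phase_coverage,
    discrimination_summary,
    error_at_reappearance,
    error_timeseries,
    median_error_curves,
    pursuit_gain,
    saccade_anticipation,
    saccade_events_from_segments,
    uncertainty_accumulation,
)
from .segmentation import segment_session
from .session import SessionBundle

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


@_stage("headpose")
def _gaze_to_screen_px(bundle: SessionBundle) -> np.ndarray:
    """Gaze in screen pixels; maps via the smoothed pose when needed."""
    gaze_px = bundle.gaze[["u_px", "v_px"]].to_numpy(dtype=float)
    if bundle.gaze_frame == "screen":
        return gaze_px
    if bundle.markers is None or len(bundle.markers) == 0:
        raise ValueError("camera-frame gaze requires a marker stream")
    cfg = bundle.config
    layout = marker_layout(cfg.task, cfg.pose_drift.marker_size)
    times, obs = frames_from_dataframe(bundle.markers, layout)
    poses, _ = uks_smooth(times, obs, cfg.uks_noise, cfg.camera)
    # interpolate pose to gaze sample times
    gt = bundle.gaze["t"].to_numpy(dtype=float)
    pose_i = np.column_stack([
        np.interp(gt, times, poses[:, j]) for j in range(6)
    ])
    screen_px, valid = map_gaze_to_screen(gaze_px, pose_i, cfg.camera, cfg.task)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("gaze mapping: %d samples invalid (ray misses screen)",
                       n_bad)
    return screen_px


@_stage("metrics")
def _compute_metrics(segments: pd.DataFrame, denoised: pd.DataFrame,
                     bundle: SessionBundle) -> dict:
    cfg = bundle.config.task
    trials = bundle.trials
    events = saccade_events_from_segments(segments, cfg)
    events["participant"] = bundle.participant_id
    events = add_occlusion_relative_times(events, trials)

    vis_time = sum(tr.visible_duration for tr in trials)
    occ_time = sum(tr.occl_duration for tr in trials)
    n_vis = int((events["visibility"] == "visible").sum())
    n_occ = int((events["visibility"] == "occluded").sum())

    coverage = cumulative_phase_coverage(segments, trials, cfg)
    gains = pursuit_gain(segments, cfg)
    traces = error_timeseries(denoised, trials, cfg)
    med_curves = median_error_curves(traces, cfg) if len(traces) else pd.DataFrame()
    reapp = error_at_reappearance(denoised, trials, cfg)
    occl_reapp = reapp[reapp["occl_duration"] > 0] if len(reapp) else reapp

    def _share_median(period: str, col: str):
        sub = coverage[(coverage["period"] == period)][col].dropna()
        return float(sub.median()) if len(sub) else None

    uncertainty = uncertainty_accumulation(events) if n_occ else \
        {"curves": pd.DataFrame(), "phase": None, "radius": None}

    summary = {
        "participant_id": bundle.participant_id,
        "n_trials": len(trials),
        "saccade_rate": {
            "visible": n_vis / vis_time if vis_time > 0 else None,
            "occluded": n_occ / occ_time if occ_time > 0 else None,
        },
        "saccade_amplitude_median": {
            "visible": float(events.loc[events["visibility"] == "visible",
                                        "amplitude"].median()) if n_vis else None,
            "occluded": float(events.loc[events["visibility"] == "occluded",
                                         "amplitude"].median()) if n_occ else None,
        },
        "anticipation": saccade_anticipation(events),
        "coverage": {
            "pursuit_share_median": {
                "visible": _share_median("visible", "pursuit_share"),
                "occluded": _share_median("occluded", "pursuit_share"),
            },
            "share_at_probe_median": {
                "visible": _share_median("visible", "share_at_probe"),
                "occluded": _share_median("occluded", "share_at_probe"),
            },
        },
        "pursuit_gain_median": {
            "visible": float(gains.loc[gains["visibility"] == "visible",
                                       "gain"].median())
            if (gains["visibility"] == "visible").any() else None,
            "occluded": float(gains.loc[gains["visibility"] == "occluded",
                                        "gain"].median())
            if (gains["visibility"] == "occluded").any() else None,
        },
        "reappearance_error": {
            "euclidean_mean": float(occl_reapp["euclidean"].mean())
            if len(occl_reapp) else None,
            "abs_phase_mean": float(occl_reapp["phase_diff"].abs().mean())
            if len(occl_reapp) else None,
            "abs_radius_mean": float(occl_reapp["radius_diff"].abs().mean())
            if len(occl_reapp) else None,
        },
        "discrimination": discrimination_summary(trials, reapp),
        "uncertainty": {
            comp: uncertainty[comp] for comp in ("phase", "radius")
        },
        "counts": {
            "segments": int(len(segments)),
            "saccades_visible": n_vis,
            "saccades_occluded": n_occ,
        },
    }
    tables = {
        "segments": segments,
        "denoised": denoised,
        "saccade_events": events,
        "coverage": coverage,
        "gains": gains,
        "error_traces": traces,
        "median_error_curves": med_curves,
        "reappearance_errors": reapp,
        "uncertainty_curves": uncertainty["curves"],
    }
    return {"summary": summary, "tables": tables}


def run_pipeline(bundle: SessionBundle, out_dir=None) -> dict:
    """Run the full analysis on one session.

    Returns ``{"summary": dict, "tables": {name: DataFrame}}`` and, if
    ``out_dir`` is given, writes each table as CSV plus ``summary.json``.
    """
    screen_px = _gaze_to_screen_px(bundle)
    cfg = bundle.config
    deg = px_to_degrees(screen_px, cfg.task)
    samples = pd.DataFrame({
        "t": bundle.gaze["t"].to_numpy(dtype=float),
        "x_deg": deg[:, 0],
        "y_deg": deg[:, 1],
        "confidence": bundle.gaze["confidence"].to_numpy(dtype=float),
    })
    samples = samples[np.isfinite(samples["x_deg"])
                      & np.isfinite(samples["y_deg"])].reset_index(drop=True)
    try:
        segments, denoised = segment_session(
            samples, bundle.trials, cfg.segmentation,
            conf_threshold=cfg.confidence_threshold)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("segmentation", str(exc)) from exc
    result = _compute_metrics(segments, denoised, bundle)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in result["tables"].items():
            table.to_csv(out / f"{name}.csv", index=False, float_format="%.9g")
        (out / "summary.json").write_text(
            json.dumps(result["summary"], indent=1, sort_keys=True,
                       default=float))
    return result
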