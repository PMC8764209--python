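"""Generative model of oculomotor tracking behavior for the circular task.

Visible periods are tracked by smooth pursuit at a configurable gain with
Poisson-rate catch-up saccades that land on the target. During occlusion,
after a reaction latency, tracking becomes a sequence of anticipatory
saccades: each saccade lands a configurable phase lead ahead of an internal
estimate of target position, gaze then dwells (near-zero-gain pursuit /
fixation) until the estimated target catches up, and the cycle repeats.

The internal phase estimate accrues random error over the occlusion —
either a per-trial random drift rate (SD of the error grows linearly in
time; default, matching a linear regression readout) or a Gaussian random
walk (SD grows with sqrt(time)). The radius estimate is re-anchored at
each saccade landing with independent noise, so radius error does not
accumulate. This dissociation (phase uncertainty accumulating while radius
uncertainty plateaus) is the headline structure the analysis must recover.

Saccade durations follow a main-sequence-like linear rule (21 ms + 2.2
ms/deg) so the segmenter sees realistic slopes; intra-saccadic position is
linearly interpolated.

Note: inter-saccadic dwell timing during occlusion is derived from the
configured occluded saccade rate (the underlying interval distribution is
not constrained by data; the near-constant dwell with Gaussian jitter used
here is a modeling choice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ..geometry import TaskConfig, object_phase, polar_to_cartesian
from .schedule import TrialRecord, session_duration

__all__ = ["OculomotorParams", "simulate_gaze"]

SACCADE_DUR_INTERCEPT = 0.021   # s
SACCADE_DUR_SLOPE = 0.0022      # s per degree


@dataclass
class OculomotorParams:
    """Parameters of the synthetic oculomotor behavior.

    ``visible_saccade_amp`` is the expected median catch-up amplitude; it
    is emergent (≈ (1 - visible_gain) * tangential speed / saccade rate)
    and recorded here for documentation and diagnostics.
    """

    visible_gain: float = 0.87
    visible_saccade_rate: float = 1.49          # per second
    visible_saccade_amp: float = 1.83           # degrees, expected median
    occl_latency_range: Tuple[float, float] = (0.2, 0.5)  # s
    occl_saccade_rate: float = 2.88             # per second
    anticipation_lead: float = 0.05             # turns
    phase_drift_sd_rate: float = 0.025          # turns/s (linear) or turns/sqrt(s) (walk)
    drift_mode: str = "linear"                  # "linear" | "walk"
    radius_anchor_sd: float = 1.5               # degrees
    occl_gain: float = 0.05                     # pursuit gain between anticipatory saccades
    measurement_noise_sd: float = 0.15          # degrees per axis
    low_conf_fraction: float = 0.005
    visible_land_phase_sd: float = 0.004        # turns
    visible_land_radius_sd: float = 0.3         # degrees
    min_saccade_amp: float = 1.0                # degrees; smaller catch-ups overshoot
    occl_land_phase_sd: float = 0.01            # turns
    dwell_jitter_sd: float = 0.05               # s
    reappear_catchup_range: Tuple[float, float] = (0.15, 0.3)  # s
    radius_relax_tau: float = 0.4               # s, visible radius relaxation
    sample_rate: float = 120.0                  # Hz

    def __post_init__(self) -> None:
        if not (0.0 <= self.visible_gain <= 1.5 and 0.0 <= self.occl_gain <= 1.5):
            raise ValueError("gains must lie in [0, 1.5]")
        if self.visible_saccade_rate < 0 or self.occl_saccade_rate < 0:
            raise ValueError("saccade rates must be >= 0")
        if not (0.0 <= self.low_conf_fraction < 1.0):
            raise ValueError("low_conf_fraction must lie in [0, 1)")
        if self.drift_mode not in ("linear", "walk"):
            raise ValueError("drift_mode must be 'linear' or 'walk'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OculomotorParams":
        d = dict(d)
        for key in ("occl_latency_range", "reappear_catchup_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def saccade_duration(amplitude_deg: float) -> float:
    """Main-sequence-like duration rule."""
    return SACCADE_DUR_INTERCEPT + SACCADE_DUR_SLOPE * abs(amplitude_deg)


def simulate_gaze(
    schedule: List[TrialRecord],
    params: OculomotorParams,
    cfg: TaskConfig,
    seed=None,
):
    """Simulate a gaze trace over a whole session.

    Returns
    -------
    samples : DataFrame with columns t, x_deg, y_deg, confidence
    truth : dict with ground-truth ``saccades`` (list of interval dicts),
        ``events`` (full saccade / pursuit_fixation partition of the trace)
        and ``drift_rate_per_trial`` (internal phase-drift rate per trial,
        linear mode only).
    """
    if not schedule:
        raise ValueError("schedule must be nonempty")
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.sample_rate
    T = session_duration(schedule, cfg)
    n = int(math.floor(T / dt))
    times = np.arange(n) * dt
    f = cfg.angular_rate
    R = cfg.radius

    # dwell between anticipatory landing and next launch, chosen so that
    # the inter-saccade interval matches the configured occluded rate
    if params.occl_saccade_rate > 0:
        mean_interval = 1.0 / params.occl_saccade_rate
        travel = params.anticipation_lead / f
        mean_sac_dur = saccade_duration(
            2.0 * math.pi * R * params.anticipation_lead)
        dwell_mean = max(0.0, mean_interval - travel - mean_sac_dur)
    else:
        dwell_mean = math.inf

    xy = np.empty((n, 2))
    mode = "pursuit"
    gaze_phase = cfg.phase0
    gaze_radius = R
    sac: Optional[dict] = None
    next_sac_t = (rng.exponential(1.0 / params.visible_saccade_rate)
                  if params.visible_saccade_rate > 0 else math.inf)

    trial_idx = 0
    in_occlusion = False
    latency_end = math.inf
    pending_first_antic = False
    drift_rate = 0.0
    walk_err = 0.0
    drift_rates: Dict[int, float] = {}
    saccade_events: List[dict] = []

    def current_trial(t: float) -> Optional[TrialRecord]:
        nonlocal trial_idx
        while (trial_idx + 1 < len(schedule)
               and t >= schedule[trial_idx + 1].t_visible_on):
            trial_idx += 1
        return schedule[trial_idx]

    def period_of(t: float, tr: TrialRecord) -> str:
        if t < tr.t_occl_on:
            return "visible"
        if t < tr.t_reappear:
            return "occluded"
        return "post"

    def internal_phase_error(t: float, tr: TrialRecord) -> float:
        if params.drift_mode == "linear":
            return drift_rate * (t - tr.t_occl_on)
        return walk_err

    def gaze_xy() -> np.ndarray:
        return polar_to_cartesian(gaze_phase, gaze_radius, cfg)

    def launch_saccade(t: float, land_phase: float, land_radius: float,
                       period: str, tr: TrialRecord) -> None:
        nonlocal mode, sac
        p0 = gaze_xy()
        p1 = polar_to_cartesian(land_phase, land_radius, cfg)
        amp = float(np.linalg.norm(p1 - p0))
        if 0 < amp < params.min_saccade_amp:
            # stretch to the minimum amplitude along the saccade direction
            p1 = p0 + (p1 - p0) * (params.min_saccade_amp / amp)
            amp = params.min_saccade_amp
            dx = p1[0] - cfg.center[0]
            dy = p1[1] - cfg.center[1]
            land_radius = float(np.hypot(dx, dy))
            land_phase = float(np.mod(-np.arctan2(dy, dx) / (2.0 * math.pi), 1.0))
        dur = saccade_duration(amp)
        sac = {
            "t_start": t, "t_end": t + dur,
            "p0": p0, "p1": p1,
            "land_phase": land_phase, "land_radius": land_radius,
            "trial_id": tr.trial_id, "period": period,
            "amplitude": amp,
        }
        mode = "saccade"

    for i in range(n):
        t = times[i]
        tr = current_trial(t)
        period = period_of(t, tr)

        if period == "occluded" and not in_occlusion:
            in_occlusion = True
            latency_end = tr.t_occl_on + rng.uniform(*params.occl_latency_range)
            pending_first_antic = params.occl_saccade_rate > 0
            drift_rate = rng.normal(0.0, params.phase_drift_sd_rate)
            drift_rates[tr.trial_id] = drift_rate
            walk_err = 0.0
            next_sac_t = math.inf  # visible Poisson clock paused
        elif period != "occluded" and in_occlusion:
            in_occlusion = False
            latency_end = math.inf
            pending_first_antic = False
            if params.visible_saccade_rate > 0:
                # catch-up shortly after reappearance, Poisson afterwards
                next_sac_t = t + rng.uniform(*params.reappear_catchup_range)
            else:
                next_sac_t = math.inf

        if in_occlusion and params.drift_mode == "walk":
            walk_err += rng.normal(0.0, params.phase_drift_sd_rate * math.sqrt(dt))

        if mode == "saccade":
            if t < sac["t_end"]:
                u = (t - sac["t_start"]) / (sac["t_end"] - sac["t_start"])
                xy[i] = sac["p0"] + u * (sac["p1"] - sac["p0"])
                continue
            # saccade complete
            gaze_phase = sac["land_phase"]
            gaze_radius = sac["land_radius"]
            saccade_events.append({
                "t_start": sac["t_start"], "t_end": sac["t_end"],
                "x0": float(sac["p0"][0]), "y0": float(sac["p0"][1]),
                "x1": float(sac["p1"][0]), "y1": float(sac["p1"][1]),
                "amplitude": sac["amplitude"],
                "trial_id": sac["trial_id"], "period": sac["period"],
            })
            was_occluded = sac["period"] == "occluded"
            sac = None
            mode = "pursuit"
            if in_occlusion and was_occluded:
                dwell = params.anticipation_lead / f + dwell_mean \
                    + rng.normal(0.0, params.dwell_jitter_sd)
                next_sac_t = t + max(dwell, 0.05)
            elif params.visible_saccade_rate > 0:
                next_sac_t = t + rng.exponential(1.0 / params.visible_saccade_rate)
            else:
                next_sac_t = math.inf

        trigger = t >= next_sac_t
        if in_occlusion and pending_first_antic and t >= latency_end:
            trigger = True
            pending_first_antic = False
        if trigger and params.occl_saccade_rate == 0 and in_occlusion:
            trigger = False

        if trigger:
            if in_occlusion and t >= latency_end:
                est = object_phase(t, cfg) + internal_phase_error(t, tr)
                # land ahead of the internal estimate, projected to landing time
                land_phase = float(est) + params.anticipation_lead \
                    + rng.normal(0.0, params.occl_land_phase_sd)
                land_radius = R + rng.normal(0.0, params.radius_anchor_sd)
            else:
                amp_guess = float(np.linalg.norm(
                    polar_to_cartesian(object_phase(t, cfg), R, cfg) - gaze_xy()))
                t_land = t + saccade_duration(max(amp_guess, params.min_saccade_amp))
                land_phase = float(object_phase(t_land, cfg)) \
                    + rng.normal(0.0, params.visible_land_phase_sd)
                if amp_guess < params.min_saccade_amp:
                    # overshoot ahead of the target to a minimum amplitude
                    land_phase += (params.min_saccade_amp - amp_guess) \
                        / (2.0 * math.pi * R)
                land_radius = R + rng.normal(0.0, params.visible_land_radius_sd)
            launch_saccade(t, land_phase, land_radius, period, tr)
            u = 0.0 if sac["t_end"] == sac["t_start"] else \
                (t - sac["t_start"]) / (sac["t_end"] - sac["t_start"])
            xy[i] = sac["p0"] + u * (sac["p1"] - sac["p0"])
            continue

        # emit the current position, then integrate pursuit/fixation
        # dynamics forward to the next sample
        xy[i] = gaze_xy()
        if in_occlusion and t >= latency_end and params.occl_saccade_rate > 0:
            gaze_phase += params.occl_gain * f * dt
        else:
            gaze_phase += params.visible_gain * f * dt
            if not in_occlusion:
                gaze_radius += (R - gaze_radius) * dt / params.radius_relax_tau

    # measurement noise and confidence
    noisy = xy + rng.normal(0.0, params.measurement_noise_sd, size=xy.shape)
    conf = rng.uniform(0.95, 1.0, size=n)
    low = rng.random(n) < params.low_conf_fraction
    conf[low] = rng.uniform(0.0, 0.79, size=int(low.sum()))

    samples = pd.DataFrame({
        "t": times,
        "x_deg": noisy[:, 0],
        "y_deg": noisy[:, 1],
        "confidence": conf,
    })

    events = _partition_events(saccade_events, times[0], times[-1] + dt)
    truth = {
        "saccades": saccade_events,
        "events": events,
        "drift_rate_per_trial": {str(k): v for k, v in drift_rates.items()},
    }
    return samples, truth


def _partition_events(saccades: List[dict], t0: float, t1: float) -> List[dict]:
    """Full partition of [t0, t1] into saccade and pursuit_fixation events."""
    events: List[dict] = []
    cur = t0
    for s in sorted(saccades, key=lambda s: s["t_start"]):
        if s["t_start"] > cur:
            events.append({"t_start": cur, "t_end": s["t_start"],
                           "class": "pursuit_fixation"})
        events.append({"t_start": s["t_start"], "t_end": s["t_end"],
                       "class": "saccade"})
        cur = s["t_end"]
    if cur < t1:
        events.append({"t_start": cur, "t_end": t1, "class": "pursuit_fixation"})
    return events
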