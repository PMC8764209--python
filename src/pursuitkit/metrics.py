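"""Headline statistics of occluded circular tracking.

All phase quantities are in turns, radii and Euclidean errors in degrees.
Positional error is the degree-coordinate Euclidean displacement between
gaze and target (flat pixel-to-degree approximation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    TaskConfig,
    hypothetical_trajectory,
    object_phase,
    object_position,
    polar_decompose,
    wrap_phase_diff,
)
from .synth.schedule import TrialRecord

__all__ = [
    "binom_test_exact",
    "saccade_events_from_segments",
    "saccade_anticipation",
    "error_timeseries",
    "cumulative_phase_coverage",
    "pursuit_gain",
    "discrimination_summary",
    "uncertainty_accumulation",
    "add_occlusion_relative_times",
    "median_error_curves",
    "error_at_reappearance",
]

logger = logging.getLogger(__name__)


def binom_test_exact(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value.

    Sums the probability of all outcomes whose likelihood under
    Binomial(n, p0) does not exceed that of the observed count (with a
    small relative tolerance against floating-point ties).
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    return float(np.sum(pmf[pmf <= pmf[k] * (1.0 + 1e-9)]))


def _gaze_phase_radius(x, y, cfg: TaskConfig):
    phase, radius = polar_decompose(np.column_stack([x, y]), cfg)
    return phase, radius


def saccade_events_from_segments(segments: pd.DataFrame,
                                 cfg: TaskConfig) -> pd.DataFrame:
    """Launch/landing polar differences for each saccade segment.

    Positions come from the fitted (denoised) segment endpoints. Returns a
    table with one row per saccade: times, signed phase/radius differences
    at launch and landing, amplitude, visibility and trial_id.
    """
    sac = segments[segments["class"] == "saccade"]
    if len(sac) == 0:
        return pd.DataFrame(columns=[
            "t_launch", "t_land", "launch_phase_diff", "land_phase_diff",
            "launch_radius_diff", "land_radius_diff", "amplitude",
            "visibility", "trial_id"])
    gp0, gr0 = _gaze_phase_radius(sac["x0"], sac["y0"], cfg)
    gp1, gr1 = _gaze_phase_radius(sac["x1"], sac["y1"], cfg)
    op0 = object_phase(sac["t_start"].to_numpy(), cfg)
    op1 = object_phase(sac["t_end"].to_numpy(), cfg)
    return pd.DataFrame({
        "t_launch": sac["t_start"].to_numpy(),
        "t_land": sac["t_end"].to_numpy(),
        "launch_phase_diff": wrap_phase_diff(gp0 - op0),
        "land_phase_diff": wrap_phase_diff(gp1 - op1),
        "launch_radius_diff": gr0 - cfg.radius,
        "land_radius_diff": gr1 - cfg.radius,
        "amplitude": sac["amplitude"].to_numpy(),
        "visibility": sac["visibility"].to_numpy(),
        "trial_id": sac["trial_id"].to_numpy(),
    })


def saccade_anticipation(events: pd.DataFrame,
                         participant_col: str = "participant") -> dict:
    """Launch/landing phase-difference medians and the landing-vs-launch
    binomial test.

    Medians (signed and absolute) are reported separately for visible and
    occluded saccades. For each participant, the indicator is whether the
    median |phase difference| at landing exceeds that at launch for
    occluded saccades; the indicators feed an exact two-sided binomial
    test against 0.5.
    """
    out: dict = {"medians": {}}
    for visibility in ("visible", "occluded"):
        sub = events[events["visibility"] == visibility]
        if len(sub) == 0:
            out["medians"][visibility] = None
            continue
        out["medians"][visibility] = {
            "launch_signed": float(sub["launch_phase_diff"].median()),
            "land_signed": float(sub["land_phase_diff"].median()),
            "launch_abs": float(sub["launch_phase_diff"].abs().median()),
            "land_abs": float(sub["land_phase_diff"].abs().median()),
            "n": int(len(sub)),
        }
    if participant_col in events.columns:
        occl = events[events["visibility"] == "occluded"]
        flags = []
        for pid, grp in occl.groupby(participant_col):
            if len(grp) == 0:
                continue
            flags.append(grp["land_phase_diff"].abs().median()
                         > grp["launch_phase_diff"].abs().median())
        if flags:
            k = int(sum(flags))
            n = len(flags)
            out["landing_gt_launch"] = {
                "k": k, "n": n, "p_value": binom_test_exact(k, n, 0.5)}
    return out


def error_timeseries(
    denoised: pd.DataFrame,
    trials: Sequence[TrialRecord],
    cfg: TaskConfig,
    rate: float = 60.0,
    t_range: Tuple[float, float] = (-2.0, 3.0),
) -> pd.DataFrame:
    """Per-trial polar error traces on a uniform grid around occlusion onset.

    Gaze is the denoised (piecewise-linear fitted) signal, linearly
    interpolated to ``rate`` samples per second; t=0 is occlusion onset.
    Grid points outside the trial's observed span (visible onset to
    reappearance) are missing — no extrapolation.
    """
    t = denoised["t"].to_numpy(dtype=float)
    gx = denoised["x_fit"].to_numpy(dtype=float)
    gy = denoised["y_fit"].to_numpy(dtype=float)
    grid = np.arange(round(t_range[0] * rate), round(t_range[1] * rate) + 1) / rate
    rows = []
    for tr in trials:
        tt = tr.t_occl_on + grid
        ok = (tt >= max(tr.t_visible_on, t[0])) & (tt <= min(tr.t_reappear, t[-1]))
        if not ok.any():
            continue
        xi = np.interp(tt[ok], t, gx)
        yi = np.interp(tt[ok], t, gy)
        target, tphase = object_position(tt[ok], cfg)
        gphase, gradius = polar_decompose(np.column_stack([xi, yi]), cfg)
        eu = np.linalg.norm(np.column_stack([xi, yi]) - target, axis=1)
        rows.append(pd.DataFrame({
            "trial_id": tr.trial_id,
            "t_rel": grid[ok],
            "euclidean": eu,
            "phase_diff": wrap_phase_diff(gphase - tphase),
            "radius_diff": gradius - cfg.radius,
        }))
    if not rows:
        return pd.DataFrame(columns=["trial_id", "t_rel", "euclidean",
                                     "phase_diff", "radius_diff"])
    return pd.concat(rows, ignore_index=True)


def median_error_curves(traces: pd.DataFrame, cfg: TaskConfig) -> pd.DataFrame:
    """Median error across trials per time point, with the three
    hypothetical-baseline curves for reference (occluded part only)."""
    med = traces.groupby("t_rel")[["euclidean", "phase_diff", "radius_diff"]] \
        .median().reset_index()
    tpos = med["t_rel"].to_numpy()
    occl = tpos >= 0
    for kind in ("tangent", "stay", "center"):
        col = np.full(len(med), np.nan)
        if occl.any():
            _, err = hypothetical_trajectory(kind, tpos[occl], cfg)
            col[occl] = err
        med[f"baseline_{kind}"] = col
    return med


def error_at_reappearance(
    denoised: pd.DataFrame,
    trials: Sequence[TrialRecord],
    cfg: TaskConfig,
) -> pd.DataFrame:
    """Interpolated polar error exactly at each trial's reappearance time."""
    t = denoised["t"].to_numpy(dtype=float)
    gx = denoised["x_fit"].to_numpy(dtype=float)
    gy = denoised["y_fit"].to_numpy(dtype=float)
    rows = []
    for tr in trials:
        tt = tr.t_reappear
        if tt < t[0] or tt > t[-1]:
            continue
        xi = np.interp(tt, t, gx)
        yi = np.interp(tt, t, gy)
        target, tphase = object_position(tt, cfg)
        gphase, gradius = polar_decompose(np.array([xi, yi]), cfg)
        rows.append({
            "trial_id": tr.trial_id,
            "occl_duration": tr.occl_duration,
            "euclidean": float(np.hypot(xi - target[0], yi - target[1])),
            "phase_diff": float(wrap_phase_diff(gphase - tphase)),
            "radius_diff": float(gradius - cfg.radius),
            "correct": tr.correct,
        })
    return pd.DataFrame(rows)


def _segment_phase_delta(segments: pd.DataFrame, cfg: TaskConfig) -> np.ndarray:
    """Signed phase change of each segment from its fitted endpoints,
    wrapped assuming no segment covers more than half a turn."""
    gp0, _ = _gaze_phase_radius(segments["x0"], segments["y0"], cfg)
    gp1, _ = _gaze_phase_radius(segments["x1"], segments["y1"], cfg)
    return wrap_phase_diff(gp1 - gp0)


def cumulative_phase_coverage(
    segments: pd.DataFrame,
    trials: Sequence[TrialRecord],
    cfg: TaskConfig,
    probe_time: float = 1.5,
) -> pd.DataFrame:
    """Per trial and period, the phase covered by pursuit vs saccades.

    For each trial's visible and occluded window, signed per-segment phase
    deltas are accumulated by class (segments partially overlapping the
    window or the probe-time cutoff are pro-rated linearly in time).
    ``pursuit_share`` is pursuit phase over total phase; the share at the
    probe time (``share_at_probe``) is reported only for periods at least
    ``probe_time`` long.
    """
    segs = segments.copy()
    segs["phase_delta"] = _segment_phase_delta(segs, cfg)
    rows = []
    for tr in trials:
        for period, (w0, w1) in (
            ("visible", (tr.t_visible_on, tr.t_occl_on)),
            ("occluded", (tr.t_occl_on, tr.t_reappear)),
        ):
            if w1 - w0 <= 0:
                continue
            ov = segs[(segs["t_start"] < w1) & (segs["t_end"] > w0)]
            totals: Dict[str, float] = {"pursuit_fixation": 0.0, "saccade": 0.0}
            totals_probe: Dict[str, float] = {"pursuit_fixation": 0.0, "saccade": 0.0}
            for _, s in ov.iterrows():
                dur = s["t_end"] - s["t_start"]
                if dur <= 0:
                    continue
                frac = (min(s["t_end"], w1) - max(s["t_start"], w0)) / dur
                totals[s["class"]] += s["phase_delta"] * frac
                cut = min(w1, w0 + probe_time)
                frac_p = (min(s["t_end"], cut) - max(s["t_start"], w0)) / dur
                if frac_p > 0:
                    totals_probe[s["class"]] += s["phase_delta"] * frac_p
            total = totals["pursuit_fixation"] + totals["saccade"]
            row = {
                "trial_id": tr.trial_id, "period": period,
                "duration": w1 - w0,
                "pursuit_phase": totals["pursuit_fixation"],
                "saccade_phase": totals["saccade"],
                "total_phase": total,
                "pursuit_share": totals["pursuit_fixation"] / total
                if total != 0 else np.nan,
            }
            if w1 - w0 >= probe_time:
                tp = totals_probe["pursuit_fixation"] + totals_probe["saccade"]
                row["share_at_probe"] = totals_probe["pursuit_fixation"] / tp \
                    if tp != 0 else np.nan
            else:
                row["share_at_probe"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def pursuit_gain(segments: pd.DataFrame, cfg: TaskConfig) -> pd.DataFrame:
    """Gain of each pursuit/fixation segment: gaze phase change over object
    phase change in the same interval."""
    pur = segments[(segments["class"] == "pursuit_fixation")
                   & (segments["duration"] > 0)].copy()
    if len(pur) == 0:
        return pd.DataFrame(columns=["t_start", "t_end", "gain", "visibility",
                                     "trial_id"])
    delta = _segment_phase_delta(pur, cfg)
    obj_delta = cfg.angular_rate * pur["duration"].to_numpy()
    pur["gain"] = delta / obj_delta
    return pur[["t_start", "t_end", "duration", "gain", "visibility",
                "trial_id"]].reset_index(drop=True)


def discrimination_summary(trials: Sequence[TrialRecord],
                           reappear_errors: Optional[pd.DataFrame] = None,
                           error_threshold: float = 1.5,
                           occl_threshold: float = 1.0) -> dict:
    """Success rates overall and stratified by gaze error and occlusion
    duration, plus mean error by correctness."""
    answered = [tr for tr in trials if tr.correct is not None]
    if not answered:
        return {"overall": None}
    correct = np.array([tr.correct for tr in answered], dtype=bool)
    occl = np.array([tr.occl_duration for tr in answered])
    out = {
        "overall": float(correct.mean()),
        "n": len(answered),
        "by_occlusion": {
            "short": _rate(correct[occl <= occl_threshold]),
            "long": _rate(correct[occl > occl_threshold]),
        },
    }
    if reappear_errors is not None and len(reappear_errors):
        err = reappear_errors.set_index("trial_id")["euclidean"]
        ids = [tr.trial_id for tr in answered]
        have = [i for i in ids if i in err.index]
        e = err.loc[have].to_numpy()
        c = np.array([tr.correct for tr in answered if tr.trial_id in err.index],
                     dtype=bool)
        out["by_error"] = {
            "near": _rate(c[e <= error_threshold]),
            "far": _rate(c[e > error_threshold]),
        }
        out["mean_error"] = {
            "correct": float(e[c].mean()) if c.any() else None,
            "false": float(e[~c].mean()) if (~c).any() else None,
        }
    return out


def _rate(mask: np.ndarray):
    return float(mask.mean()) if mask.size else None


def uncertainty_accumulation(
    events: pd.DataFrame,
    grid_points: int = 500,
    t_max: float = 3.0,
    min_traces: int = 5,
    t_fit_min: float = 0.5,
    exclude_participants: Sequence = (),
    method: str = "mixed",
    participant_col: str = "participant",
) -> dict:
    """SD-vs-occlusion-time curves of saccade-launch errors and their
    post-0.5 s slopes.

    For each participant, each trial's launch-point sequence (phase and
    radius difference against occlusion time) is linearly interpolated
    onto a ``grid_points``-point grid; the SD across trials is kept only
    where at least ``min_traces`` traces overlap (interpolation never
    extrapolates beyond a trial's first/last launch). Slopes are fitted on
    the pooled participant curves for t > ``t_fit_min`` — by default a
    mixed model with a fixed time effect and random participant
    intercepts (marginal R^2 reported), with an OLS fallback.

    ``events`` must carry occlusion-relative launch times in ``t_rel``
    (use :func:`add_occlusion_relative_times`) and a participant column.
    """
    if participant_col not in events.columns:
        raise ValueError(f"events must have a {participant_col!r} column")
    events = events[events["visibility"] == "occluded"]
    events = events[~events[participant_col].isin(list(exclude_participants))]
    grid = np.linspace(0.0, t_max, grid_points)
    curves = []
    for pid, grp in events.groupby(participant_col):
        trial_traces = []
        for _, tg in grp.groupby("trial_id"):
            tg = tg.sort_values("t_rel")
            if len(tg) < 1:
                continue
            tt = tg["t_rel"].to_numpy()
            ph = np.interp(grid, tt, tg["launch_phase_diff"].to_numpy(),
                           left=np.nan, right=np.nan)
            ra = np.interp(grid, tt, tg["launch_radius_diff"].to_numpy(),
                           left=np.nan, right=np.nan)
            ph[(grid < tt[0]) | (grid > tt[-1])] = np.nan
            ra[(grid < tt[0]) | (grid > tt[-1])] = np.nan
            trial_traces.append((ph, ra))
        if len(trial_traces) < min_traces:
            logger.warning("participant %s: only %d occluded traces, skipped",
                           pid, len(trial_traces))
            continue
        ph = np.array([t[0] for t in trial_traces])
        ra = np.array([t[1] for t in trial_traces])
        counts = np.sum(~np.isnan(ph), axis=0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd_ph = np.nanstd(ph, axis=0, ddof=1)
            sd_ra = np.nanstd(ra, axis=0, ddof=1)
        ok = counts >= min_traces
        curves.append(pd.DataFrame({
            "participant": pid, "t": grid[ok],
            "phase_sd": sd_ph[ok], "radius_sd": sd_ra[ok],
        }))
    if not curves:
        return {"curves": pd.DataFrame(), "phase": None, "radius": None}
    curve_df = pd.concat(curves, ignore_index=True)
    fit_df = curve_df[curve_df["t"] > t_fit_min]
    result = {"curves": curve_df}
    for comp in ("phase", "radius"):
        result[comp] = _fit_sd_slope(fit_df, f"{comp}_sd", method)
    return result


def add_occlusion_relative_times(events: pd.DataFrame,
                                 trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Attach launch times relative to each trial's occlusion onset."""
    onset = {tr.trial_id: tr.t_occl_on for tr in trials}
    events = events.copy()
    events["t_rel"] = [
        t - onset.get(tid, np.nan)
        for t, tid in zip(events["t_launch"], events["trial_id"])
    ]
    return events


def _fit_sd_slope(df: pd.DataFrame, col: str, method: str) -> Optional[dict]:
    df = df.dropna(subset=[col])
    if len(df) < 3 or df["participant"].nunique() < 1:
        return None
    y = df[col].to_numpy(dtype=float)
    t = df["t"].to_numpy(dtype=float)
    if method == "mixed" and df["participant"].nunique() >= 2:
        try:
            import warnings

            import statsmodels.formula.api as smf

            model = smf.mixedlm(f"{col} ~ t", df, groups=df["participant"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=True, method="lbfgs")
            slope = float(fit.params["t"])
            var_fixed = float(np.var(fit.params["Intercept"] + slope * t))
            var_re = float(fit.cov_re.iloc[0, 0])
            var_resid = float(fit.scale)
            r2_marginal = var_fixed / (var_fixed + var_re + var_resid)
            return {"slope": slope, "intercept": float(fit.params["Intercept"]),
                    "r2_marginal": r2_marginal, "method": "mixed",
                    "n": int(len(df))}
        except Exception as exc:  # pragma: no cover - convergence fallback
            logger.warning("mixed model failed (%s); falling back to OLS", exc)
    res = stats.linregress(t, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2_marginal": float(res.rvalue ** 2), "method": "ols",
            "n": int(len(df))}
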