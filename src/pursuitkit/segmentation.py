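"""Gaze denoising and event segmentation.

The degree-scale gaze signal is partitioned into piecewise-linear segments
(a segmented linear regression: greedy top-down split search followed by a
continuous least-squares refit at the chosen breakpoints), which both
denoises the signal and yields candidate oculomotor events. Segments are
then classified as saccade vs pursuit/fixation by Viterbi decoding of a
small hidden Markov model over segment features, and finally categorized
by target visibility (visible / occluded / crossing).

Runs separated by missing data (confidence filtering) or sampling gaps are
segmented independently; no segment spans a gap longer than ``max_gap``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import solveh_banded

from .geometry import TaskConfig
from .synth.schedule import TrialRecord

__all__ = [
    "SegmentationConfig",
    "HMMConfig",
    "confidence_filter",
    "split_runs",
    "segment_nslr",
    "classify_segments",
    "demote_slow_saccade_edges",
    "merge_adjacent",
    "assign_visibility",
    "segment_session",
]

logger = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    """Split-search and refit parameters.

    ``penalty`` is the minimum squared-error reduction (deg^2, summed over
    x and y) required to accept a split; ``None`` selects a BIC-like
    default from a robust noise estimate.
    """

    penalty: Optional[float] = None
    penalty_factor: float = 0.5    # multiplies noise variance * log(n) when auto
    min_samples: int = 2           # per piece
    max_gap: float = 0.05          # s; longer gaps separate runs

    def resolve_penalty(self, t: np.ndarray, xy: np.ndarray) -> float:
        if self.penalty is not None:
            return float(self.penalty)
        # robust per-axis noise from first differences (saccades are rare)
        d = np.diff(xy, axis=0)
        mad = np.median(np.abs(d - np.median(d, axis=0)), axis=0)
        sigma = float(np.mean(mad)) / 0.6745 / math.sqrt(2.0)
        sigma = max(sigma, 1e-3)
        return self.penalty_factor * sigma ** 2 * math.log(max(len(t), 10))


# Frozen classifier: fixation, pursuit, post-saccadic oscillation, and two
# saccade states (small catch-up vs large anticipatory saccades; the
# saccade population is bimodal in speed and amplitude). Emissions are
# Gaussian on log10(mean speed in deg/s), log10(duration in s) and
# log10(amplitude in deg); parameters were fit on labeled synthetic
# sessions and frozen here. PSO and both saccade states merge to saccade
# on output, fixation and pursuit to pursuit_fixation.
@dataclass
class HMMConfig:
    states: Tuple[str, ...] = ("fixation", "pursuit", "pso", "sac_small",
                               "saccade")
    means: Tuple[Tuple[float, float, float], ...] = (
        (0.15, -0.98, -0.83),
        (1.20, -1.35, -0.14),
        (1.56, -1.50, 0.06),
        (1.65, -1.60, 0.10),
        (2.10, -1.60, 0.60),
    )
    sds: Tuple[Tuple[float, float, float], ...] = (
        (0.30, 0.45, 0.45),
        (0.28, 0.45, 0.50),
        (0.25, 0.30, 0.30),
        (0.25, 0.35, 0.22),
        (0.30, 0.25, 0.30),
    )
    transition: Tuple[Tuple[float, ...], ...] = (
        (0.24, 0.42, 0.01, 0.18, 0.15),
        (0.06, 0.60, 0.01, 0.24, 0.09),
        (0.12, 0.44, 0.05, 0.13, 0.26),
        (0.15, 0.50, 0.10, 0.15, 0.10),
        (0.12, 0.38, 0.15, 0.10, 0.25),
    )
    initial: Tuple[float, ...] = (0.10, 0.60, 0.05, 0.10, 0.15)
    # events this small are indistinguishable from sampling noise at the
    # default noise level and are folded back into pursuit/fixation
    min_saccade_amplitude: float = 0.8
    collapse: Dict[str, str] = field(default_factory=lambda: {
        "fixation": "pursuit_fixation",
        "pursuit": "pursuit_fixation",
        "pso": "saccade",
        "sac_small": "saccade",
        "saccade": "saccade",
    })


def confidence_filter(samples: pd.DataFrame, threshold: float = 0.8):
    """Drop samples below the pupil-detection confidence threshold.

    Returns (filtered samples, missing intervals as a list of (t0, t1)
    pairs bounding removed stretches). No interpolation is performed.
    """
    if "confidence" not in samples.columns:
        raise ValueError("samples must have a 'confidence' column")
    conf = samples["confidence"].to_numpy()
    if np.any((conf < 0) | (conf > 1)):
        raise ValueError("confidence values must lie in [0, 1]")
    keep = conf >= threshold
    out = samples.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("all samples removed by confidence filter")
    n_removed = int((~keep).sum())
    logger.info("confidence filter: removed %d of %d samples (%.2f%%)",
                n_removed, len(samples), 100.0 * n_removed / len(samples))
    missing = []
    t = samples["t"].to_numpy()
    bad = ~keep
    i = 0
    while i < len(bad):
        if bad[i]:
            j = i
            while j + 1 < len(bad) and bad[j + 1]:
                j += 1
            missing.append((float(t[i]), float(t[j])))
            i = j + 1
        else:
            i += 1
    return out, missing


def split_runs(t: np.ndarray, max_gap: float) -> List[slice]:
    """Slices of contiguous samples (gaps longer than max_gap split runs)."""
    if len(t) == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) > max_gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(t)]])
    return [slice(int(a), int(b)) for a, b in zip(starts, ends)]


def _prefix_sse(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """SSE of the best independent line fit over prefixes [0..k) for all k.

    Vectorized via cumulative sums; k < 2 gives 0.
    """
    n = len(t)
    k = np.arange(n + 1, dtype=float)
    St = np.concatenate([[0.0], np.cumsum(t)])
    Sx = np.concatenate([[0.0], np.cumsum(x)])
    Stt = np.concatenate([[0.0], np.cumsum(t * t)])
    Stx = np.concatenate([[0.0], np.cumsum(t * x)])
    Sxx = np.concatenate([[0.0], np.cumsum(x * x)])
    with np.errstate(divide="ignore", invalid="ignore"):
        det = k * Stt - St * St
        b = np.where(det > 1e-12, (k * Stx - St * Sx) / np.where(det > 0, det, 1.0), 0.0)
        a = np.where(k > 0, (Sx - b * St) / np.where(k > 0, k, 1.0), 0.0)
        sse = Sxx - a * Sx - b * Stx
    sse = np.where(k < 2, 0.0, np.maximum(sse, 0.0))
    return sse


def _window_sse_curves(t: np.ndarray, xy: np.ndarray):
    """Left-prefix and right-suffix SSE (summed over dims) for one window."""
    left = np.zeros(len(t) + 1)
    right = np.zeros(len(t) + 1)
    for d in range(xy.shape[1]):
        left += _prefix_sse(t, xy[:, d])
        right += _prefix_sse(t[::-1].copy() * -1.0, xy[::-1, d])[::-1]
    return left, right


def _find_breakpoints(t: np.ndarray, xy: np.ndarray, penalty: float,
                      min_samples: int) -> List[int]:
    """Greedy top-down recursive split search; returns sorted split indices."""
    out: List[int] = []
    stack = [(0, len(t))]
    while stack:
        i, j = stack.pop()
        n = j - i
        if n < 2 * min_samples:
            continue
        left, right = _window_sse_curves(t[i:j], xy[i:j])
        full = left[n]
        # candidate split k: left piece [0, k), right piece [k, n)
        ks = np.arange(min_samples, n - min_samples + 1)
        if len(ks) == 0:
            continue
        totals = left[ks] + right[ks]
        kbest = int(ks[np.argmin(totals)])
        if full - totals[kbest - min_samples] > penalty:
            out.append(i + kbest)
            stack.append((i, i + kbest))
            stack.append((i + kbest, j))
    return sorted(out)


def _refine_breakpoints(t: np.ndarray, xy: np.ndarray, splits: List[int],
                        min_samples: int, radius: int = 3,
                        passes: int = 1) -> List[int]:
    """Local coordinate descent: shift each breakpoint within ``radius``
    samples to minimize the SSE of its two adjacent pieces."""
    if not splits:
        return splits
    splits = sorted(splits)
    n = len(t)
    for _ in range(passes):
        moved = False
        bounds = [0] + splits + [n]
        for bi in range(1, len(bounds) - 1):
            a, b, c = bounds[bi - 1], bounds[bi], bounds[bi + 1]
            lo = max(a + min_samples, b - radius)
            hi = min(c - min_samples, b + radius)
            if lo > hi:
                continue
            left, right = _window_sse_curves(t[a:c], xy[a:c])
            ks = np.arange(lo - a, hi - a + 1)
            sses = left[ks] + right[ks]
            best_b = int(a + ks[np.argmin(sses)])
            if best_b != b:
                bounds[bi] = best_b
                moved = True
        splits = bounds[1:-1]
        if not moved:
            break
    return splits


def _continuous_fit(t: np.ndarray, xy: np.ndarray, splits: Sequence[int]):
    """Least-squares continuous piecewise-linear fit at fixed breakpoints.

    Node times are the first sample time, the breakpoint sample times, and
    the last sample time. The interpolation (hat-function) basis yields a
    tridiagonal normal system solved per dimension.

    Returns (node_times, node_values (m, dims), fitted (n, dims)).
    """
    n = len(t)
    nodes = np.concatenate([[t[0]], t[list(splits)], [t[-1]]]) if splits \
        else np.array([t[0], t[-1]])
    m = len(nodes)
    if m == 2 and n == 1:
        nodes = np.array([t[0], t[0]])
    # assign samples to intervals
    idx = np.clip(np.searchsorted(nodes, t, side="right") - 1, 0, m - 2)
    span = nodes[idx + 1] - nodes[idx]
    u = np.where(span > 0, (t - nodes[idx]) / np.where(span > 0, span, 1.0), 0.0)
    w0 = 1.0 - u   # weight on node idx
    w1 = u         # weight on node idx+1
    # tridiagonal normal equations
    diag = np.zeros(m)
    off = np.zeros(m - 1)
    np.add.at(diag, idx, w0 * w0)
    np.add.at(diag, idx + 1, w1 * w1)
    np.add.at(off, idx, w0 * w1)
    rhs = np.zeros((m, xy.shape[1]))
    for d in range(xy.shape[1]):
        np.add.at(rhs[:, d], idx, w0 * xy[:, d])
        np.add.at(rhs[:, d], idx + 1, w1 * xy[:, d])
    ab = np.zeros((2, m))
    ab[0, 1:] = off
    ab[1] = diag + 1e-12
    values = solveh_banded(ab, rhs)
    fitted = w0[:, None] * values[idx] + w1[:, None] * values[idx + 1]
    return nodes, values, fitted


def segment_nslr(
    t: np.ndarray,
    xy: np.ndarray,
    config: SegmentationConfig = SegmentationConfig(),
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Segment one contiguous run into continuous linear pieces.

    Returns (segment table, fitted positions per sample). Runs shorter
    than 2 samples are emitted as a single degenerate segment flagged
    ``degenerate=True`` (excluded from statistics downstream).
    """
    t = np.asarray(t, dtype=float)
    xy = np.asarray(xy, dtype=float)
    if len(t) < 2:
        seg = pd.DataFrame([{
            "t_start": t[0], "t_end": t[0],
            "x0": xy[0, 0], "y0": xy[0, 1], "x1": xy[0, 0], "y1": xy[0, 1],
            "amplitude": 0.0, "duration": 0.0, "mean_speed": 0.0,
            "n_samples": 1, "degenerate": True,
        }]) if len(t) == 1 else pd.DataFrame()
        return seg, xy.copy()
    penalty = config.resolve_penalty(t, xy)
    splits = _find_breakpoints(t, xy, penalty, config.min_samples)
    splits = _refine_breakpoints(t, xy, splits, config.min_samples)
    nodes, values, fitted = _continuous_fit(t, xy, splits)
    rows = []
    for k in range(len(nodes) - 1):
        p0, p1 = values[k], values[k + 1]
        dur = nodes[k + 1] - nodes[k]
        amp = float(np.linalg.norm(p1 - p0))
        rows.append({
            "t_start": float(nodes[k]), "t_end": float(nodes[k + 1]),
            "x0": float(p0[0]), "y0": float(p0[1]),
            "x1": float(p1[0]), "y1": float(p1[1]),
            "amplitude": amp, "duration": float(dur),
            "mean_speed": amp / dur if dur > 0 else 0.0,
            "n_samples": int(np.sum((t >= nodes[k]) & (t <= nodes[k + 1]))),
            "degenerate": False,
        })
    return pd.DataFrame(rows), fitted


def classify_segments(segments: pd.DataFrame,
                      hmm: HMMConfig = HMMConfig()) -> pd.DataFrame:
    """Viterbi-label segments and collapse to saccade / pursuit_fixation."""
    segments = segments.copy()
    if len(segments) == 0:
        segments["class"] = pd.Series(dtype=str)
        return segments
    speed = np.maximum(segments["mean_speed"].to_numpy(dtype=float), 1e-3)
    dur = np.maximum(segments["duration"].to_numpy(dtype=float), 1e-4)
    amp = np.maximum(segments["amplitude"].to_numpy(dtype=float), 1e-3)
    feats = np.column_stack([np.log10(speed), np.log10(dur), np.log10(amp)])

    means = np.asarray(hmm.means)
    sds = np.asarray(hmm.sds)
    logtrans = np.log(np.asarray(hmm.transition))
    loginit = np.log(np.asarray(hmm.initial))
    # Gaussian log-emissions, diagonal covariance
    z = (feats[:, None, :] - means[None, :, :]) / sds[None, :, :]
    logem = -0.5 * np.sum(z ** 2 + np.log(2 * math.pi * sds[None, :, :] ** 2), axis=2)

    n, S = logem.shape
    delta = loginit + logem[0]
    back = np.zeros((n, S), dtype=int)
    for i in range(1, n):
        cand = delta[:, None] + logtrans
        back[i] = np.argmax(cand, axis=0)
        delta = cand[back[i], np.arange(S)] + logem[i]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i][path[i]]
    labels = [hmm.states[s] for s in path]
    segments["hmm_state"] = labels
    segments["class"] = [hmm.collapse[s] for s in labels]
    return segments


def demote_slow_saccade_edges(segments: pd.DataFrame,
                              speed_frac: float = 0.5) -> pd.DataFrame:
    """Reassign slow flanking pieces of saccadic runs to pursuit/fixation.

    A saccade event is the chain of consecutive saccade-class pieces; its
    boundaries are defined by the fast core, so edge pieces slower than
    ``speed_frac`` times the chain's peak piece speed (pre/post-saccadic
    contamination from imperfect breakpoints) are demoted. The chain's
    fastest piece is never demoted.
    """
    segments = segments.copy()
    classes = segments["class"].to_numpy().copy()
    speeds = segments["mean_speed"].to_numpy()
    runs = []
    start = None
    for i, c in enumerate(classes):
        if c == "saccade" and start is None:
            start = i
        elif c != "saccade" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(classes)))
    for a, b in runs:
        thresh = speed_frac * speeds[a:b].max()
        lo, hi = a, b
        while lo < hi - 1 and speeds[lo] < thresh:
            classes[lo] = "pursuit_fixation"
            lo += 1
        while hi - 1 > lo and speeds[hi - 1] < thresh:
            classes[hi - 1] = "pursuit_fixation"
            hi -= 1
    segments["class"] = classes
    return segments


def merge_adjacent(segments: pd.DataFrame) -> pd.DataFrame:
    """Merge consecutive same-class segments within a run.

    The split search over-segments long smooth stretches (and can cut one
    saccade in two); after classification, adjacent segments sharing a
    class are combined so each row is one oculomotor event. Endpoints come
    from the outer boundaries; amplitude and mean speed are re-derived.
    """
    if len(segments) == 0:
        return segments
    rows = []
    cur = None
    for _, seg in segments.iterrows():
        if (cur is not None and seg["class"] == cur["class"]
                and seg.get("run_id", 0) == cur.get("run_id", 0)
                and abs(seg["t_start"] - cur["t_end"]) < 1e-9):
            cur["t_end"] = seg["t_end"]
            cur["x1"], cur["y1"] = seg["x1"], seg["y1"]
            cur["n_samples"] = cur["n_samples"] + seg["n_samples"] - 1
        else:
            if cur is not None:
                rows.append(cur)
            cur = seg.to_dict()
    rows.append(cur)
    out = pd.DataFrame(rows)
    out["duration"] = out["t_end"] - out["t_start"]
    out["amplitude"] = np.hypot(out["x1"] - out["x0"], out["y1"] - out["y0"])
    out["mean_speed"] = np.where(out["duration"] > 0,
                                 out["amplitude"] / out["duration"], 0.0)
    return out.reset_index(drop=True)


def assign_visibility(segments: pd.DataFrame,
                      trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Categorize segments by target visibility.

    A segment fully inside a visible window is ``visible``; fully inside an
    occlusion, ``occluded``; touching both, ``crossing``; anything else
    (probe/feedback periods, outside trials) is ``other`` and excluded from
    the period statistics. Windows are closed-open, so a segment ending
    exactly at occlusion onset is visible.
    """
    segments = segments.copy()
    vis = np.array([[tr.t_visible_on, tr.t_occl_on] for tr in trials])
    occ = np.array([[tr.t_occl_on, tr.t_reappear] for tr in trials])
    cats = []
    trial_ids = []
    for _, seg in segments.iterrows():
        a, b = seg["t_start"], seg["t_end"]
        in_vis = (vis[:, 0] <= a) & (b <= vis[:, 1])
        in_occ = (occ[:, 0] <= a) & (b <= occ[:, 1])
        ov_vis = (a < vis[:, 1]) & (b > vis[:, 0])
        ov_occ = (a < occ[:, 1]) & (b > occ[:, 0])
        if in_vis.any():
            i = int(np.argmax(in_vis))
            cats.append("visible")
        elif in_occ.any():
            i = int(np.argmax(in_occ))
            cats.append("occluded")
        elif (ov_vis & ov_occ).any():
            i = int(np.argmax(ov_vis & ov_occ))
            cats.append("crossing")
        elif ov_vis.any() or ov_occ.any():
            i = int(np.argmax(ov_vis | ov_occ))
            cats.append("other")
        else:
            i = -1
            cats.append("other")
        trial_ids.append(trials[i].trial_id if i >= 0 else -1)
    segments["visibility"] = cats
    segments["trial_id"] = trial_ids
    return segments


def segment_session(
    samples: pd.DataFrame,
    trials: Sequence[TrialRecord],
    config: SegmentationConfig = SegmentationConfig(),
    hmm: HMMConfig = HMMConfig(),
    conf_threshold: float = 0.8,
):
    """Full segmentation stage: filter, split runs, segment, classify,
    assign visibility.

    Returns (segment table with run_id/class/visibility, denoised samples
    DataFrame with columns t, x_fit, y_fit, run_id).
    """
    filtered, _ = confidence_filter(samples, conf_threshold)
    t = filtered["t"].to_numpy(dtype=float)
    xy = filtered[["x_deg", "y_deg"]].to_numpy(dtype=float)
    seg_tables = []
    fit_parts = []
    for run_id, sl in enumerate(split_runs(t, config.max_gap)):
        segs, fitted = segment_nslr(t[sl], xy[sl], config)
        if len(segs):
            segs["run_id"] = run_id
            seg_tables.append(segs)
        fit_parts.append(pd.DataFrame({
            "t": t[sl], "x_fit": fitted[:, 0], "y_fit": fitted[:, 1],
            "run_id": run_id,
        }))
    segments = pd.concat(seg_tables, ignore_index=True)
    ok = ~segments["degenerate"]
    segments = classify_segments(segments[ok].reset_index(drop=True), hmm)
    segments = demote_slow_saccade_edges(segments)
    segments = merge_adjacent(segments)
    small = (segments["class"] == "saccade") \
        & (segments["amplitude"] < hmm.min_saccade_amplitude)
    if small.any():
        segments.loc[small, "class"] = "pursuit_fixation"
        segments = merge_adjacent(segments)
    segments = assign_visibility(segments, trials)
    denoised = pd.concat(fit_parts, ignore_index=True)
    return segments, denoised
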