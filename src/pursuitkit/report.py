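"""Figure rendering from persisted analysis tables.

Produces analogues of the headline figures: median positional-error
development with hypothetical baselines, launch/landing phase-difference
distributions, cumulative phase coverage, pursuit gain over trial time
(with an optional loess-style smoother, plotting only), and SD-vs-time
uncertainty curves.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["render_report", "loess_smooth"]


def loess_smooth(x: np.ndarray, y: np.ndarray, frac: float = 0.4,
                 n_out: int = 100) -> tuple:
    """Locally weighted linear smoother (tricube weights); plotting only."""
    order = np.argsort(x)
    x, y = np.asarray(x)[order], np.asarray(y)[order]
    xs = np.linspace(x.min(), x.max(), n_out)
    k = max(int(frac * len(x)), 3)
    ys = np.empty(n_out)
    for i, x0 in enumerate(xs):
        d = np.abs(x - x0)
        idx = np.argsort(d)[:k]
        w = (1 - (d[idx] / max(d[idx].max(), 1e-12)) ** 3) ** 3
        A = np.column_stack([np.ones(k), x[idx] - x0])
        coef, *_ = np.linalg.lstsq(A * w[:, None], y[idx] * w, rcond=None)
        ys[i] = coef[0]
    return xs, ys


def render_report(analysis_dir: Path, out_dir: Path) -> List[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    med_path = analysis_dir / "median_error_curves.csv"
    if med_path.exists():
        med = pd.read_csv(med_path)
        fig, axes = plt.subplots(3, 1, figsize=(7, 9), sharex=True)
        axes[0].plot(med["t_rel"], med["euclidean"], color="C0")
        for kind, style in (("tangent", "-"), ("stay", ":"), ("center", "--")):
            axes[0].plot(med["t_rel"], med[f"baseline_{kind}"], style,
                         color="k", lw=1, label=kind)
        axes[0].set_ylabel("error (deg)")
        axes[0].legend()
        axes[1].plot(med["t_rel"], med["phase_diff"], color="C0")
        axes[1].set_ylabel("phase diff (turns)")
        axes[2].plot(med["t_rel"], med["radius_diff"], color="C0")
        axes[2].set_ylabel("radius diff (deg)")
        axes[2].set_xlabel("time from occlusion onset (s)")
        for ax in axes:
            ax.axvline(0, ls="--", color="gray", lw=1)
        p = out_dir / "error_development.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    ev_path = analysis_dir / "saccade_events.csv"
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, vis in zip(axes, ("visible", "occluded")):
            sub = ev[ev["visibility"] == vis]
            if len(sub):
                bins = np.linspace(-0.25, 0.25, 41)
                ax.hist(sub["launch_phase_diff"], bins=bins, alpha=0.6,
                        label="launch")
                ax.hist(sub["land_phase_diff"], bins=bins, alpha=0.6,
                        label="landing")
                ax.axvline(sub["launch_phase_diff"].median(), ls="--", color="C0")
                ax.axvline(sub["land_phase_diff"].median(), ls="--", color="C1")
            ax.set_title(vis)
            ax.set_xlabel("phase difference (turns)")
            ax.legend()
        p = out_dir / "saccade_phase_differences.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    gains_path = analysis_dir / "gains.csv"
    if gains_path.exists():
        gains = pd.read_csv(gains_path)
        if len(gains):
            fig, ax = plt.subplots(figsize=(7, 4))
            colors = {"visible": "green", "crossing": "black",
                      "occluded": "C0", "other": "lightgray"}
            for _, g in gains.iterrows():
                ax.plot([g["t_start"], g["t_end"]], [g["gain"], g["gain"]],
                        color=colors.get(g["visibility"], "gray"), lw=1,
                        alpha=0.5)
            mid = (gains["t_start"] + gains["t_end"]) / 2
            if len(gains) > 10:
                xs, ys = loess_smooth(mid.to_numpy(), gains["gain"].to_numpy())
                ax.plot(xs, ys, "k--")
            ax.set_xlabel("time (s)")
            ax.set_ylabel("pursuit gain")
            ax.set_ylim(-0.5, 2.0)
            p = out_dir / "pursuit_gain.png"
            fig.savefig(p, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(p)

    unc_path = analysis_dir / "uncertainty_curves.csv"
    if unc_path.exists():
        unc = pd.read_csv(unc_path)
        if len(unc):
            fig, axes = plt.subplots(1, 2, figsize=(10, 4))
            for pid, g in unc.groupby("participant"):
                axes[0].plot(g["t"], g["phase_sd"], alpha=0.7)
                axes[1].plot(g["t"], g["radius_sd"], alpha=0.7)
            axes[0].set_ylabel("phase SD (turns)")
            axes[1].set_ylabel("radius SD (deg)")
            for ax in axes:
                ax.set_xlabel("time from occlusion onset (s)")
            p = out_dir / "uncertainty_accumulation.png"
            fig.savefig(p, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(p)

    return written
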