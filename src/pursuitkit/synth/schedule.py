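"""Trial-schedule generation for synthetic sessions.

The session is one continuous timeline: target motion is never interrupted.
Each trial is visible for a uniform random duration, occluded for a uniform
random duration, then shows a brief probe followed by a fixed feedback
period, after which the next trial's visible period starts immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Optional

import numpy as np

from ..geometry import TaskConfig

__all__ = ["TrialRecord", "generate_schedule", "session_duration"]

PROBE_DIRECTIONS = ("up", "down", "left", "right")


@dataclass
class TrialRecord:
    """One trial's timing windows, probe and (optionally) response."""

    trial_id: int
    t_visible_on: float
    t_occl_on: float
    t_reappear: float
    probe_direction: str
    response: Optional[str] = None
    correct: Optional[bool] = None

    @property
    def occl_duration(self) -> float:
        return self.t_reappear - self.t_occl_on

    @property
    def visible_duration(self) -> float:
        return self.t_occl_on - self.t_visible_on

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        return cls(**{k: d[k] for k in (
            "trial_id", "t_visible_on", "t_occl_on", "t_reappear",
            "probe_direction", "response", "correct")})


def generate_schedule(n_trials: int, cfg: TaskConfig, seed=None) -> List[TrialRecord]:
    """Draw a continuous schedule of ``n_trials`` trials.

    Visible and occlusion durations are i.i.d. uniform on the configured
    ranges; probe directions are uniform over the four alternatives.
    Responses are left unfilled.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    trials: List[TrialRecord] = []
    t = 0.0
    for i in range(n_trials):
        vis = rng.uniform(*cfg.visible_range)
        occ = rng.uniform(*cfg.occlusion_range)
        t_on = t
        t_occl = t_on + vis
        t_re = t_occl + occ
        trials.append(
            TrialRecord(
                trial_id=i,
                t_visible_on=t_on,
                t_occl_on=t_occl,
                t_reappear=t_re,
                probe_direction=str(rng.choice(PROBE_DIRECTIONS)),
            )
        )
        t = t_re + cfg.probe_duration + cfg.feedback_duration
    return trials


def session_duration(trials: List[TrialRecord], cfg: TaskConfig) -> float:
    """End time of the last trial's feedback period."""
    last = trials[-1]
    return last.t_reappear + cfg.probe_duration + cfg.feedback_duration
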