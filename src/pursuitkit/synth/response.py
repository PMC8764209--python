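"""Two-rate model of discrimination responses.

Correctness is Bernoulli with probability ``p_near`` when the gaze error at
target reappearance is at most ``near_threshold`` degrees and ``p_far``
otherwise; wrong responses are uniform over the three other directions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .schedule import TrialRecord, PROBE_DIRECTIONS

__all__ = ["ResponseParams", "simulate_response"]


@dataclass
class ResponseParams:
    p_near: float = 0.92
    p_far: float = 0.51
    near_threshold: float = 1.5  # degrees

    def __post_init__(self) -> None:
        for p in (self.p_near, self.p_far):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseParams":
        return cls(**d)


def simulate_response(
    trial: TrialRecord,
    gaze_error_at_reappear: float,
    params: ResponseParams = ResponseParams(),
    rng=None,
) -> TrialRecord:
    """Fill in ``response`` and ``correct`` for a trial in place.

    Returns the same TrialRecord for convenience.
    """
    if gaze_error_at_reappear < 0:
        raise ValueError("gaze error must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    p = params.p_near if gaze_error_at_reappear <= params.near_threshold \
        else params.p_far
    correct = bool(rng.random() < p)
    if correct:
        response = trial.probe_direction
    else:
        others = [d for d in PROBE_DIRECTIONS if d != trial.probe_direction]
        response = str(rng.choice(others))
    trial.response = response
    trial.correct = correct
    return trial
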