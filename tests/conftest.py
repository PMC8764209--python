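import numpy as np
import pytest

from pursuitkit.geometry import TaskConfig
from pursuitkit.synth import OculomotorParams, generate_schedule, simulate_gaze


@pytest.fixture(scope="session")
def cfg():
    return TaskConfig()


@pytest.fixture(scope="session")
def default_session(cfg):
    """One 30-trial synthetic session with ground truth (seed fixed)."""
    trials = generate_schedule(30, cfg, seed=101)
    samples, truth = simulate_gaze(trials, OculomotorParams(), cfg, seed=1)
    return trials, samples, truth


@pytest.fixture(scope="session")
def segmented_session(cfg, default_session):
    from pursuitkit.segmentation import segment_session

    trials, samples, truth = default_session
    segments, denoised = segment_session(samples, trials)
    return trials, samples, truth, segments, denoised


def match_saccades(true_saccades, detected, tol=0.025, require_offset=True):
    """One-to-one greedy matching of true saccades to detected saccade
    segments by onset (and optionally offset) proximity."""
    used = set()
    matched = 0
    for s in true_saccades:
        cands = detected[(detected["t_start"] - s["t_start"]).abs() < tol]
        if require_offset:
            cands = cands[(cands["t_end"] - s["t_end"]).abs() < tol]
        for i in cands.index:
            if i not in used:
                used.add(i)
                matched += 1
                break
    return matched / len(true_saccades)
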