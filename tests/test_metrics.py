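import math

import numpy as np
import pandas as pd
import pytest

from pursuitkit.geometry import (
    TaskConfig,
    object_phase,
    object_position,
    polar_decompose,
    wrap_phase_diff,
)
from pursuitkit.metrics import (
    add_occlusion_relative_times,
    binom_test_exact,
    cumulative_phase_coverage,
    discrimination_summary,
    error_at_reappearance,
    error_timeseries,
    pursuit_gain,
    saccade_anticipation,
    saccade_events_from_segments,
    uncertainty_accumulation,
)
from pursuitkit.metrics import _segment_phase_delta
from pursuitkit.synth import (
    OculomotorParams,
    ResponseParams,
    generate_schedule,
    simulate_gaze,
    simulate_response,
)


def enumeration_binom_p(k, n, p0):
    """Independent oracle: exact enumeration with math.comb."""
    probs = [math.comb(n, i) * p0 ** i * (1 - p0) ** (n - i)
             for i in range(n + 1)]
    pk = probs[k]
    return sum(p for p in probs if p <= pk * (1 + 1e-9))


class TestBinomTest:
    def test_nine_of_ten(self):
        assert round(binom_test_exact(9, 10, 0.5), 3) == 0.021

    def test_ten_of_ten(self):
        assert round(binom_test_exact(10, 10, 0.5), 3) == 0.002

    def test_symmetric_null_gives_one(self):
        assert binom_test_exact(5, 10, 0.5) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            binom_test_exact(0, 0, 0.5)

    def test_matches_enumeration_oracle_all_n_up_to_25(self):
        for n in range(1, 26):
            for k in range(n + 1):
                for p0 in (0.5, 0.3):
                    assert binom_test_exact(k, n, p0) == pytest.approx(
                        enumeration_binom_p(k, n, p0), abs=1e-12)


class TestErrorTimeseries:
    def _denoised_from(self, t, xy):
        return pd.DataFrame({"t": t, "x_fit": xy[:, 0], "y_fit": xy[:, 1],
                             "run_id": 0})

    def test_perfect_tracking_zero_error(self, cfg):
        trials = generate_schedule(3, cfg, seed=0)
        t = np.arange(0.0, trials[-1].t_reappear, 1 / 120.0)
        xy, _ = object_position(t, cfg)
        traces = error_timeseries(self._denoised_from(t, xy), trials, cfg)
        # linear resampling of the curved path bounds error at
        # (w*dt)^2 * R / 8 ~ 3e-4 deg
        assert np.nanmax(traces["euclidean"]) < 1e-3
        assert np.nanmax(np.abs(traces["phase_diff"])) < 1e-4

    def test_frozen_gaze_matches_stay_closed_form(self, cfg):
        trials = generate_schedule(1, cfg, seed=5)
        tr = trials[0]
        t = np.arange(0.0, tr.t_reappear + 0.5, 1 / 120.0)
        p0, _ = object_position(tr.t_occl_on, cfg)
        xy = np.where((t >= tr.t_occl_on)[:, None], p0[None, :],
                      object_position(t, cfg)[0])
        traces = error_timeseries(self._denoised_from(t, xy), trials, cfg)
        # skip the grid point straddling the freeze instant (the
        # constructed trace freezes at the first sample past onset)
        occl = traces[traces["t_rel"] > 1.5 / 120.0]
        chord = 2 * cfg.radius * np.abs(
            np.sin(math.pi * cfg.angular_rate * occl["t_rel"]))
        assert np.allclose(occl["euclidean"], chord, atol=1e-3)

    def test_no_extrapolation_beyond_trial(self, cfg):
        trials = generate_schedule(2, cfg, seed=1)
        tr = trials[0]
        t = np.arange(0.0, trials[-1].t_reappear, 1 / 120.0)
        xy, _ = object_position(t, cfg)
        traces = error_timeseries(self._denoised_from(t, xy), trials, cfg)
        per_trial = traces[traces["trial_id"] == tr.trial_id]
        assert per_trial["t_rel"].max() <= tr.occl_duration + 1e-9
        assert per_trial["t_rel"].min() >= -tr.visible_duration - 1e-9


class TestSaccadeAnticipation:
    def test_binomial_wiring(self):
        rows = []
        for pid in range(10):
            # landing |dphi| > launch |dphi| for all but participant 0
            sign = -1 if pid == 0 else 1
            for k in range(6):
                rows.append({
                    "visibility": "occluded", "participant": pid,
                    "launch_phase_diff": 0.01 * sign,
                    "land_phase_diff": (0.05 if sign > 0 else 0.001),
                })
        out = saccade_anticipation(pd.DataFrame(rows))
        assert out["landing_gt_launch"]["k"] == 9
        assert round(out["landing_gt_launch"]["p_value"], 3) == 0.021

    def test_occluded_landing_leads_launch(self, segmented_session, cfg):
        trials, _, _, segments, _ = segmented_session
        events = saccade_events_from_segments(segments, cfg)
        out = saccade_anticipation(events)
        med = out["medians"]["occluded"]
        assert med["land_abs"] > med["launch_abs"]
        assert med["land_signed"] > 0.02  # anticipatory: lands well ahead


class TestPhaseCoverage:
    def test_conservation_identity(self, segmented_session, cfg):
        _, _, _, segments, _ = segmented_session
        for _, run in segments.groupby("run_id"):
            deltas = _segment_phase_delta(run, cfg)
            gp0, _ = polar_decompose(
                run[["x0", "y0"]].to_numpy()[0], cfg)
            gp1, _ = polar_decompose(
                run[["x1", "y1"]].to_numpy()[-1], cfg)
            # segment endpoints chain, so deltas telescope
            chained = np.sum(deltas)
            step_sum = np.sum(wrap_phase_diff(
                polar_decompose(run[["x1", "y1"]].to_numpy(), cfg)[0]
                - polar_decompose(run[["x0", "y0"]].to_numpy(), cfg)[0]))
            assert chained == pytest.approx(step_sum, abs=1e-9)

    def test_pure_pursuit_share_is_one(self, cfg):
        trials = generate_schedule(4, cfg, seed=2)
        params = OculomotorParams(visible_saccade_rate=0.0,
                                  occl_saccade_rate=0.0,
                                  measurement_noise_sd=0.0,
                                  low_conf_fraction=0.0)
        samples, _ = simulate_gaze(trials, params, cfg, seed=2)
        from pursuitkit.segmentation import segment_session

        segments, _ = segment_session(samples, trials)
        cov = cumulative_phase_coverage(segments, trials, cfg)
        vis = cov[cov["period"] == "visible"]["pursuit_share"].dropna()
        assert np.allclose(vis, 1.0)

    def test_share_medians_reproduce_visibility_contrast(self,
                                                         segmented_session,
                                                         cfg):
        trials, _, _, segments, _ = segmented_session
        cov = cumulative_phase_coverage(segments, trials, cfg)
        vis = cov[cov["period"] == "visible"]["pursuit_share"].dropna().median()
        occ = cov[cov["period"] == "occluded"]["pursuit_share"].dropna().median()
        assert vis > 0.5
        assert occ < 0.5

    def test_zero_length_period_skipped(self, cfg):
        trials = generate_schedule(1, TaskConfig(occlusion_range=(0.0, 0.0)),
                                   seed=0)
        seg = pd.DataFrame([{
            "t_start": trials[0].t_visible_on,
            "t_end": trials[0].t_occl_on,
            "x0": 13.5, "y0": 0.0, "x1": 0.0, "y1": -13.5,
            "class": "pursuit_fixation", "visibility": "visible",
            "duration": trials[0].visible_duration, "amplitude": 1.0,
            "mean_speed": 1.0,
        }])
        cov = cumulative_phase_coverage(seg, trials, cfg)
        assert set(cov["period"]) == {"visible"}


class TestPursuitGain:
    def _seg(self, t0, t1, p0, p1, cls="pursuit_fixation"):
        return {
            "t_start": t0, "t_end": t1, "x0": p0[0], "y0": p0[1],
            "x1": p1[0], "y1": p1[1], "class": cls, "visibility": "visible",
            "duration": t1 - t0, "amplitude": 1.0, "mean_speed": 1.0,
            "trial_id": 0,
        }

    def test_tracking_target_gain_one(self, cfg):
        p0, _ = object_position(1.0, cfg)
        p1, _ = object_position(1.8, cfg)
        gains = pursuit_gain(pd.DataFrame([self._seg(1.0, 1.8, p0, p1)]), cfg)
        assert gains["gain"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_stationary_gaze_gain_zero(self, cfg):
        p, _ = object_position(1.0, cfg)
        gains = pursuit_gain(pd.DataFrame([self._seg(1.0, 1.8, p, p)]), cfg)
        assert gains["gain"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_configured_gains(self, segmented_session, cfg):
        trials, _, _, segments, _ = segmented_session
        gains = pursuit_gain(segments, cfg)
        vis = gains[gains["visibility"] == "visible"]["gain"].median()
        assert abs(vis - OculomotorParams().visible_gain) < 0.1
        # deep into occlusion the pursuit gain collapses
        occl = gains[gains["visibility"] == "occluded"]
        onset = {tr.trial_id: tr.t_occl_on for tr in trials}
        deep = occl[[row["t_start"] - onset[row["trial_id"]] > 1.0
                     for _, row in occl.iterrows()]]
        assert deep["gain"].median() < 0.3


class TestDiscrimination:
    def test_all_correct(self, cfg):
        trials = generate_schedule(10, cfg, seed=0)
        for tr in trials:
            tr.response, tr.correct = tr.probe_direction, True
        out = discrimination_summary(trials)
        assert out["overall"] == 1.0

    def test_round_trip_with_generator(self, cfg):
        rng = np.random.default_rng(0)
        trials = generate_schedule(4000, cfg, seed=1)
        errors = rng.uniform(0.0, 3.0, len(trials))
        rows = []
        for tr, e in zip(trials, errors):
            simulate_response(tr, e, ResponseParams(), rng)
            rows.append({"trial_id": tr.trial_id, "euclidean": e})
        out = discrimination_summary(trials, pd.DataFrame(rows))
        assert out["by_error"]["near"] > 0.88
        assert abs(out["by_error"]["far"] - 0.51) < 0.05
        assert out["mean_error"]["false"] > out["mean_error"]["correct"]

    def test_empty_stratum_missing_not_zero(self, cfg):
        trials = generate_schedule(5, TaskConfig(occlusion_range=(0.0, 0.5)),
                                   seed=0)
        for tr in trials:
            tr.response, tr.correct = tr.probe_direction, True
        out = discrimination_summary(trials)
        assert out["by_occlusion"]["long"] is None


def _truth_launch_events(cfg, n_participants, n_trials, params, seed0=0):
    rows = []
    for pid in range(n_participants):
        trials = generate_schedule(n_trials, cfg, seed=1000 + pid + seed0)
        _, truth = simulate_gaze(trials, params, cfg, seed=2000 + pid + seed0)
        onset = {tr.trial_id: tr.t_occl_on for tr in trials}
        for s in truth["saccades"]:
            if s["period"] != "occluded":
                continue
            ph, ra = polar_decompose(np.array([s["x0"], s["y0"]]), cfg)
            op = object_phase(s["t_start"], cfg)
            rows.append({
                "participant": pid, "trial_id": s["trial_id"],
                "visibility": "occluded", "t_launch": s["t_start"],
                "launch_phase_diff": float(wrap_phase_diff(ph - op)),
                "launch_radius_diff": float(ra - cfg.radius),
                "t_rel": s["t_start"] - onset[s["trial_id"]],
            })
    return pd.DataFrame(rows)


class TestUncertaintyAccumulation:
    def test_zero_drift_flat_phase_sd(self, cfg):
        params = OculomotorParams(phase_drift_sd_rate=1e-9)
        events = _truth_launch_events(cfg, 4, 20, params)
        res = uncertainty_accumulation(events, method="ols")
        assert abs(res["phase"]["slope"]) < 0.008

    def test_recovers_configured_drift_rate(self, cfg):
        events = _truth_launch_events(cfg, 10, 30, OculomotorParams())
        res = uncertainty_accumulation(events)
        slope = res["phase"]["slope"]
        assert abs(slope - 0.025) / 0.025 < 0.25

    def test_radius_dissociation(self, cfg):
        events = _truth_launch_events(cfg, 6, 25, OculomotorParams())
        res = uncertainty_accumulation(events)
        # phase uncertainty accumulates; radius (re-anchored) stays flat:
        # compare slopes on a common scale (degrees along the trajectory)
        phase_deg = res["phase"]["slope"] * 2 * math.pi * cfg.radius
        assert phase_deg > 1.0
        assert abs(res["radius"]["slope"]) < 0.5

    def test_interpolation_never_extrapolates(self, cfg):
        events = _truth_launch_events(cfg, 6, 10, OculomotorParams())
        res = uncertainty_accumulation(events, min_traces=5)
        assert res["curves"]["t"].max() <= 3.0

    def test_below_trace_minimum_skipped(self, cfg):
        events = _truth_launch_events(cfg, 1, 3, OculomotorParams())
        res = uncertainty_accumulation(events, min_traces=5)
        assert len(res["curves"]) == 0

    def test_participant_exclusion_flag(self, cfg):
        events = _truth_launch_events(cfg, 4, 15, OculomotorParams())
        res = uncertainty_accumulation(events, exclude_participants=[0])
        assert 0 not in set(res["curves"]["participant"])


class TestReappearanceErrors:
    def test_interpolated_at_reappearance(self, cfg):
        trials = generate_schedule(3, cfg, seed=4)
        t = np.arange(0.0, trials[-1].t_reappear + 0.1, 1 / 120.0)
        xy, _ = object_position(t, cfg)
        den = pd.DataFrame({"t": t, "x_fit": xy[:, 0], "y_fit": xy[:, 1]})
        out = error_at_reappearance(den, trials, cfg)
        assert len(out) == 3
        assert np.allclose(out["euclidean"], 0.0, atol=1e-3)
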