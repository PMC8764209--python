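# pursuitkit

Analysis pipeline for gaze behavior while tracking an intermittently
occluded target moving on a circular trajectory. The package covers the
full chain from raw gaze/marker streams to the headline statistics:

- **`pursuitkit.geometry`** — task model: circular target kinematics
  (13.5° radius, 0.25 turns/s, clockwise by default), flat pixel↔degree
  conversion (80°/1920 px), polar (phase/radius) decomposition of gaze
  relative to the trajectory, and the hypothetical baseline trajectories
  (tangent / stay / center).
- **`pursuitkit.synth`** — synthetic session generator: trial schedules
  (visible 1–2 s, occlusion 0–3 s, 0.05 s probe, 1 s feedback on a
  continuous timeline), an oculomotor model (smooth pursuit with catch-up
  saccades when the target is visible; anticipatory saccade sequences with
  an accumulating internal phase estimate and radius re-anchoring during
  occlusion), a two-rate discrimination-response model, and a scene-camera
  simulator (head-pose random walk + pinhole projections of four
  screen-corner markers with dropout).
- **`pursuitkit.headpose`** — unscented Kalman smoother for camera pose
  from marker-corner observations (forward UKF + backward RTS pass over a
  random-walk transition), per-frame pose fitting as a baseline, and
  gaze-to-screen mapping by ray/plane intersection.
- **`pursuitkit.segmentation`** — pupil-confidence filtering (default
  threshold 0.8), piecewise-linear gaze segmentation (greedy top-down
  split search with local refinement and a continuous least-squares
  refit), HMM/Viterbi classification into saccade vs pursuit/fixation,
  and visibility categorization (visible / occluded / crossing).
- **`pursuitkit.metrics`** — positional-error time series (60 Hz grid
  around occlusion onset), saccade launch/landing anticipation statistics
  with exact two-sided binomial tests, cumulative phase coverage by
  event class, pursuit gain from the phase component, discrimination
  summaries, and uncertainty accumulation (SD of launch errors over
  occlusion time, 500-point interpolation, ≥5-trace rule, post-0.5 s
  mixed-model regression with optional participant exclusion).
- **`pursuitkit.session` / `pursuitkit.pipeline` / `pursuitkit.cli`** —
  native file formats, session validation, and the end-to-end pipeline.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (deterministic
geometry/binomial checks, seeded parameter-recovery checks, and the
property bundle).

## CLI

```bash
# write a synthetic session directory (add --camera for a scene-camera
# gaze stream plus marker observations, exercising the head-pose stage)
pursuitkit simulate --seed 1 --n-trials 30 --out session/

# run the full analysis; writes tidy CSV tables + summary.json
pursuitkit analyze --session session/ --out analysis/

# render figures from an analysis directory
pursuitkit report --analysis analysis/

# single stages
pursuitkit headpose --session session/ --out pose.csv
pursuitkit segment --session session/ --out segments.csv

# dump the default YAML configuration
pursuitkit init-config --out config.yaml
```

`simulate` followed by `analyze` composes to exactly the in-process
`pursuitkit.pipeline.run_pipeline`.

## Session format

A session directory holds `gaze.csv` (t, u_px, v_px, confidence),
optional `markers.csv` (t, marker_id, corner_id, u_px, v_px),
`events.json` (trial windows, probe directions, responses, and meta:
participant id + whether gaze is in screen or scene-camera pixels), and
`config.yaml`. Synthetic sessions also carry `ground_truth.json` (true
oculomotor events, pose trajectory, and per-trial drift rates) for
testing. All times are float seconds on one session clock.

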