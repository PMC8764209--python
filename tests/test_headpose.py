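import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pursuitkit.geometry import TaskConfig
from pursuitkit.headpose import (
    CameraModel,
    NoiseConfig,
    PoseState,
    default_camera,
    fit_pose_frame,
    frames_from_dataframe,
    map_gaze_to_screen,
    marker_layout,
    project_markers,
    project_points,
    project_screen_point_to_camera,
    trajectory_log_likelihood,
    ukf_filter,
    uks_smooth,
)
from pursuitkit.synth import PoseDriftParams, simulate_camera


@pytest.fixture(scope="module")
def cam():
    return default_camera()


@pytest.fixture(scope="module")
def dropout_stream(cfg, cam):
    pp = PoseDriftParams(dropout=0.5, obs_noise_px=2.0)
    markers, true_pose = simulate_camera(20.0, pp, cam, cfg, seed=3)
    layout = marker_layout(cfg, pp.marker_size)
    times, obs = frames_from_dataframe(
        markers, layout, frame_times=true_pose["t"].to_numpy())
    truth = true_pose[["x", "y", "z", "yaw", "pitch", "roll"]].to_numpy()
    # noise terms matched to the generating random walk
    noise = NoiseConfig(pos_rate=0.01, rot_rate=0.01, obs_sd=2.0 / cam.focal)
    return times, obs, truth, noise


class TestProjection:
    def test_corner_on_optical_axis_projects_to_principal_point(self, cfg, cam):
        layout = marker_layout(cfg)
        corner = layout[0][0]  # a screen-plane point
        pose = PoseState(p=(corner[0], corner[1], 1.3), rot=(0.0, 0.0, 0.0))
        uv, valid = project_markers(pose, cam, corner[None, :2])
        assert valid[0]
        assert uv[0] == pytest.approx(cam.principal_point, abs=1e-9)

    def test_focal_doubling_doubles_offsets(self, cfg, cam):
        layout = marker_layout(cfg)
        pose = PoseState(p=(0.0, 0.0, 1.3), rot=(0.02, -0.01, 0.03))
        cam2 = CameraModel(focal=2 * cam.focal,
                           principal_point=cam.principal_point,
                           resolution=cam.resolution)
        uv1, _ = project_markers(pose, cam, layout[2])
        uv2, _ = project_markers(pose, cam2, layout[2])
        pp = np.asarray(cam.principal_point)
        assert np.allclose(uv2 - pp, 2 * (uv1 - pp), atol=1e-9)

    def test_matches_independent_rotation_oracle(self, cfg, cam):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = np.concatenate([
                rng.normal([0, 0, 1.3], 0.1), rng.normal(0.0, 0.1, 3)])
            pts = np.column_stack([rng.uniform(-0.8, 0.8, 6),
                                   rng.uniform(-0.5, 0.5, 6),
                                   np.zeros(6)])
            uv, valid = project_points(x, cam, pts)
            # oracle: scipy rotation + explicit transform and divide
            r_cam = Rotation.from_euler("YXZ", x[3:6]).as_matrix()
            c2w = np.diag([1.0, -1.0, -1.0]) @ r_cam
            pc = (pts - x[:3]) @ c2w
            exp_u = cam.focal * pc[:, 0] / pc[:, 2] + cam.principal_point[0]
            exp_v = cam.focal * pc[:, 1] / pc[:, 2] + cam.principal_point[1]
            assert np.all(valid)
            assert np.allclose(uv, np.column_stack([exp_u, exp_v]), atol=1e-9)

    def test_point_behind_camera_flagged(self, cam):
        x = np.array([0.0, 0.0, -1.0, 0.0, 0.0, 0.0])  # camera behind screen
        uv, valid = project_points(x, cam, np.array([[0.0, 0.0, 0.0]]))
        assert not valid[0]


class TestUKS:
    def test_static_zero_noise_recovers_pose(self, cfg, cam):
        pp = PoseDriftParams(pos_walk_sd=0.0, rot_walk_sd=0.0,
                             obs_noise_px=0.0, dropout=0.0,
                             base_position=(0.05, -0.03, 1.25),
                             base_rotation=(0.02, 0.01, -0.015))
        markers, true_pose = simulate_camera(3.0, pp, cam, cfg, seed=0)
        layout = marker_layout(cfg, pp.marker_size)
        times, obs = frames_from_dataframe(markers, layout)
        # noise terms matched to the noiseless stream; with the loose
        # defaults the UT's second-order curvature correction would bias
        # the weakly observable depth axis
        noise = NoiseConfig(pos_rate=1e-4, rot_rate=1e-4, obs_sd=1e-5)
        xs, _ = uks_smooth(times, obs, noise, cam)
        truth = true_pose[["x", "y", "z", "yaw", "pitch", "roll"]].to_numpy()
        assert np.max(np.abs(xs - truth)) < 1e-6

    def test_smoother_beats_filter_beats_perframe(self, dropout_stream, cam):
        times, obs, truth, noise = dropout_stream
        xs, _ = uks_smooth(times, obs, noise, cam)
        xf, _, _, _ = ukf_filter(times, obs, noise, cam)
        pf = np.array([fit_pose_frame(o[0], o[1], cam)
                       if o is not None else [np.nan] * 6 for o in obs])

        def rmse(est):
            return float(np.sqrt(np.nanmean((est - truth) ** 2)))

        assert rmse(xs) < rmse(xf) < rmse(pf)

    def test_smoothed_likelihood_at_least_filtered(self, dropout_stream, cam):
        times, obs, truth, noise = dropout_stream
        xs, _ = uks_smooth(times, obs, noise, cam)
        xf, _, _, _ = ukf_filter(times, obs, noise, cam)
        ll_s = trajectory_log_likelihood(xs, times, obs, noise, cam)
        ll_f = trajectory_log_likelihood(xf, times, obs, noise, cam)
        assert ll_s >= ll_f

    def test_deterministic(self, dropout_stream, cam):
        times, obs, _, noise = dropout_stream
        xs1, _ = uks_smooth(times, obs, noise, cam)
        xs2, _ = uks_smooth(times, obs, noise, cam)
        assert np.array_equal(xs1, xs2)

    def test_dropout_gap_interpolates_smoothly(self, cfg, cam):
        pp = PoseDriftParams(dropout=0.0, obs_noise_px=1.0)
        markers, true_pose = simulate_camera(10.0, pp, cam, cfg, seed=7)
        # knock out all markers for a 1-second stretch mid-sequence
        gap = (markers["t"] > 4.0) & (markers["t"] < 5.0)
        markers = markers[~gap]
        layout = marker_layout(cfg, pp.marker_size)
        times, obs = frames_from_dataframe(
            markers, layout, frame_times=true_pose["t"].to_numpy())
        noise = NoiseConfig(pos_rate=0.01, rot_rate=0.01, obs_sd=1.0 / cam.focal)
        xs, _ = uks_smooth(times, obs, noise, cam)
        steps = np.abs(np.diff(xs, axis=0))
        dt = float(np.median(np.diff(times)))
        bound = 3.0 * max(noise.pos_rate, noise.rot_rate) * np.sqrt(dt)
        in_gap = (times[:-1] > 4.0) & (times[:-1] < 5.0)
        assert np.max(steps[in_gap]) < bound

    def test_high_frequency_power_suppressed(self, dropout_stream, cam):
        times, obs, truth, noise = dropout_stream
        xs, _ = uks_smooth(times, obs, noise, cam)
        pf_list, keep = [], []
        for k, o in enumerate(obs):
            if o is not None:
                pf_list.append(fit_pose_frame(o[0], o[1], cam))
                keep.append(k)
        pf = np.array(pf_list)
        fs = 1.0 / float(np.median(np.diff(times)))

        def hf_power(sig):
            sig = sig - sig.mean(axis=0)
            spec = np.abs(np.fft.rfft(sig, axis=0)) ** 2
            freqs = np.fft.rfftfreq(len(sig), d=1.0 / fs)
            return float(spec[freqs > 10.0].sum())

        assert hf_power(xs[keep]) < 0.01 * hf_power(pf)

    def test_all_empty_stream_rejected(self, cam):
        with pytest.raises(ValueError):
            uks_smooth(np.array([0.0, 0.1]), [None, None], NoiseConfig(), cam)

    def test_non_monotone_times_rejected(self, cfg, cam):
        layout = marker_layout(cfg)
        pts = layout[0]
        x = np.array([0, 0, 1.2, 0, 0, 0.0])
        uv, _ = project_points(x, cam, pts)
        obs = [(pts, uv), (pts, uv)]
        with pytest.raises(ValueError):
            uks_smooth(np.array([0.1, 0.1]), obs, NoiseConfig(), cam)


class TestGazeMapping:
    def test_principal_point_square_on_maps_to_screen_center(self, cfg, cam):
        pose = np.array([0.0, 0.0, 1.24, 0.0, 0.0, 0.0])
        screen_px, valid = map_gaze_to_screen(
            np.array([cam.principal_point]), pose[None, :], cam, cfg)
        assert valid[0]
        w, h = cfg.screen_px
        assert screen_px[0] == pytest.approx([w / 2, h / 2], abs=1e-9)

    def test_round_trip_identity(self, cfg, cam):
        rng = np.random.default_rng(4)
        for _ in range(20):
            pose = np.concatenate([
                rng.normal([0, 0, 1.3], 0.05), rng.normal(0.0, 0.05, 3)])
            pt_sh = rng.uniform([-0.7, -0.45], [0.7, 0.45])
            uv, valid = project_screen_point_to_camera(pt_sh, pose, cam)
            assert valid[0]
            screen_px, ok = map_gaze_to_screen(uv, pose[None, :], cam, cfg)
            from pursuitkit.headpose import screen_px_to_sh

            assert ok[0]
            assert np.allclose(screen_px_to_sh(screen_px, cfg)[0], pt_sh,
                               atol=1e-9)

    def test_translation_shifts_mapped_point_equally(self, cfg, cam):
        base = np.array([0.0, 0.0, 1.24, 0.0, 0.0, 0.0])
        shifted = base.copy()
        shifted[0] += 0.1  # screen heights
        gaze = np.array([cam.principal_point])
        a, _ = map_gaze_to_screen(gaze, base[None, :], cam, cfg)
        b, _ = map_gaze_to_screen(gaze, shifted[None, :], cam, cfg)
        h = cfg.screen_px[1]
        assert (b - a)[0] == pytest.approx([0.1 * h, 0.0], abs=1e-9)

    def test_ray_away_from_screen_invalid(self, cfg, cam):
        # camera turned 180 degrees away
        pose = np.array([0.0, 0.0, 1.24, np.pi, 0.0, 0.0])
        _, valid = map_gaze_to_screen(np.array([cam.principal_point]),
                                      pose[None, :], cam, cfg)
        assert not valid[0]
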