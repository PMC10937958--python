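import numpy as np
import pandas as pd
import pytest

from lfpstate.behavior import (PoseTrack, BoutConfig, average_position,
                               compute_speed, detect_bouts, bout_statistics,
                               cumulative_turning, summarize_track)
from lfpstate.synth import generate_pose_track


def _track_from_parts(parts: dict, fps=25.0):
    df = pd.DataFrame({(bp, c): v for bp, xy in parts.items()
                       for c, v in zip(("x", "y"), xy)})
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["bodypart", "coord"])
    return PoseTrack(data=df, fps=fps)


class TestAveragePosition:
    def test_single_part_identity(self):
        x = np.arange(10.0)
        track = _track_from_parts({"body": (x, 2 * x)})
        np.testing.assert_array_equal(average_position(track),
                                      np.column_stack([x, 2 * x]))

    def test_two_parts_midpoint(self):
        track = _track_from_parts({"a": (np.zeros(5), np.zeros(5)),
                                   "b": (np.full(5, 2.0), np.full(5, 2.0))})
        assert np.all(average_position(track) == 1.0)

    def test_missing_part_ignored(self):
        xa = np.zeros(5)
        xb = np.full(5, 2.0)
        xc = np.full(5, np.nan)
        track = _track_from_parts({"a": (xa, xa), "b": (xb, xb), "c": (xc, xc)})
        assert np.all(average_position(track)[:, 0] == 1.0)


class TestComputeSpeed:
    def test_static_centroid_zero(self):
        speed = compute_speed(np.ones((100, 2)), 25.0)
        assert np.all(speed == 0.0)

    def test_constant_displacement(self):
        pos = np.column_stack([0.2 * np.arange(50), np.zeros(50)])
        speed = compute_speed(pos, 25.0)
        np.testing.assert_allclose(speed, 5.0)

    def test_circular_motion_matches_analytic(self):
        fps, r, omega = 250.0, 10.0, 2 * np.pi * 0.25
        t = np.arange(int(4 * fps)) / fps
        pos = np.column_stack([r * np.cos(omega * t), r * np.sin(omega * t)])
        speed = compute_speed(pos, fps)
        assert np.median(speed) == pytest.approx(r * omega, rel=0.01)


class TestDetectBouts:
    def test_constant_supra_threshold_one_bout(self):
        speed = np.full(250, 3.0)
        bouts = detect_bouts(speed, 25.0)
        assert len(bouts) == 1
        assert bouts[0].duration_s == pytest.approx(10.0)

    def test_sub_threshold_no_bouts(self):
        assert detect_bouts(np.full(250, 1.0), 25.0) == []

    def test_minimum_duration_is_13_frames_at_25fps(self):
        speed = np.zeros(100)
        speed[10:22] = 5.0       # 12 frames: just under 0.5 s
        assert detect_bouts(speed, 25.0, BoutConfig(smoothing_frames=1)) == []
        speed[10:23] = 5.0       # 13 frames
        bouts = detect_bouts(speed, 25.0, BoutConfig(smoothing_frames=1))
        assert len(bouts) == 1

    def test_schedule_recovered_from_generator(self):
        schedule = [(5.0, 8.0, 6.0), (20.0, 22.0, 5.0), (40.0, 45.0, 8.0),
                    (60.0, 63.0, 4.0), (80.0, 86.0, 10.0)]
        track = generate_pose_track(schedule, duration_s=100.0, noise_cm=0.0)
        centroid = average_position(track)
        speed = compute_speed(centroid, track.fps)
        bouts = detect_bouts(speed, track.fps)
        assert len(bouts) == len(schedule)
        for bout, (s0, e0, _) in zip(bouts, schedule):
            assert abs(bout.start_frame - s0 * 25) <= 1
            assert abs(bout.end_frame - e0 * 25) <= 1


class TestBoutStatistics:
    def test_rate_per_minute(self):
        speed = np.zeros(20 * 60 * 25)
        for k in range(6):
            i0 = k * 5000
            speed[i0:i0 + 50] = 5.0
        bouts = detect_bouts(speed, 25.0)
        stats = bout_statistics(bouts, window_s=20 * 60)
        assert stats["rate_per_min"] == pytest.approx(0.3)

    def test_no_bouts_missing_means(self):
        stats = bout_statistics([], window_s=60.0)
        assert stats["rate_per_min"] == 0.0
        assert np.isnan(stats["mean_speed"])

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            bout_statistics([], window_s=0.0)


class TestCumulativeTurning:
    def test_straight_path_zero(self):
        pos = np.column_stack([np.linspace(0, 50, 200), np.zeros(200)])
        assert abs(cumulative_turning(pos, 25.0)) < 1.0

    def test_counterclockwise_circle(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=True)
        pos = 20 * np.column_stack([np.cos(t), np.sin(t)])
        assert cumulative_turning(pos, 25.0) == pytest.approx(360.0, abs=5.0)

    def test_clockwise_circle_negative(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=True)
        pos = 20 * np.column_stack([np.cos(-t), np.sin(-t)])
        assert cumulative_turning(pos, 25.0) == pytest.approx(-360.0, abs=5.0)

    def test_generator_turn_rate_integrates(self):
        track = generate_pose_track([(0.0, 60.0, 5.0)], duration_s=60.0,
                                    turn_rate_deg_s=10.0, noise_cm=0.0,
                                    arena_diameter_cm=200.0)
        centroid = average_position(track)
        total = cumulative_turning(centroid, track.fps)
        assert total == pytest.approx(600.0, abs=5.0)


class TestGeneratorContracts:
    def test_empty_schedule_zero_speed(self):
        track = generate_pose_track([], duration_s=10.0, noise_cm=0.0)
        speed = compute_speed(average_position(track), track.fps)
        assert np.max(speed) == 0.0

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            generate_pose_track([(0.0, 5.0, 5.0), (4.0, 8.0, 5.0)],
                                duration_s=10.0)

    def test_speed_translation_rotation_invariance(self):
        track = generate_pose_track([(1.0, 4.0, 5.0)], duration_s=5.0,
                                    noise_cm=0.0)
        pos = average_position(track)
        speed0 = compute_speed(pos, track.fps)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        speed1 = compute_speed(pos @ rot.T + np.array([5.0, -3.0]), track.fps)
        np.testing.assert_allclose(speed1, speed0, atol=1e-9)

    def test_dlc_csv_round_trip(self, tmp_path):
        track = generate_pose_track([(1.0, 3.0, 5.0)], duration_s=5.0,
                                    noise_cm=0.0, seed=1)
        path = tmp_path / "track.csv"
        track.to_dlc_csv(path)
        back = PoseTrack.from_dlc_csv(path)
        np.testing.assert_allclose(back.data.to_numpy(),
                                   track.data.to_numpy(), atol=1e-9)

    def test_higher_bout_rate_detected(self):
        """Psychotomimetic-like schedules show more bouts than baseline ones."""
        from lfpstate.synth import draw_episode_schedule
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            lo = [(s, e, 6.0) for s, e in
                  draw_episode_schedule(2.0, 300.0, (1.0, 3.0), rng)]
            hi = [(s, e, 6.0) for s, e in
                  draw_episode_schedule(8.0, 300.0, (1.0, 3.0), rng)]
            t_lo = generate_pose_track(lo, duration_s=300.0, seed=rng)
            t_hi = generate_pose_track(hi, duration_s=300.0, seed=rng)
            n_lo = summarize_track(t_lo)["n_bouts"]
            n_hi = summarize_track(t_hi)["n_bouts"]
            wins += n_hi > n_lo
        assert wins == 10
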