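import numpy as np
import pytest

from vestib import (
    ExerciseConfig,
    FrameRecord,
    MotionSimParams,
    compute_adherence,
    compute_session_metrics,
    run_gaze_shift_session,
    run_remembered_target_session,
    run_session,
    run_vorx_session,
    speed_preset_value,
)
from vestib.exercises import read_frame_log, write_frame_log
from vestib.synthetic import (
    simulate_gaze_shift_stream,
    simulate_remembered_target_stream,
)
from conftest import make_stream


def ramp_stream(slope_dps, duration_s=31.0, rate_hz=10.0, gaze_x=0.5, gaze_y=0.5):
    """Constant-velocity yaw ramp with gaze pinned to one point."""
    t = np.arange(int(duration_s * rate_hz) + 1) / rate_hz
    return make_stream(t, yaw=slope_dps * t, gaze_x=gaze_x, gaze_y=gaze_y)


class TestSpeedPresets:
    def test_horizontal_values(self):
        assert [speed_preset_value("horizontal", p)
                for p in ("slow", "medium", "fast", "fastest")] == [60.0, 120.0, 180.0, 240.0]

    def test_vertical_values(self):
        assert [speed_preset_value("vertical", p)
                for p in ("slow", "medium", "fast", "fastest")] == [45.0, 78.0, 88.0, 95.0]

    def test_unknown_axis_or_preset(self):
        with pytest.raises(ValueError, match="axis"):
            speed_preset_value("diagonal", "slow")
        with pytest.raises(ValueError, match="preset"):
            speed_preset_value("horizontal", "ludicrous")


class TestExerciseConfig:
    def test_duration_bounds(self):
        ExerciseConfig(duration_s=30.0)
        ExerciseConfig(duration_s=120.0)
        for bad in (29.9, 120.1):
            with pytest.raises(ValueError, match="duration"):
                ExerciseConfig(duration_s=bad)

    def test_unknown_game(self):
        with pytest.raises(ValueError, match="game"):
            ExerciseConfig(game="tetris")

    def test_threshold_resolves_from_axis_and_preset(self):
        cfg = ExerciseConfig(axis="vertical", speed_preset="medium")
        assert cfg.threshold_dps == 78.0
        assert cfg.head_axis == "pitch"
        assert cfg.screen_axis == "y"

    def test_dict_round_trip(self):
        cfg = ExerciseConfig(game="gaze_shift", duration_s=45.0, speed_preset="fast")
        assert ExerciseConfig.from_dict(cfg.to_dict()) == cfg


class TestVorxSession:
    def test_full_speed_stream_grows_plant_to_one(self):
        cfg = ExerciseConfig(game="vorx1", duration_s=30.0)
        frames, metrics = run_vorx_session(cfg, ramp_stream(200.0))
        assert metrics.final_plant_size == 1.0
        assert metrics.pct_time_eyes_on_target == pytest.approx(100.0)
        assert metrics.pct_time_both == pytest.approx(100.0)
        assert metrics.mean_speed == pytest.approx(200.0, rel=1e-6)

    def test_sub_threshold_stream_grows_nothing(self):
        cfg = ExerciseConfig(game="vorx1", duration_s=30.0)
        frames, metrics = run_vorx_session(cfg, ramp_stream(5.0))
        assert metrics.final_plant_size == 0.0
        assert metrics.pct_time_head_above_threshold == 0.0

    def test_eyes_off_target_stops_growth_after_grace(self):
        cfg = ExerciseConfig(game="vorx1", duration_s=30.0)
        frames, metrics = run_vorx_session(cfg, ramp_stream(200.0, gaze_x=0.95))
        assert metrics.pct_time_eyes_on_target == 0.0
        # growth only during the initial grace period: 0.5 s of 30 s
        assert metrics.final_plant_size == pytest.approx(0.5 / 30.0, abs=0.01)

    def test_plant_is_monotone_and_bounded(self):
        cfg = ExerciseConfig(game="vorx1", duration_s=30.0)
        frames, _ = run_vorx_session(cfg, ramp_stream(200.0))
        sizes = [f.plant_size for f in frames]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))
        assert all(0.0 <= s <= 1.0 for s in sizes)

    def test_vorx2_target_moves_antiphase(self):
        # gaze that tracks 0.5 - yaw/30 stays on the vorx2 target
        rate = 50.0
        t = np.arange(int(31 * rate) + 1) / rate
        # +-6 deg triangle wave at 120 deg/s
        period = 4 * 6 / 120.0
        phase = (t / period) % 1.0
        yaw = 6.0 * (4 * np.abs(phase - 0.5) - 1.0)
        gaze_x = 0.5 - yaw / 30.0
        stream = make_stream(t, yaw=yaw, gaze_x=gaze_x)
        cfg = ExerciseConfig(game="vorx2", duration_s=30.0)
        frames, metrics = run_vorx_session(cfg, stream)
        assert metrics.pct_time_eyes_on_target == pytest.approx(100.0)
        # the same gaze trace is far from the *stationary* vorx1 target
        # whenever the head is deflected, so x1 scoring must differ
        cfg1 = ExerciseConfig(game="vorx1", duration_s=30.0)
        _, metrics1 = run_vorx_session(cfg1, stream)
        assert metrics1.pct_time_eyes_on_target < 100.0

    def test_too_short_stream_is_an_error(self):
        cfg = ExerciseConfig(game="vorx1", duration_s=30.0)
        with pytest.raises(ValueError, match="stream ends"):
            run_vorx_session(cfg, ramp_stream(200.0, duration_s=20.0))

    def test_wrong_game_rejected(self):
        cfg = ExerciseConfig(game="gaze_shift", duration_s=30.0)
        with pytest.raises(ValueError, match="vorx"):
            run_vorx_session(cfg, ramp_stream(200.0))


@pytest.fixture(scope="module")
def gaze_shift_result():
    params = MotionSimParams(
        seed=5, amplitude_deg=20.0, noise_sd_deg=0.0, noise_sd_norm=0.0,
        duration_s=31.0,
    )
    stream = simulate_gaze_shift_stream(params)
    cfg = ExerciseConfig(game="gaze_shift", duration_s=30.0)
    return run_gaze_shift_session(cfg, stream)


class TestGazeShiftSession:
    def test_counts_one_rep_per_side_switch(self, gaze_shift_result):
        _, metrics = gaze_shift_result
        # the scripted stream switches sides every 2 s; each switch yields
        # one eye-then-head repetition inside the 30 s scored block
        assert metrics.reps == 15

    def test_latency_is_eye_to_head_interval(self, gaze_shift_result):
        _, metrics = gaze_shift_result
        # gaze jumps 0.15 s into each period; the head ramps across the full
        # +-20 deg span between 0.2 s and 0.6 s, crossing the 15 deg
        # tolerance at 0.55 s -> median eye-to-head latency ~0.40 s
        assert metrics.median_eye_head_latency_s == pytest.approx(0.40, abs=0.03)


class TestRememberedTargetSession:
    def run(self, reopen_error_norm):
        params = MotionSimParams(
            seed=9, amplitude_deg=30.0, noise_sd_deg=0.0, noise_sd_norm=0.0,
            duration_s=31.0,
        )
        stream = simulate_remembered_target_stream(
            params, trials=5, reopen_error_norm=reopen_error_norm
        )
        cfg = ExerciseConfig(game="remembered_target", duration_s=30.0)
        return run_remembered_target_session(cfg, stream)

    def test_perfect_reopening_deals_full_damage(self):
        _, metrics = self.run(0.0)
        assert metrics.n_trials == 5
        assert metrics.damage_per_trial == pytest.approx(1.0)
        assert metrics.total_damage == 1.0  # capped

    def test_damage_decreases_with_reopening_error(self):
        damages = [self.run(e)[1].damage_per_trial for e in (0.0, 0.05, 0.12)]
        assert damages[0] > damages[1] > damages[2] > 0.0

    def test_error_beyond_three_radii_deals_nothing(self):
        _, metrics = self.run(0.35)
        assert metrics.n_trials == 5
        assert metrics.damage_per_trial == 0.0


class TestRunSessionDispatch:
    def test_dispatches_by_game(self):
        cfg = ExerciseConfig(game="vorx1", duration_s=30.0)
        frames, metrics = run_session(cfg, ramp_stream(200.0))
        assert metrics.final_plant_size == 1.0


class TestSessionMetrics:
    def test_hand_computed_time_weighting(self):
        def fr(t, eyes, head, speed, plant):
            return FrameRecord(t=t, gaze_x=0.5, gaze_y=0.5, head_pitch=0.0,
                               head_yaw=0.0, head_roll=0.0, head_velocity=speed,
                               eyes_on_target=eyes, head_on_target=head,
                               plant_size=plant)

        frames = [
            fr(0.0, True, True, 100.0, 0.0),   # weight 0 (no preceding interval)
            fr(1.0, True, False, 80.0, 0.1),   # weight 1/3
            fr(3.0, False, True, 60.0, 0.2),   # weight 2/3
        ]
        m = compute_session_metrics(frames)
        assert m.pct_time_eyes_on_target == pytest.approx(100.0 / 3)
        assert m.pct_time_head_above_threshold == pytest.approx(200.0 / 3)
        assert m.pct_time_both == pytest.approx(0.0)
        assert m.mean_speed == pytest.approx((80.0 + 2 * 60.0) / 3)
        assert m.peak_speed == 100.0
        assert m.final_plant_size == 0.2

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            compute_session_metrics([])


class TestAdherence:
    def test_weekly_and_overall(self):
        out = compute_adherence([10, 5, 12], [10, 10, 10])
        assert out["weekly_pct"] == [100.0, 50.0, 120.0]
        assert out["overall_pct"] == pytest.approx(90.0)
        assert out["weeks_over_100"] == [3]

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_adherence([1], [1, 2])
        with pytest.raises(ValueError):
            compute_adherence([], [])
        with pytest.raises(ValueError, match="positive"):
            compute_adherence([1], [0])


class TestFrameLogIO:
    def test_round_trip(self, tmp_path):
        cfg = ExerciseConfig(game="vorx1", duration_s=30.0)
        frames, _ = run_vorx_session(cfg, ramp_stream(200.0))
        path = tmp_path / "frames.csv"
        write_frame_log(frames, path)
        back = read_frame_log(path)
        assert len(back) == len(frames)
        assert back[-1].plant_size == pytest.approx(frames[-1].plant_size)
        assert back[0].eyes_on_target == frames[0].eyes_on_target

    def test_replayed_log_reproduces_metrics(self, tmp_path):
        cfg = ExerciseConfig(game="vorx1", duration_s=30.0)
        frames, metrics = run_vorx_session(cfg, ramp_stream(200.0))
        path = tmp_path / "frames.csv"
        write_frame_log(frames, path)
        replayed = compute_session_metrics(read_frame_log(path))
        assert replayed.pct_time_both == pytest.approx(metrics.pct_time_both)
        assert replayed.final_plant_size == pytest.approx(metrics.final_plant_size)

    def test_missing_column_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t_s,gaze_x\n0.0,0.5\n")
        with pytest.raises(ValueError, match="missing column"):
            read_frame_log(path)
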