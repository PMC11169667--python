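import numpy as np
import pytest

from vestib import (
    AcuityResult,
    MotionSimParams,
    ObserverParams,
    StaircaseState,
    TriggerParams,
    find_optotype_onsets,
    make_observer,
    pacing_from_bpm,
    predict_zero_crossing,
    run_dva,
    run_sva,
    should_display_optotype,
    staircase_update,
)
from vestib.dva import StreamExhaustedError, write_trial_log
from vestib.synthetic import head_positions, simulate_vorx_stream, true_zero_crossings
from conftest import sine_positions


class TestPacing:
    def test_one_beat_is_half_a_cycle(self):
        p = pacing_from_bpm(60.0)
        assert p.half_cycle_s == 1.0
        assert p.cycle_hz == 0.5

    def test_other_tempi(self):
        assert pacing_from_bpm(90.0).cycle_hz == 0.75
        assert pacing_from_bpm(120.0).cycle_hz == 1.0

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            pacing_from_bpm(0.0)


class TestPredictZeroCrossing:
    def test_exact_line(self):
        # theta = 10 - 100 t crosses zero at t = 0.1
        hist = [(t, 10.0 - 100.0 * t) for t in (0.0, 0.01, 0.02, 0.03, 0.04)]
        will, t_cross = predict_zero_crossing(hist, horizon_ms=130.0)
        assert will
        assert t_cross == pytest.approx(0.1, abs=1e-9)

    def test_crossing_beyond_horizon(self):
        hist = [(t, 30.0 - 100.0 * t) for t in (0.0, 0.01, 0.02, 0.03, 0.04)]
        will, t_cross = predict_zero_crossing(hist, horizon_ms=130.0)
        assert not will and t_cross is None

    def test_moving_away_never_crosses(self):
        hist = [(t, 10.0 + 100.0 * t) for t in (0.0, 0.01, 0.02)]
        will, _ = predict_zero_crossing(hist, horizon_ms=130.0)
        assert not will

    def test_needs_history(self):
        with pytest.raises(ValueError):
            predict_zero_crossing([(0.0, 1.0)])


class TestDisplayGates:
    def hist(self, theta0=10.0, slope=-100.0):
        return [(t, theta0 + slope * t) for t in (0.0, 0.01, 0.02, 0.03, 0.04)]

    def test_fires_when_all_gates_pass(self):
        assert should_display_optotype(self.hist(), velocity_now=-100.0)

    def test_blocked_outside_center_limit(self):
        hist = [(t, 25.0 - 100.0 * t) for t in (0.0, 0.01)]
        assert not should_display_optotype(hist, velocity_now=-100.0)

    def test_blocked_when_too_slow(self):
        assert not should_display_optotype(self.hist(), velocity_now=-50.0)

    def test_blocked_when_moving_away_from_center(self):
        hist = self.hist(theta0=-10.0, slope=-100.0)
        assert not should_display_optotype(hist, velocity_now=-100.0)

    def test_blocked_when_crossing_beyond_horizon(self):
        hist = [(t, 30.0 - 100.0 * t) for t in (0.0, 0.01)]
        assert not should_display_optotype(hist, velocity_now=-100.0)


class TestFindOnsets:
    def test_one_onset_per_crossing_on_noiseless_sine(self):
        # 90 bpm pacing: 0.75 Hz, crossings every 2/3 s
        positions = sine_positions(25.5, 0.75, 90.0, 20.0)
        onsets = find_optotype_onsets(positions)
        crossings = [k * (2 / 3) for k in range(int(20.0 / (2 / 3)) + 1)]
        # interior crossings each get exactly one onset
        assert len(onsets) == pytest.approx(len(crossings), abs=1)
        t_on = [o.t_on for o in onsets]
        assert all(b > a for a, b in zip(t_on, t_on[1:]))

    def test_onsets_alternate_direction(self):
        positions = sine_positions(25.5, 0.75, 90.0, 10.0)
        onsets = find_optotype_onsets(positions)
        dirs = [o.direction_at_on for o in onsets]
        assert set(dirs) <= {"leftward", "rightward"}
        assert all(a != b for a, b in zip(dirs, dirs[1:]))

    def test_onset_near_true_crossing_of_lagged_trace(self):
        # the trace reports with 130 ms lag, exactly the anticipation horizon,
        # so onsets should land near the *true* (unlagged) crossings
        positions = sine_positions(25.5, 0.75, 90.0, 20.0, phase_lag_s=0.13)
        onsets = find_optotype_onsets(positions)
        crossings = np.array([k * (2 / 3) for k in range(40)])
        for o in onsets:
            err = np.min(np.abs(crossings - o.t_on))
            assert err < 0.05  # within ~4 samples of the true crossing

    def test_no_onsets_below_speed_gate(self):
        # peak velocity 2*pi*0.5*10 = 31 deg/s, under the 60 deg/s gate
        positions = sine_positions(10.0, 0.5, 90.0, 10.0)
        assert find_optotype_onsets(positions) == []


class TestStaircase:
    def test_correct_descends_one_line(self):
        s = staircase_update(StaircaseState(current_logmar=1.0), correct=True)
        assert s.current_logmar == pytest.approx(0.9)
        assert not s.terminated

    def test_incorrect_represents_same_size(self):
        s = staircase_update(StaircaseState(current_logmar=0.5), correct=False)
        assert s.current_logmar == 0.5
        assert s.consecutive_incorrect == 1
        assert not s.terminated

    def test_three_consecutive_incorrect_terminates(self):
        s = StaircaseState(current_logmar=0.5)
        for _ in range(3):
            s = staircase_update(s, correct=False)
        assert s.terminated
        # acuity is the smallest size answered correctly: one line above
        assert s.acuity_logmar == pytest.approx(0.6)

    def test_incorrect_streak_reset_by_correct(self):
        s = StaircaseState(current_logmar=0.5)
        s = staircase_update(s, correct=False)
        s = staircase_update(s, correct=False)
        s = staircase_update(s, correct=True)
        assert s.consecutive_incorrect == 0
        assert not s.terminated

    def test_correct_at_floor_terminates_with_floor(self):
        s = StaircaseState(current_logmar=0.0, floor_logmar=0.0)
        s = staircase_update(s, correct=True)
        assert s.terminated
        assert s.acuity_logmar == 0.0

    def test_update_after_termination_rejected(self):
        s = StaircaseState(current_logmar=0.0)
        s = staircase_update(s, correct=True)
        with pytest.raises(ValueError):
            staircase_update(s, correct=True)

    def test_history_records_every_presentation(self):
        s = StaircaseState(current_logmar=0.3)
        s = staircase_update(s, correct=True, orientation="up", response="up")
        s = staircase_update(s, correct=False, orientation="left", response="up")
        assert len(s.history) == 2
        assert s.history[0] == (0.3, "up", "up", True)
        assert s.history[1] == (0.2, "left", "up", False)


class TestRunSva:
    def test_deterministic_threshold_observer(self):
        def observer(logmar, orientation):
            return orientation if logmar >= 0.25 else "wrong"

        result = run_sva(observer, seed=1)
        assert result.acuity_logmar == pytest.approx(0.3)
        assert result.mode == "sva"

    def test_perfect_observer_reaches_floor(self):
        result = run_sva(lambda lm, o: o, seed=1)
        assert result.acuity_logmar == 0.0


class TestRunDva:
    def observer(self, threshold):
        def f(logmar, orientation):
            return orientation if logmar >= threshold else "nope"

        return f

    def test_staircase_over_paced_motion(self):
        params = MotionSimParams(seed=21, amplitude_deg=25.5, cycle_hz=None, bpm=90.0,
                                 noise_sd_deg=0.0, noise_sd_norm=0.0, duration_s=60.0)
        stream = simulate_vorx_stream(params)
        result = run_dva(self.observer(0.45), head_positions(stream), seed=4)
        assert result.mode == "dva"
        assert result.acuity_logmar == pytest.approx(0.5)
        assert result.n_trials >= 8
        # every presentation happened near a true head zero crossing: the
        # trigger anticipates the *reported* crossing by the 130 ms latency,
        # which lands the flash back on the true one
        crossings = np.array(true_zero_crossings(params))
        for tr in result.trials:
            assert np.min(np.abs(crossings - tr.t_on)) < 0.1

    def test_per_direction_acuity_reported(self):
        params = MotionSimParams(seed=22, amplitude_deg=25.5, cycle_hz=None, bpm=90.0,
                                 noise_sd_deg=0.0, noise_sd_norm=0.0, duration_s=90.0)
        stream = simulate_vorx_stream(params)
        result = run_dva(self.observer(0.45), head_positions(stream), seed=4)
        assert set(result.acuity_by_direction) == {"leftward", "rightward"}
        for v in result.acuity_by_direction.values():
            assert v >= result.acuity_logmar >= 0.0

    def test_exhausted_stream_carries_partial_trials(self):
        params = MotionSimParams(seed=23, amplitude_deg=25.5, cycle_hz=None, bpm=90.0,
                                 noise_sd_deg=0.0, noise_sd_norm=0.0, duration_s=5.0)
        stream = simulate_vorx_stream(params)
        with pytest.raises(StreamExhaustedError) as exc:
            run_dva(self.observer(0.0), head_positions(stream), seed=4)
        assert len(exc.value.trials) >= 1


class TestTrialLog:
    def test_write(self, tmp_path):
        result = run_sva(lambda lm, o: o, seed=1)
        path = tmp_path / "trials.csv"
        write_trial_log(result.trials, path)
        text = path.read_text()
        assert text.splitlines()[0].startswith("trial_idx,t_on,logmar")
        assert len(text.splitlines()) == result.n_trials + 1
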