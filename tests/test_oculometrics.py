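import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gazeflight as gf
from gazeflight.preprocess import AngularTrace, FlightWindow, KinematicTrace
from gazeflight.oculometrics import (
    SaccadeEvent,
    TaskGeometry,
    classify_prediction,
    coherence_and_lag,
    detect_saccades,
    pursuit_gain,
)
from conftest import make_trial

FS = 120.0


def _kin(vel, t=None, valid=None, plane="combined"):
    n = len(vel)
    t = np.arange(n) / FS if t is None else t
    vel = np.asarray(vel, float)
    acc = np.gradient(vel, t)
    return KinematicTrace(t=t, velocity=vel, acceleration=acc,
                         valid=np.ones(n, bool) if valid is None else valid,
                         plane=plane)


def _min_jerk_speed(n, onset, dur_frames, amplitude):
    """Speed profile of a minimum-jerk step on an otherwise static trace."""
    v = np.zeros(n)
    tau = (np.arange(n) - onset) / dur_frames
    inside = (tau >= 0) & (tau <= 1)
    v[inside] = 30 * amplitude * (tau[inside]**2 - 2 * tau[inside]**3
                                  + tau[inside]**4) * FS / dur_frames
    return v


class TestDetectSaccades:
    def _window(self, n):
        return FlightWindow(0, n - 1, min(3, n - 1))

    def test_constant_velocity_pursuit_yields_no_events(self):
        n = 60
        eye = _kin(np.full(n, 20.0))
        ball = _kin(np.full(n, 20.0))
        assert detect_saccades(eye, ball, np.ones(n, bool), self._window(n)) == []

    def test_single_step_detected_with_correct_bounds(self):
        # brute-force oracle: the region where the analytic minimum-jerk speed
        # exceeds threshold must lie inside the reported event
        n = 80
        speed = _min_jerk_speed(n, onset=40, dur_frames=7, amplitude=10.0)
        eye = _kin(speed)
        ball = _kin(np.zeros(n))
        events = detect_saccades(eye, ball, np.ones(n, bool), self._window(n))
        assert len(events) == 1
        ev = events[0]
        fast = np.flatnonzero(speed > 40.0)
        assert ev.onset_t <= fast[0] / FS
        assert ev.offset_t >= fast[-1] / FS
        assert ev.peak_velocity == pytest.approx(speed.max(), rel=1e-6)

    def test_step_preceded_by_missing_data_discarded(self):
        n = 80
        speed = _min_jerk_speed(n, onset=40, dur_frames=7, amplitude=10.0)
        eye = _kin(speed)
        ball = _kin(np.zeros(n))
        valid = np.ones(n, bool)
        valid[37:39] = False  # the two frames before the burst
        events = detect_saccades(eye, ball, valid, self._window(n))
        assert events == []

    def test_slow_step_fails_velocity_rule(self):
        n = 80
        speed = _min_jerk_speed(n, onset=40, dur_frames=7, amplitude=1.0)  # peak ~32 deg/s
        eye = _kin(speed)
        ball = _kin(np.zeros(n))
        assert detect_saccades(eye, ball, np.ones(n, bool), self._window(n)) == []

    def test_step_not_exceeding_ball_speed_rejected(self):
        n = 80
        speed = _min_jerk_speed(n, onset=40, dur_frames=7, amplitude=10.0)
        eye = _kin(speed)
        ball = _kin(np.full(n, speed.max()))  # ball as fast as the saccade peak
        assert detect_saccades(eye, ball, np.ones(n, bool), self._window(n)) == []

    def test_short_window_rejected(self):
        eye = _kin(np.zeros(10))
        ball = _kin(np.zeros(10))
        with pytest.raises(ValueError, match="frames"):
            detect_saccades(eye, ball, np.ones(10, bool), FlightWindow(0, 3, 2))

    def test_all_invalid_window_warns_and_returns_empty(self):
        n = 40
        eye = _kin(np.zeros(n))
        ball = _kin(np.zeros(n))
        with pytest.warns(UserWarning, match="no valid samples"):
            assert detect_saccades(eye, ball, np.zeros(n, bool), self._window(n)) == []

    def test_event_invariants(self):
        with pytest.raises(ValueError):
            SaccadeEvent(onset_t=1.0, offset_t=0.5, peak_velocity=100, amplitude=5)
        with pytest.raises(ValueError):
            SaccadeEvent(onset_t=0.0, offset_t=0.1, peak_velocity=100, amplitude=-1)


class TestCoherenceAndLag:
    def _smooth(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n + 40)
        k = np.hanning(15)
        return np.convolve(x, k / k.sum(), mode="same")[20:-20]

    def test_identical_series(self):
        v = self._smooth(60, 0)
        coh, lag = coherence_and_lag(v, v, FS)
        assert coh == pytest.approx(1.0, abs=1e-12)
        assert lag == 0.0

    def test_pure_delay_recovered(self):
        v = self._smooth(120, 1)
        k0 = 6  # 50 ms at 120 Hz
        eye = np.roll(v, k0)
        coh, lag = coherence_and_lag(eye[20:-20], v[20:-20], FS)
        assert lag == pytest.approx(k0 / FS, abs=1e-12)
        assert coh > 0.99

    def test_brute_force_oracle_agreement(self):
        # independent oracle: recompute the lagged-Pearson search from scratch
        eye = self._smooth(80, 2)
        ball = self._smooth(80, 3)
        coh, lag = coherence_and_lag(eye, ball, FS, max_lag=0.1)
        best_r, best_k = -2.0, None
        n = len(eye)
        for k in range(-12, 13):
            e = eye[k:] if k >= 0 else eye[:n + k]
            b = ball[:n - k] if k >= 0 else ball[-k:]
            if len(e) < 10:
                continue
            r = np.corrcoef(e, b)[0, 1]
            if r > best_r or (r == best_r and abs(k) < abs(best_k)):
                best_r, best_k = r, k
        assert coh == pytest.approx(best_r, abs=1e-12)
        assert lag == pytest.approx(best_k / FS, abs=1e-12)

    def test_anticorrelated_series(self):
        v = self._smooth(60, 4)
        r0 = np.corrcoef(-v, v)[0, 1]
        assert r0 == pytest.approx(-1.0, abs=1e-12)
        coh, _ = coherence_and_lag(-v, v, FS)
        assert coh >= -1.0

    def test_zero_variance_flagged_missing(self):
        coh, lag = coherence_and_lag(np.zeros(40), np.ones(40), FS)
        assert np.isnan(coh) and np.isnan(lag)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), offset=st.floats(-20.0, 20.0))
    def test_affine_invariance(self, scale, offset):
        eye = self._smooth(60, 5)
        ball = self._smooth(60, 6)
        coh1, lag1 = coherence_and_lag(eye, ball, FS)
        coh2, lag2 = coherence_and_lag(scale * eye + offset, ball, FS)
        assert coh2 == pytest.approx(coh1, abs=1e-9)
        assert lag2 == lag1

    def test_ties_break_toward_zero_lag(self):
        v = np.tile([1.0, -1.0], 30)  # period-2 signal: equal r at many lags
        coh, lag = coherence_and_lag(v, v, FS, max_lag=0.05)
        assert lag == 0.0


class TestPursuitGain:
    def _setup(self, eye_vel, ball_vel):
        n = len(eye_vel)
        eye = _kin(eye_vel, plane="yaw")
        ball = _kin(ball_vel, plane="yaw")
        win = FlightWindow(0, n - 1, 1)
        return eye, ball, win

    def test_identity_gain(self):
        v = np.linspace(10, 60, 50)
        eye, ball, win = self._setup(v, v)
        assert pursuit_gain(eye, ball, [], win) == pytest.approx(1.0)

    def test_stationary_eye(self):
        eye, ball, win = self._setup(np.zeros(50), np.linspace(10, 60, 50))
        assert pursuit_gain(eye, ball, [], win) == pytest.approx(0.0)

    def test_half_velocity_pointwise(self):
        # brute-force: ratio of sample-wise means computed directly
        v = np.linspace(5, 80, 60)
        eye, ball, win = self._setup(0.5 * v, v)
        expected = np.mean(0.5 * v[1:-1]) / np.mean(v[1:-1])
        assert pursuit_gain(eye, ball, [], win) == pytest.approx(expected)

    def test_saccade_intervals_removed(self):
        v = np.full(60, 30.0)
        ev = 30.0 * np.ones(60)
        ev[20:27] = 300.0  # a saccadic burst that would inflate the mean
        eye, ball, win = self._setup(ev, v)
        sacc = [SaccadeEvent(onset_t=20 / FS, offset_t=26 / FS,
                             peak_velocity=300.0, amplitude=10.0)]
        assert pursuit_gain(eye, ball, sacc, win) == pytest.approx(1.0)

    def test_too_few_samples_gives_nan(self):
        v = np.linspace(10, 20, 6)
        eye, ball, win = self._setup(v, v)
        sacc = [SaccadeEvent(onset_t=0.0, offset_t=1.0,
                             peak_velocity=100.0, amplitude=5.0)]
        assert np.isnan(pursuit_gain(eye, ball, sacc, win))

    def test_zero_ball_speed_rejected(self):
        eye, ball, win = self._setup(np.ones(30), np.zeros(30))
        with pytest.raises(ValueError, match="ball speed"):
            pursuit_gain(eye, ball, [], win)


class TestClassifyPrediction:
    GEOM = TaskGeometry(location_yaw_left=-10.75, location_yaw_right=10.75)

    def _trace(self, yaw_value, valid=True):
        n = 100
        t = np.arange(n) / FS
        return AngularTrace(t=t, yaw=np.full(n, float(yaw_value)),
                            pitch=np.zeros(n),
                            valid=np.full(n, valid))

    def _yaw_for(self, u_norm):
        return np.degrees(np.arctan(u_norm / 0.8 * np.tan(np.radians(10.75))))

    def test_central_gaze_is_nonpredictive(self):
        pred, correct, u = classify_prediction(self._trace(0.0), 0.5, self.GEOM, "right")
        assert pred is None and correct == "not-applicable" and u == pytest.approx(0.0)

    def test_gaze_on_location_is_correct_prediction(self):
        pred, correct, u = classify_prediction(
            self._trace(10.75), 0.5, self.GEOM, "right")
        assert pred == "right" and correct == "true"
        assert u == pytest.approx(0.8, abs=1e-9)

    def test_just_outside_band_wrong_side(self):
        yaw = self._yaw_for(-0.41)
        pred, correct, u = classify_prediction(self._trace(yaw), 0.5, self.GEOM, "right")
        assert pred == "left" and correct == "false"
        assert u == pytest.approx(-0.41, abs=1e-9)

    def test_no_valid_samples_is_missing(self):
        pred, correct, u = classify_prediction(
            self._trace(5.0, valid=False), 0.5, self.GEOM, "right")
        assert pred is None and correct == "not-applicable" and np.isnan(u)

    def test_partition_is_exhaustive_and_exclusive(self):
        # every normalized position maps to exactly one of {left, none, right}
        for u_norm in np.linspace(-1.2, 1.2, 241):
            pred, _, u = classify_prediction(
                self._trace(self._yaw_for(u_norm)), 0.5, self.GEOM, "left")
            assert u == pytest.approx(u_norm, abs=1e-9)
            if abs(u_norm) <= 0.4 + 1e-12:
                assert pred is None
            else:
                assert pred == ("left" if u_norm < 0 else "right")

    def test_band_width_matches_quoted_visual_angle(self):
        # the central half of the inter-location space subtends ~10.9 deg
        # (10.85 deg by exact trigonometry for a 21.5 deg span at 4 m)
        edge_yaw = self._yaw_for(0.4)
        assert 2 * edge_yaw == pytest.approx(10.85, abs=0.05)


class TestTrialMetrics:
    def test_pivot_trial_metrics(self, clean_config, geometry):
        rec = make_trial(clean_config, gain=0.0, lag=0.0, strategy="pivot",
                         commit=0.0, drift_sd=0.0)
        row = gf.compute_trial_metrics(rec, geometry)
        assert row["n_saccades"] == 0
        assert row["gain"] == pytest.approx(0.0, abs=0.01)
        assert row["prediction"] is None

    def test_clean_predictive_trial_metrics(self, clean_config, geometry):
        rec = make_trial(clean_config, gain=1.0, lag=0.0, side="left", p_left=1.0)
        row = gf.compute_trial_metrics(rec, geometry)
        assert row["coherence"] == pytest.approx(1.0, abs=1e-6)
        assert row["gain"] == pytest.approx(1.0, abs=1e-6)
        assert row["lag"] == 0.0
        assert row["prediction"] == "left" and row["prediction_correct"] == "true"

    def test_one_row_per_trial(self, small_dataset, small_metrics):
        _, recs = small_dataset
        assert len(small_metrics) == len(recs)
        assert small_metrics["participant_id"].nunique() == 8

    def test_missing_propagates_as_missing(self, clean_config, geometry):
        rec = make_trial(clean_config, gain=0.9, lag=0.05)
        rec.valid[:] = False
        rec.valid[-3:] = True  # classification window empty, kinematics starved
        with pytest.warns(UserWarning):
            row = gf.compute_trial_metrics(rec, geometry)
        assert row["prediction"] is None
        assert row["prediction_correct"] == "not-applicable"
        assert np.isnan(row["prediction_position"])


class TestParameterRecovery:
    """Ground-truth recovery on generated trials (the module's core promise)."""

    @pytest.mark.parametrize("gain_true", [0.25, 0.5, 0.8, 1.0])
    def test_noise_free_gain_recovery(self, clean_config, geometry, gain_true):
        rec = make_trial(clean_config, gain=gain_true, lag=0.0, side="left",
                         p_left=1.0)
        row = gf.compute_trial_metrics(rec, geometry)
        assert row["gain"] == pytest.approx(gain_true, abs=0.02)

    @pytest.mark.parametrize("lag_ms", [25, 50, 100])
    def test_lag_recovery_within_one_frame(self, clean_config, geometry, lag_ms):
        rec = make_trial(clean_config, gain=1.0, lag=lag_ms / 1000, side="right",
                         p_left=0.0)
        row = gf.compute_trial_metrics(rec, geometry)
        assert abs(row["lag"] - lag_ms / 1000) <= 1 / FS + 1e-9

    def test_saccade_count_equality_noise_free(self, clean_config, geometry):
        mismatches = 0
        total = 0
        rng = np.random.default_rng(17)
        for i in range(24):
            rec = make_trial(clean_config, gain=0.85, lag=0.1, catchup=6.0,
                             commit=0.7, drift_sd=2.0, seed=100 + i, trial_id=i,
                             side="right" if i % 2 else "left",
                             p_left=0.7 if i % 3 else 0.3)
            row = gf.compute_trial_metrics(rec, geometry)
            total += rec.truth["n_saccades_injected"]
            mismatches += row["n_saccades"] != rec.truth["n_saccades_injected"]
        assert total > 5  # the scenario actually produces saccades
        assert mismatches == 0

    def test_saccade_count_with_tracker_noise(self, geometry):
        cfg = gf.SimConfig(gaze_noise_sd=1.0, missing_rate=0.0,
                           onset_delay_range=(1.0, 1.0))
        errors = []
        for i in range(40):
            rec = make_trial(cfg, gain=0.85, lag=0.1, catchup=6.0, commit=0.7,
                             drift_sd=2.0, seed=200 + i, trial_id=i,
                             side="right" if i % 2 else "left", p_left=0.6)
            row = gf.compute_trial_metrics(rec, geometry)
            errors.append(abs(row["n_saccades"] - rec.truth["n_saccades_injected"]))
        assert np.mean(errors) < 0.2
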