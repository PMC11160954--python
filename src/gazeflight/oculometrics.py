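"""Per-trial tracking metrics: saccades, coherence/lag, pursuit gain,
pre-onset prediction.

All in-flight metrics operate on head-centric angular traces produced by
:mod:`gazeflight.preprocess`.  Saccade detection runs on the 50 Hz filter
channel; the positional metrics (cross-correlation, pursuit gain, pre-onset
gaze position) run on the 15 Hz channel, matching the two-channel filtering
convention for pursuit pipelines.

Saccade detection follows an adaptive acceleration rule: candidate intervals
are portions of the flight where |gaze acceleration| exceeds five times its
median absolute value over the analysis window, retained only when gaze speed
exceeds 40 deg/s for at least five consecutive frames while also exceeding
1.2x the ball's angular speed (which suppresses pursuit of the ball's own
fast final sweep), and discarded when preceded by missing data.  Event
boundaries are placed at the quiet points of the acceleration profile
bracketing the burst.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import (
    AngularTrace,
    KinematicTrace,
    FlightWindow,
    denoise_trace,
    differentiate,
    flight_window,
    gaze_to_angles,
    ball_to_angles,
)


@dataclass
class SaccadeEvent:
    onset_t: float
    offset_t: float
    peak_velocity: float   # deg/s
    amplitude: float       # deg

    def __post_init__(self) -> None:
        if not self.onset_t < self.offset_t:
            raise ValueError("saccade onset must precede offset")
        if self.amplitude < 0:
            raise ValueError("saccade amplitude must be nonnegative")


@dataclass(frozen=True)
class TaskGeometry:
    """Yaws of the two release locations and the nonpredictive central band.

    The normalized horizontal coordinate is linear in wall position, with the
    release locations at -0.8 and +0.8; gaze inside [-0.4, 0.4] (the central
    half of the inter-location space, ~10.9 deg of visual angle for a
    21.5 deg span) counts as nonpredictive.
    """

    location_yaw_left: float
    location_yaw_right: float
    band_half_width: float = 0.4

    def __post_init__(self) -> None:
        if not (self.location_yaw_left < 0 < self.location_yaw_right):
            raise ValueError("expected location yaws bracketing 0 (left < 0 < right)")

    def normalize_yaw(self, yaw_deg: float) -> float:
        """Map a yaw angle to the normalized wall coordinate (+-0.8 at the
        locations); linear in lateral wall position, i.e. in tan(yaw)."""
        return 0.8 * np.tan(np.radians(yaw_deg)) / np.tan(np.radians(self.location_yaw_right))


def detect_saccades(
    eye_kin: KinematicTrace,
    ball_kin: KinematicTrace,
    valid: np.ndarray,
    window: FlightWindow,
    eye_trace: AngularTrace | None = None,
    accel_multiplier: float = 5.0,
    velocity_threshold: float = 40.0,
    min_fast_frames: int = 5,
    ball_ratio: float = 1.2,
    merge_gap: float = 0.020,
    boundary_mode: str = "absolute",
    missing_lookback: int = 3,
) -> list[SaccadeEvent]:
    """Detect saccadic gaze shifts inside the analysis window.

    Parameters
    ----------
    eye_kin, ball_kin : KinematicTrace
        Combined-plane gaze and ball kinematics on the 50 Hz channel.
    valid : bool array
        Gaze validity per sample (full trial length).
    eye_trace : AngularTrace, optional
        Angular positions used to compute event amplitudes; when omitted the
        amplitude is the integral of speed over the event.
    boundary_mode : {"absolute", "signed"}
        "absolute" expands each burst to the nearest local minima of
        |acceleration| on either side (default); "signed" uses the preceding
        local maximum / following local minimum of the signed acceleration.
    """
    i0, i1 = window.release_index, window.end_index
    if i1 - i0 + 1 < min_fast_frames:
        raise ValueError(
            f"analysis window has {i1 - i0 + 1} frames; need >= {min_fast_frames}"
        )
    t = eye_kin.t
    sl = slice(i0, i1 + 1)
    win_valid = np.asarray(valid, bool)[sl] & eye_kin.valid[sl]
    if not win_valid.any():
        warnings.warn("saccade detection window contains no valid samples")
        return []
    acc = eye_kin.acceleration[sl]
    speed = np.abs(eye_kin.velocity[sl])
    ball_speed = np.abs(ball_kin.velocity[sl])
    med = np.median(np.abs(acc[win_valid]))
    threshold = accel_multiplier * med
    hot = (np.abs(acc) > threshold) & win_valid
    if not hot.any():
        return []

    # contiguous candidate runs; runs separated by < merge_gap merge (a single
    # minimum-jerk saccade shows two acceleration lobes around a quiet middle)
    idx = np.flatnonzero(hot)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = [(r[0], r[-1]) for r in np.split(idx, breaks + 1)]
    dt = float(np.median(np.diff(t)))
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and (a - merged[-1][1]) * dt < merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    events: list[SaccadeEvent] = []
    n_win = i1 - i0 + 1
    full_valid = np.asarray(valid, bool)
    for a, b in merged:
        # missing-data rule: a candidate just preceded by invalid frames is
        # unreliable (interpolation across the gap can fake a velocity burst)
        prev = slice(max(0, i0 + a - missing_lookback), i0 + a)
        if not full_valid[prev].all():
            continue
        # velocity rule: >= min_fast_frames consecutive frames above the fixed
        # threshold and 20% faster than the ball, searched around the burst
        lo = max(0, a - min_fast_frames)
        hi = min(n_win - 1, b + min_fast_frames)
        fast = ((speed[lo:hi + 1] > velocity_threshold)
                & (speed[lo:hi + 1] > ball_ratio * ball_speed[lo:hi + 1])
                & win_valid[lo:hi + 1])
        if not _has_run(fast, min_fast_frames):
            continue
        onset_i, offset_i = _event_bounds(acc, a, b, boundary_mode)
        events.append(_make_event(t, sl, speed, eye_trace, onset_i, offset_i))

    # final merge on boundary times
    out: list[SaccadeEvent] = []
    for ev in events:
        if out and ev.onset_t - out[-1].offset_t < merge_gap:
            prev_ev = out.pop()
            out.append(SaccadeEvent(
                onset_t=prev_ev.onset_t, offset_t=ev.offset_t,
                peak_velocity=max(prev_ev.peak_velocity, ev.peak_velocity),
                amplitude=prev_ev.amplitude + ev.amplitude,
            ))
        else:
            out.append(ev)
    return out


def _has_run(mask: np.ndarray, length: int) -> bool:
    count = 0
    for m in mask:
        count = count + 1 if m else 0
        if count >= length:
            return True
    return False


def _event_bounds(acc: np.ndarray, a: int, b: int, mode: str) -> tuple[int, int]:
    n = len(acc)
    if mode == "absolute":
        mag = np.abs(acc)
        i = a
        while i > 0 and mag[i - 1] <= mag[i]:
            i -= 1
        j = b
        while j < n - 1 and mag[j + 1] <= mag[j]:
            j += 1
        return i, j
    if mode == "signed":
        # orient the profile along the movement direction: the acceleration in
        # the first lobe is positive by construction of the speed derivative
        i = a
        while 0 < i and acc[i - 1] >= acc[i]:
            i -= 1
        while i > 0 and acc[i - 1] <= acc[i]:
            i -= 1
        i = min(i + 1, a)
        j = b
        while j < n - 1 and acc[j + 1] <= acc[j]:
            j += 1
        while j < n - 1 and acc[j + 1] >= acc[j]:
            j += 1
        j = max(j - 1, b)
        return i, j
    raise ValueError(f"unknown boundary_mode {mode!r}")


def _make_event(t, sl, speed, eye_trace, onset_i, offset_i) -> SaccadeEvent:
    onset_t = float(t[sl][onset_i])
    offset_t = float(t[sl][offset_i])
    peak = float(speed[onset_i:offset_i + 1].max())
    if eye_trace is not None:
        y = eye_trace.yaw[sl]
        p = eye_trace.pitch[sl]
        amplitude = float(np.hypot(y[offset_i] - y[onset_i], p[offset_i] - p[onset_i]))
    else:
        dt = float(np.median(np.diff(t)))
        amplitude = float(np.trapezoid(speed[onset_i:offset_i + 1], dx=dt))
    return SaccadeEvent(onset_t=onset_t, offset_t=offset_t,
                        peak_velocity=peak, amplitude=amplitude)


def coherence_and_lag(
    eye_vel: np.ndarray,
    ball_vel: np.ndarray,
    sample_rate: float,
    valid: np.ndarray | None = None,
    max_lag: float = 0.250,
    min_overlap: int = 10,
) -> tuple[float, float]:
    """Peak lagged Pearson correlation between eye and ball yaw velocities.

    Returns (coherence, lag_seconds).  Positive lag means the eye trails the
    ball: the peak occurs when the eye series is shifted *back* in time to
    meet the ball.  Ties break toward the smaller |lag|.  Degenerate
    (zero-variance) overlaps return (nan, nan).
    """
    eye_vel = np.asarray(eye_vel, float)
    ball_vel = np.asarray(ball_vel, float)
    n = len(eye_vel)
    if valid is None:
        valid = np.ones(n, bool)
    valid = np.asarray(valid, bool)
    max_k = int(round(max_lag * sample_rate))
    best: tuple[float, int] | None = None
    for k in range(-max_k, max_k + 1):
        # lag k > 0: eye[i] aligns with ball[i - k]
        if k >= 0:
            e, b, v = eye_vel[k:], ball_vel[:n - k], valid[k:] & valid[:n - k]
        else:
            e, b, v = eye_vel[:n + k], ball_vel[-k:], valid[:n + k] & valid[-k:]
        if v.sum() < min_overlap:
            continue
        e, b = e[v], b[v]
        if e.std() == 0 or b.std() == 0:
            continue
        r = float(np.corrcoef(e, b)[0, 1])
        if best is None or r > best[0] + 1e-12 or (
            abs(r - best[0]) <= 1e-12 and abs(k) < abs(best[1])
        ):
            best = (r, k)
    if best is None:
        return float("nan"), float("nan")
    return best[0], best[1] / sample_rate


def pursuit_gain(
    eye_kin: KinematicTrace,
    ball_kin: KinematicTrace,
    saccades: list[SaccadeEvent],
    window: FlightWindow,
    min_samples: int = 5,
) -> float:
    """Closed-loop pursuit gain: saccade-free mean gaze yaw speed divided by
    mean ball yaw speed over [closed-loop start, flight end).

    Gain uses the ratio of means (not mean of ratios) so that ball-velocity
    zero crossings cannot blow the estimate up, and the numerator is the eye
    velocity projected onto the ball's direction of motion rather than its
    absolute value: on clean traces the two are identical (the eye moves with
    the ball), but the signed projection stays unbiased under zero-mean
    tracker noise, where rectified speeds would inflate low gains.  Values
    near 1 indicate close continuous tracking; NaN when fewer than
    ``min_samples`` saccade-free valid samples remain.
    """
    t = eye_kin.t
    sl = slice(window.closed_loop_start_index, window.end_index)
    keep = eye_kin.valid[sl] & ball_kin.valid[sl]
    tt = t[sl]
    for ev in saccades:
        keep &= ~((tt >= ev.onset_t) & (tt <= ev.offset_t))
    if keep.sum() < min_samples:
        return float("nan")
    ball_v = ball_kin.velocity[sl][keep]
    if np.abs(ball_v).mean() == 0:
        raise ValueError("mean ball speed is zero over the closed-loop window")
    eye_along_ball = eye_kin.velocity[sl][keep] * np.sign(ball_v)
    return float(eye_along_ball.mean() / np.abs(ball_v).mean())


def classify_prediction(
    eye_trace: AngularTrace,
    tone_end_time: float,
    geometry: TaskGeometry,
    release_side: str | None = None,
    window_s: float = 0.050,
) -> tuple[str | None, str, float]:
    """Classify pre-onset gaze as a left/right prediction or nonpredictive.

    Gaze yaw is averaged over the ``window_s`` window ending at tone
    termination (the last moment before the ball can appear), mapped to the
    normalized wall coordinate, and compared against the central band.

    Returns (prediction, prediction_correct, normalized_position) where
    prediction is "left", "right" or None and prediction_correct is "true",
    "false" or "not-applicable".  With no valid samples in the window all
    three are missing (None, "not-applicable", nan).
    """
    sel = (eye_trace.t >= tone_end_time - window_s) & (eye_trace.t <= tone_end_time)
    sel &= eye_trace.valid
    if not sel.any():
        return None, "not-applicable", float("nan")
    u = geometry.normalize_yaw(float(eye_trace.yaw[sel].mean()))
    if abs(u) <= geometry.band_half_width:
        return None, "not-applicable", u
    prediction = "left" if u < 0 else "right"
    if release_side is None:
        return prediction, "not-applicable", u
    return prediction, ("true" if prediction == release_side else "false"), u


def compute_trial_metrics(
    recording,
    geometry: TaskGeometry,
    sample_rate: float | None = None,
    max_lag: float = 0.250,
    xcorr_signal: str = "velocity",
    boundary_mode: str = "absolute",
    filter_edge_frames: int = 6,
) -> dict:
    """Run the full per-trial metric battery on one recording.

    Returns one row (dict) with coherence, lag, gain, saccade count, the
    pre-onset prediction class and trial metadata; metrics that cannot be
    computed propagate as NaN/None, never as zero.

    The recording ends at the interception event, so the zero-phase filters'
    boundary transients overlap the final frames of the flight; the last
    ``filter_edge_frames`` samples are therefore excluded from all
    velocity-based metrics.
    """
    rec = recording
    fs = sample_rate or 1.0 / float(np.median(np.diff(rec.t)))
    eye_raw = gaze_to_angles(rec.gaze_dir, rec.t, rec.valid)
    win = flight_window(rec.t, rec.ball_release_time, rec.ball_end_time)
    ball_ok = ~np.isnan(rec.ball_pos[:, 0])
    ok_idx = np.flatnonzero(ball_ok)
    if ok_idx.size == 0:
        raise ValueError(
            f"trial {rec.meta.trial_id} of participant {rec.meta.participant_id} "
            "has no ball samples")
    # hold the first/last in-play ball position across out-of-play samples so
    # the zero-phase filters see a defined, flat series outside the flight
    ball_filled = rec.ball_pos.copy()
    ball_filled[:ok_idx[0]] = rec.ball_pos[ok_idx[0]]
    ball_filled[ok_idx[-1] + 1:] = rec.ball_pos[ok_idx[-1]]
    inner_nan = ~ball_ok & (np.arange(len(ball_ok)) > ok_idx[0]) & (
        np.arange(len(ball_ok)) < ok_idx[-1])
    if inner_nan.any():
        for c in range(3):
            ball_filled[inner_nan, c] = np.interp(
                np.flatnonzero(inner_nan), ok_idx, rec.ball_pos[ok_idx, c])
    ball_raw = ball_to_angles(ball_filled, rec.eye_origin, rec.t, ball_ok)

    eye_sacc = denoise_trace(eye_raw, "saccade", fs)
    eye_pos = denoise_trace(eye_raw, "positional", fs)
    ball_sacc = denoise_trace(ball_raw, "saccade", fs)
    ball_pos_tr = denoise_trace(ball_raw, "positional", fs)

    eye_kin_c = differentiate(eye_sacc, "combined")
    ball_kin_c = differentiate(ball_sacc, "combined")
    eye_kin_y = differentiate(eye_pos, "yaw")
    ball_kin_y = differentiate(ball_pos_tr, "yaw")
    if filter_edge_frames > 0:
        for kin in (eye_kin_c, ball_kin_c, eye_kin_y, ball_kin_y):
            kin.valid[-filter_edge_frames:] = False

    saccades = detect_saccades(eye_kin_c, ball_kin_c, rec.valid, win,
                               eye_trace=eye_sacc, boundary_mode=boundary_mode)

    fsl = slice(win.release_index, win.end_index + 1)
    joint = eye_kin_y.valid[fsl] & ball_kin_y.valid[fsl]
    if xcorr_signal == "velocity":
        coh, lag = coherence_and_lag(eye_kin_y.velocity[fsl], ball_kin_y.velocity[fsl],
                                     fs, joint, max_lag)
    else:
        coh, lag = coherence_and_lag(eye_pos.yaw[fsl], ball_pos_tr.yaw[fsl],
                                     fs, joint, max_lag)
    try:
        gain = pursuit_gain(eye_kin_y, ball_kin_y, saccades, win)
    except ValueError:
        gain = float("nan")
    prediction, pred_correct, u_norm = classify_prediction(
        eye_pos, rec.tone_end_time, geometry, rec.meta.release_side)

    return {
        "participant_id": rec.meta.participant_id,
        "block_id": rec.meta.block_id,
        "trial_id": rec.meta.trial_id,
        "release_side": rec.meta.release_side,
        "success": bool(rec.interception_success),
        "coherence": coh,
        "lag": lag,
        "gain": gain,
        "n_saccades": len(saccades),
        "prediction": prediction,
        "prediction_correct": pred_correct,
        "prediction_position": u_norm,
        "expectedness": rec.meta.expectedness,
        "_saccades": saccades,
    }


def metrics_table(recordings, geometry: TaskGeometry, **kwargs) -> pd.DataFrame:
    """Per-trial metrics for a whole dataset (one row per trial)."""
    rows = [compute_trial_metrics(rec, geometry, **kwargs) for rec in recordings]
    df = pd.DataFrame(rows)
    return df.drop(columns=["_saccades"])


def saccade_table(recordings, geometry: TaskGeometry, **kwargs) -> pd.DataFrame:
    """Flat table of every detected saccade across a dataset."""
    rows = []
    for rec in recordings:
        row = compute_trial_metrics(rec, geometry, **kwargs)
        for ev in row["_saccades"]:
            rows.append({
                "participant_id": rec.meta.participant_id,
                "block_id": rec.meta.block_id,
                "trial_id": rec.meta.trial_id,
                "onset_t": ev.onset_t, "offset_t": ev.offset_t,
                "amplitude": ev.amplitude, "peak_velocity": ev.peak_velocity,
            })
    return pd.DataFrame(rows, columns=["participant_id", "block_id", "trial_id",
                                       "onset_t", "offset_t", "amplitude",
                                       "peak_velocity"])
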