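"""Signal conditioning for gaze and ball time series.

Raw recordings carry a cyclopean gaze direction (unit 3-vector) and a ball
position (metres), both in a world frame with ``x`` rightward, ``y`` up and
``z`` pointing from the observer toward the front wall.  Analysis happens in
head-centric angles: yaw is rotation about the gravity-aligned vertical axis
(0 deg = straight ahead at the front wall, positive = rightward) and pitch is
elevation relative to the horizontal eye-height plane (+90 deg = straight up,
-90 deg = straight down).

Two filter channels are maintained throughout, following standard practice
for pursuit/saccade pipelines: a 3-sample moving median followed by a
zero-phase second-order Butterworth low-pass at 50 Hz for saccade detection,
and the same cascade with a 15 Hz cut-off for positional tracking measures.
Zero-phase (forward-backward) filtering is used so that the filter itself
contributes no tracking lag to the lag estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

#: Butterworth cut-off (Hz) per filter channel.
CHANNEL_CUTOFFS = {"saccade": 50.0, "positional": 15.0}


@dataclass
class AngularTrace:
    """Yaw/pitch time series (degrees) for one source (eye or ball)."""

    t: np.ndarray
    yaw: np.ndarray
    pitch: np.ndarray
    valid: np.ndarray
    source: str = "eye"
    filter_channel: str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.yaw = np.asarray(self.yaw, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.yaw) == len(self.pitch) == len(self.valid)):
            raise ValueError("AngularTrace fields must share one length")


@dataclass
class KinematicTrace:
    """Angular velocity and acceleration (deg/s, deg/s^2) of a trace."""

    t: np.ndarray
    velocity: np.ndarray      # signed, in the requested plane ("combined": speed)
    acceleration: np.ndarray
    valid: np.ndarray
    plane: str = "yaw"


@dataclass(frozen=True)
class FlightWindow:
    """Sample indices delimiting ball flight within a trial.

    ``closed_loop_start_index`` marks the onset of visually driven (closed
    loop) pursuit, 140 ms after ball release; the open-loop interval before it
    is excluded from pursuit-gain estimation.
    """

    release_index: int
    end_index: int
    closed_loop_start_index: int

    def __post_init__(self) -> None:
        if not (self.release_index < self.closed_loop_start_index <= self.end_index):
            raise ValueError(
                "require release_index < closed_loop_start_index <= end_index, got "
                f"{self.release_index}, {self.closed_loop_start_index}, {self.end_index}"
            )


def moving_median3(x: np.ndarray) -> np.ndarray:
    """3-sample moving median; the window shrinks at the series edges."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return x.copy()
    out = np.empty_like(x)
    out[1:-1] = np.median(np.column_stack([x[:-2], x[1:-1], x[2:]]), axis=1)
    out[0] = 0.5 * (x[0] + x[1])
    out[-1] = 0.5 * (x[-2] + x[-1])
    return out


def interpolate_gaps(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly interpolate invalid samples (edge gaps: hold nearest valid)."""
    x = np.asarray(x, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if valid.all():
        return x.copy()
    if not valid.any():
        raise ValueError("cannot interpolate a series with no valid samples")
    idx = np.arange(x.size)
    out = x.copy()
    out[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    return out


def denoise(
    x: np.ndarray,
    channel: str,
    sample_rate: float,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Median-then-Butterworth denoising of one scalar series.

    Invalid samples are linearly interpolated before filtering so the filter
    state stays well defined across gaps; callers keep the validity mask and
    re-flag those samples downstream.

    Parameters
    ----------
    channel : {"saccade", "positional"}
        Selects the 50 Hz or 15 Hz Butterworth cut-off.
    """
    if channel not in CHANNEL_CUTOFFS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {sorted(CHANNEL_CUTOFFS)}")
    cutoff = CHANNEL_CUTOFFS[channel]
    nyquist = sample_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(
            f"cut-off {cutoff} Hz is not below the Nyquist frequency {nyquist} Hz "
            f"(sample rate {sample_rate} Hz)"
        )
    x = np.asarray(x, dtype=float)
    if valid is not None:
        x = interpolate_gaps(x, valid)
    x = moving_median3(x)
    if x.size < 10:  # filtfilt needs padding room; tiny series pass through the median only
        return x
    b, a = signal.butter(2, cutoff, btype="low", fs=sample_rate)
    return signal.filtfilt(b, a, x)


def vector_to_angles(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert world-frame direction vector(s) to (yaw, pitch) in degrees.

    Accepts one vector of shape (3,) or a stack of shape (n, 3).
    """
    d = np.asarray(direction, dtype=float)
    single = d.ndim == 1
    d = np.atleast_2d(d)
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length direction vector has no yaw/pitch")
    x, y, z = d[:, 0], d[:, 1], d[:, 2]
    yaw = np.degrees(np.arctan2(x, z))
    pitch = np.degrees(np.arctan2(y, np.hypot(x, z)))
    if single:
        return float(yaw[0]), float(pitch[0])
    return yaw, pitch


def angles_to_vector(yaw: np.ndarray, pitch: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vector_to_angles`; returns unit vectors (n, 3)."""
    yaw_r = np.radians(np.asarray(yaw, dtype=float))
    pitch_r = np.radians(np.asarray(pitch, dtype=float))
    x = np.cos(pitch_r) * np.sin(yaw_r)
    y = np.sin(pitch_r)
    z = np.cos(pitch_r) * np.cos(yaw_r)
    return np.stack(np.broadcast_arrays(x, y, z), axis=-1)


def ball_to_angles(
    ball_pos: np.ndarray,
    eye_origin: np.ndarray,
    t: np.ndarray,
    valid: np.ndarray | None = None,
) -> AngularTrace:
    """Ball position series (n, 3) to a head-centric angular trace.

    The ball direction is taken from the eye-tracker origin, matching the
    frame in which gaze is expressed.
    """
    ball_pos = np.asarray(ball_pos, dtype=float)
    rel = ball_pos - np.asarray(eye_origin, dtype=float)
    if np.any(np.linalg.norm(rel, axis=1) < 1e-9):
        raise ValueError("ball position coincides with the eye origin")
    yaw, pitch = vector_to_angles(rel)
    if valid is None:
        valid = np.ones(len(yaw), dtype=bool)
    return AngularTrace(t=t, yaw=yaw, pitch=pitch, valid=valid, source="ball")


def gaze_to_angles(gaze_dir: np.ndarray, t: np.ndarray, valid: np.ndarray) -> AngularTrace:
    """Cyclopean gaze direction series (n, 3) to an angular trace."""
    yaw, pitch = vector_to_angles(np.asarray(gaze_dir, dtype=float))
    return AngularTrace(t=t, yaw=yaw, pitch=pitch, valid=valid, source="eye")


def denoise_trace(trace: AngularTrace, channel: str, sample_rate: float) -> AngularTrace:
    """Apply :func:`denoise` to both angle components of a trace."""
    return AngularTrace(
        t=trace.t,
        yaw=denoise(trace.yaw, channel, sample_rate, trace.valid),
        pitch=denoise(trace.pitch, channel, sample_rate, trace.valid),
        valid=trace.valid.copy(),
        source=trace.source,
        filter_channel=channel,
    )


def differentiate(trace: AngularTrace, plane: str = "yaw") -> KinematicTrace:
    """Differentiate an angular trace into velocity and acceleration.

    Central differences in the interior, one-sided at the ends (numpy
    gradient).  ``plane="combined"`` returns the angular speed on the unit
    sphere, sqrt((yaw_rate*cos(pitch))^2 + pitch_rate^2): yaw circles shrink
    by cos(pitch) away from the horizon while meridians are great circles, so
    the convergence correction applies to the yaw term.  Invalidity spreads
    one frame to each side because a difference touching a bad sample is bad.
    """
    n_valid = int(trace.valid.sum())
    if n_valid < 3:
        raise ValueError(f"need >=3 valid samples to differentiate, got {n_valid}")
    if plane not in ("yaw", "pitch", "combined"):
        raise ValueError(f"unknown plane {plane!r}")
    t = trace.t
    yaw_v = np.gradient(trace.yaw, t)
    pitch_v = np.gradient(trace.pitch, t)
    if plane == "yaw":
        vel = yaw_v
    elif plane == "pitch":
        vel = pitch_v
    else:
        vel = np.hypot(yaw_v * np.cos(np.radians(trace.pitch)), pitch_v)
    acc = np.gradient(vel, t)
    bad = ~trace.valid
    spread = bad | np.roll(bad, 1) | np.roll(bad, -1)
    if bad.any():
        # roll wraps the ends; a bad first/last sample must not invalidate the other end
        spread[0] = bad[0] or bad[1]
        spread[-1] = bad[-1] or bad[-2]
    return KinematicTrace(t=t, velocity=vel, acceleration=acc, valid=~spread, plane=plane)


def flight_window(
    t: np.ndarray,
    release_time: float,
    end_time: float,
    closed_loop_delay: float = 0.140,
) -> FlightWindow:
    """Locate the flight interval [release, line crossing] in sample indices."""
    t = np.asarray(t, dtype=float)
    release_index = int(np.searchsorted(t, release_time, side="left"))
    end_index = int(np.searchsorted(t, end_time, side="right") - 1)
    closed_loop = int(np.searchsorted(t, release_time + closed_loop_delay, side="left"))
    return FlightWindow(release_index, end_index, min(closed_loop, end_index))
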