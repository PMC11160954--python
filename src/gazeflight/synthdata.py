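"""Synthetic VR interception trials with known ground-truth gaze parameters.

The simulated task mirrors a virtual racquetball paradigm: balls launch from
one of two wall locations spanning 21.5 deg of visual angle as seen from the
interception line 4 m away, travel in a straight line at 10 m/s (0.4 s of
flight), and arrive at chest height.  Each participant completes 6 blocks of
20 trials whose left/right mixes are 50/50, 50/50, 90/10, 70/30, 30/70 and
10/90, with a uniform 0-5 s onset delay after the warning tones.

Gaze is generated under one of two strategies observed in this kind of task:

* ``predictive`` — before ball onset, gaze sits on the anticipated release
  location (the normalized +-0.8 position); in flight the eye follows the
  ball's yaw, delayed by ``lag`` and scaled by ``pursuit_gain`` about the
  pre-onset position, with minimum-jerk catch-up saccades injected whenever
  the angular error exceeds ``catchup_threshold``.
* ``pivot`` — gaze anchors near the midpoint between the two locations
  (a "visual pivot") with per-trial drift, tracks weakly and makes no
  catch-up saccades, standing in for peripheral-vision monitoring.

Every stochastic element flows from one seeded generator, with fixed
per-participant substreams, so datasets are exactly reproducible and all
ground-truth parameters (gain, lag, injected saccade count, predicted side)
are recorded for parameter-recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import vector_to_angles, angles_to_vector

EYE_HEIGHT_DEFAULT = 1.6  # m, standing eye height of the simulated observer


@dataclass
class GazeStrategyParams:
    """Ground-truth tracking parameters for one pre-onset strategy."""

    pursuit_gain: float = 0.9        # unitless velocity gain of in-flight pursuit
    lag: float = 0.10                # s, delay of eye behind ball
    catchup_threshold: float | None = 6.0  # deg; None disables catch-up saccades
    pivot_drift_sd: float = 2.0      # deg, per-trial jitter of the anchored position
    predict_rate_range: tuple[float, float] = (0.75, 0.98)
    # fraction of trials on which a participant of this strategy commits to a
    # side before onset (drawn once per participant); the complement is spent
    # at the central pivot position

    gain_sd: float = 0.05            # between-participant SD of pursuit gain
    lag_sd: float = 0.015            # between-participant SD of lag (s)


@dataclass
class SimConfig:
    """Geometry, schedule and gaze-model parameters of the simulated task."""

    n_participants: int = 41
    blocks: tuple[tuple[int, float], ...] = (
        (20, 0.5), (20, 0.5), (20, 0.9), (20, 0.7), (20, 0.3), (20, 0.1),
    )
    ball_speed: float = 10.0         # m/s, average over the flight
    release_distance: float = 4.0    # m, front wall to interception line
    location_span: float = 21.5      # deg of visual angle between release locations
    arrival_height: float = 1.36     # m, ball height crossing the line (chest)
    arrival_offset: float = 0.30     # m, lateral arrival offset (same side as release)
    interception_plane: float = 0.5  # m in front of the line where the racquet
                                     # meets the ball; tracking and the flight
                                     # window end at this crossing
    onset_delay_range: tuple[float, float] = (0.0, 5.0)  # s, uniform
    tone_lead: float = 0.5           # s of recording before the tones end
    sample_rate: float = 120.0       # Hz
    gaze_noise_sd: float = 0.5       # deg, band-limited angular tracker noise
    noise_bandwidth: float = 10.0    # Hz, bandwidth of the tracker-noise model
    missing_rate: float = 0.01       # fraction of samples lost, in runs of 1-3
    strategy_mix: float = 22 / 41    # fraction of participants assigned "predictive"
    predictive: GazeStrategyParams = field(default_factory=GazeStrategyParams)
    pivot: GazeStrategyParams = field(
        default_factory=lambda: GazeStrategyParams(
            pursuit_gain=0.15, lag=0.15, catchup_threshold=None,
            predict_rate_range=(0.02, 0.25), gain_sd=0.05, lag_sd=0.02,
        )
    )
    saccade_duration_range: tuple[float, float] = (0.055, 0.060)  # s, minimum jerk
    saccade_refractory: float = 0.05  # s after a saccade before the next can launch
    saccade_blackout: float = 0.10    # s before interception with no new saccades
    saccade_lead: float = 0.15        # s; saccades land on the ball's position
                                      # extrapolated this far ahead (predictive targeting)
    saccade_ball_speed_limit: float = 28.0  # deg/s; no saccades once the ball's
                                      # angular speed exceeds this (late flight is
                                      # monitored with pursuit/periphery only)
    # logistic success model: b0 + skill_i + b_err * mean angular error (deg)
    # + b_exp * expectedness, with skill_i a per-participant intercept
    success_intercept: float = 0.9
    success_error_weight: float = -0.01
    success_expectedness_weight: float = 0.5
    success_skill_sd: float = 1.1    # SD of the participant skill intercept
                                     # (success variance in this task is mostly
                                     # between-participant)
    eye_origin: tuple[float, float, float] = (0.0, EYE_HEIGHT_DEFAULT, 0.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.strategy_mix <= 1.0 and 0.0 <= self.missing_rate <= 1.0):
            raise ValueError("strategy_mix and missing_rate must lie in [0, 1]")
        for nm in ("ball_speed", "release_distance", "location_span", "sample_rate"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be strictly positive")
        if self.sample_rate < 60.0:
            raise ValueError("sample_rate must be at least 60 Hz")
        if not all(0.0 <= p <= 1.0 for _, p in self.blocks):
            raise ValueError("block left-probabilities must lie in [0, 1]")
        lo, hi = self.onset_delay_range
        if lo < 0 or hi < lo:
            raise ValueError("onset_delay_range must be ordered and nonnegative")

    # --- derived geometry -------------------------------------------------
    @property
    def half_span_m(self) -> float:
        """Lateral wall offset of each release location from centre (m)."""
        return self.release_distance * np.tan(np.radians(self.location_span / 2.0))

    @property
    def location_yaws(self) -> tuple[float, float]:
        """(left, right) release-location yaws in degrees from the line."""
        half = self.location_span / 2.0
        return (-half, half)

    @property
    def flight_duration(self) -> float:
        return self.release_distance / self.ball_speed

    @property
    def interception_delay(self) -> float:
        """Time from release to the racquet-plane crossing (s)."""
        if not 0.0 <= self.interception_plane < self.release_distance:
            raise ValueError("interception_plane must lie between the wall and the line")
        frac = (self.release_distance - self.interception_plane) / self.release_distance
        return frac * self.flight_duration


@dataclass
class TrialMeta:
    participant_id: int
    block_id: int
    trial_id: int
    release_side: str              # "left" | "right"
    onset_delay: float             # s between tone end and ball release
    p_left: float                  # block-level probability of a left release

    @property
    def expectedness(self) -> float:
        """Block probability of the realized side (how expected the trial was)."""
        return self.p_left if self.release_side == "left" else 1.0 - self.p_left


@dataclass
class TrialRecording:
    """One trial's synchronized gaze/ball series plus metadata and truth."""

    meta: TrialMeta
    t: np.ndarray                  # s, strictly increasing
    gaze_dir: np.ndarray           # (n, 3) unit vectors, world frame
    ball_pos: np.ndarray           # (n, 3) m; NaN before release / after crossing
    valid: np.ndarray              # gaze validity flags
    eye_origin: np.ndarray         # (3,) m
    tone_end_time: float
    ball_release_time: float
    ball_end_time: float           # line-crossing time
    interception_success: bool
    truth: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.t)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def participant_rng(seed: int, participant_id: int) -> np.random.Generator:
    """Deterministic per-participant substream of the dataset seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(participant_id,)))


def make_schedule(config: SimConfig, seed: int | None = None) -> list[TrialMeta]:
    """Build the full trial schedule for every participant.

    Block composition is exact: a block of ``n`` trials with left-probability
    ``p`` contains round-half-up(n*p) left trials, shuffled within the block.
    Onset delays are uniform draws from ``config.onset_delay_range``.
    """
    seed = config.rng_seed if seed is None else seed
    schedule: list[TrialMeta] = []
    for pid in range(config.n_participants):
        rng = participant_rng(seed, pid)
        trial_counter = 0
        for block_id, (n_trials, p_left) in enumerate(config.blocks):
            n_left = _round_half_up(n_trials * p_left)
            sides = np.array(["left"] * n_left + ["right"] * (n_trials - n_left))
            rng.shuffle(sides)
            delays = rng.uniform(*config.onset_delay_range, size=n_trials)
            for side, delay in zip(sides, delays):
                schedule.append(TrialMeta(pid, block_id, trial_counter, str(side),
                                          float(delay), float(p_left)))
                trial_counter += 1
    return schedule


def simulate_ball(meta: TrialMeta, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Straight-line constant-rate ball path for one trial.

    Returns (t_flight, pos) where ``t_flight`` spans [release, crossing] at the
    configured sample rate and ``pos`` is (n, 3) in metres.  The path runs from
    the release location on the front wall to a reachable point on the
    interception line at arrival height, in ``release_distance / ball_speed``
    seconds.
    """
    sgn = -1.0 if meta.release_side == "left" else 1.0
    start = np.array([sgn * config.half_span_m, config.arrival_height,
                      config.release_distance])
    end = np.array([sgn * config.arrival_offset, config.arrival_height, 0.0])
    duration = config.flight_duration
    release = config.tone_lead + meta.onset_delay
    dt = 1.0 / config.sample_rate
    # sample grid aligned to the trial clock that started at t=0
    n0 = int(np.ceil(release / dt - 1e-9))
    n1 = int(np.floor((release + duration) / dt + 1e-9))
    t_flight = np.arange(n0, n1 + 1) * dt
    frac = np.clip((t_flight - release) / duration, 0.0, 1.0)
    pos = start[None, :] + frac[:, None] * (end - start)[None, :]
    return t_flight, pos


def _min_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _band_limited_noise(n: int, sd: float, bandwidth: float, sample_rate: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Gaussian angular noise low-passed at ``bandwidth`` and rescaled to ``sd``.

    Models the temporally correlated jitter/drift of a head-mounted eye
    tracker; white sample-to-sample noise would imply a physically implausible
    acceleration spectrum.
    """
    if sd <= 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if n < 20:
        return sd * white
    from scipy import signal as sps
    b, a = sps.butter(2, bandwidth, btype="low", fs=sample_rate)
    shaped = sps.filtfilt(b, a, white)
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else np.zeros(n)


def simulate_gaze(
    meta: TrialMeta,
    t_flight: np.ndarray,
    ball_pos: np.ndarray,
    strategy: str,
    params: GazeStrategyParams,
    config: SimConfig,
    rng: np.random.Generator,
    pursuit_gain: float | None = None,
    lag: float | None = None,
) -> dict:
    """Generate the gaze series for one trial.

    Returns a dict with the full-trial time base, gaze yaw/pitch (deg), the
    per-sample validity mask, and ground truth (injected saccades, predicted
    side, pre-onset position).  ``pursuit_gain`` and ``lag`` override the
    strategy means (used for participant-level variation and recovery tests).
    """
    gain = params.pursuit_gain if pursuit_gain is None else pursuit_gain
    lag_s = params.lag if lag is None else lag
    if lag_s >= config.flight_duration:
        raise ValueError(
            f"requested lag {lag_s} s is not shorter than the flight duration "
            f"{config.flight_duration} s; the eye would never start moving"
        )
    dt = 1.0 / config.sample_rate
    release = config.tone_lead + meta.onset_delay
    # the trial record ends at the interception event (hit: the ball
    # disappears at the racquet plane; miss: the trial is over), so the
    # recorded series stop there even though the ball's path continues
    t_int = release + config.interception_delay
    end_time = min(t_flight[-1], t_int)
    t = np.arange(0.0, end_time + 0.5 * dt, dt)
    n = len(t)
    eye = np.asarray(config.eye_origin, dtype=float)

    # ball angles over flight, from the eye origin
    rel = ball_pos - eye[None, :]
    ball_yaw, ball_pitch = vector_to_angles(rel)

    # --- pre-onset placement ---------------------------------------------
    left_yaw, right_yaw = config.location_yaws
    predicts = rng.random() < meta.p_left  # True -> predicts left
    # probability of committing gaze to a side this trial; callers pass a
    # degenerate range when the rate is a per-participant constant
    commit_p = 0.5 * (params.predict_rate_range[0] + params.predict_rate_range[1])
    commit = rng.random() < commit_p
    if commit:
        predicted_side = "left" if predicts else "right"
        pre_yaw = left_yaw if predicts else right_yaw
    else:
        predicted_side = None
        pre_yaw = float(rng.normal(0.0, params.pivot_drift_sd)) if params.pivot_drift_sd > 0 else 0.0
    hole_dist = np.hypot(config.release_distance,
                         config.half_span_m if predicted_side else 0.0)
    pre_pitch = float(np.degrees(np.arctan2(config.arrival_height - eye[1], hole_dist)))

    yaw = np.full(n, pre_yaw)
    pitch = np.full(n, pre_pitch)

    # --- in-flight pursuit ------------------------------------------------
    i0 = int(np.searchsorted(t, t_flight[0] - 1e-9))
    n_fl = n - i0                       # flight samples inside the recording
    fl = slice(i0, n)
    lagged = np.clip(t[fl] - lag_s, t_flight[0], t_flight[-1])
    ball_yaw_lag = np.interp(lagged, t_flight, ball_yaw)
    ball_pitch_lag = np.interp(lagged, t_flight, ball_pitch)
    yaw[fl] = pre_yaw + gain * (ball_yaw_lag - ball_yaw_lag[0])
    pitch[fl] = pre_pitch + gain * (ball_pitch_lag - ball_pitch_lag[0])

    # --- orienting / catch-up saccades -------------------------------------
    # Saccades launch when the gaze-ball error exceeds the threshold, but only
    # while the ball's angular speed is still modest: once the approaching
    # ball sweeps faster than ~30 deg/s, observers stop foveating it with
    # discrete jumps (and no velocity-based detector could separate such jumps
    # from the target's own motion).  Each saccade lands on the ball's
    # position extrapolated ``saccade_lead`` seconds ahead — the predictive
    # targeting characteristic of interceptive gaze.
    injected: list[dict] = []
    if strategy == "predictive" and params.catchup_threshold is not None:
        ball_yaw_v = np.gradient(ball_yaw, t_flight)
        ball_pitch_v = np.gradient(ball_pitch, t_flight)
        ball_speed = np.hypot(
            ball_yaw_v * np.cos(np.radians(ball_pitch)), ball_pitch_v)
        extra_yaw = np.zeros(n)
        extra_pitch = np.zeros(n)
        next_allowed = -np.inf
        blackout_after = end_time - config.saccade_blackout
        for j in range(i0, n):
            tj = t[j]
            k = j - i0
            if (tj < next_allowed or tj > blackout_after
                    or ball_speed[k] > config.saccade_ball_speed_limit):
                continue
            err_yaw = ball_yaw[k] - (yaw[j] + extra_yaw[j])
            err_pitch = ball_pitch[k] - (pitch[j] + extra_pitch[j])
            if np.hypot(err_yaw, err_pitch) <= params.catchup_threshold:
                continue
            dur = rng.uniform(*config.saccade_duration_range)
            if tj + dur > end_time:
                continue
            t_target = min(tj + config.saccade_lead, t_flight[-1])
            amp_yaw = np.interp(t_target, t_flight, ball_yaw) - (yaw[j] + extra_yaw[j])
            amp_pitch = (np.interp(t_target, t_flight, ball_pitch)
                         - (pitch[j] + extra_pitch[j]))
            prof = _min_jerk((t - tj) / dur)
            extra_yaw += amp_yaw * prof
            extra_pitch += amp_pitch * prof
            next_allowed = tj + dur + config.saccade_refractory
            injected.append({"onset_t": float(tj), "offset_t": float(tj + dur),
                             "amplitude": float(np.hypot(amp_yaw, amp_pitch))})
        yaw += extra_yaw
        pitch += extra_pitch

    # --- tracker noise and dropouts ----------------------------------------
    yaw = yaw + _band_limited_noise(n, config.gaze_noise_sd, config.noise_bandwidth,
                                    config.sample_rate, rng)
    pitch = pitch + _band_limited_noise(n, config.gaze_noise_sd, config.noise_bandwidth,
                                        config.sample_rate, rng)
    valid = np.ones(n, dtype=bool)
    if config.missing_rate > 0:
        n_bad_target = config.missing_rate * n
        lost = 0
        while lost < n_bad_target:
            run = int(rng.integers(1, 4))
            start = int(rng.integers(0, n))
            valid[start:start + run] = False
            lost += run
        # dropout: the tracker repeats the last valid sample
        for j in range(1, n):
            if not valid[j]:
                yaw[j] = yaw[j - 1]
                pitch[j] = pitch[j - 1]

    return {
        "t": t, "yaw": yaw, "pitch": pitch, "valid": valid,
        "flight_slice": fl,
        "truth": {
            "strategy": strategy, "pursuit_gain": gain, "lag": lag_s,
            "predicted_side": predicted_side, "pre_onset_yaw": pre_yaw,
            "injected_saccades": injected, "n_saccades_injected": len(injected),
        },
    }


def simulate_outcome(
    meta: TrialMeta,
    gaze: dict,
    t_flight: np.ndarray,
    ball_pos: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    skill: float = 0.0,
) -> tuple[bool, float]:
    """Bernoulli interception outcome from tracking error and expectedness.

    success ~ Bernoulli(logistic(b0 + b_err * mean |angular error| + b_exp *
    expectedness)); the angular error is the great-circle angle between gaze
    and ball directions, averaged over the flight.
    """
    eye = np.asarray(config.eye_origin, dtype=float)
    fl = gaze["flight_slice"]
    n_fl = fl.stop - fl.start
    gdir = angles_to_vector(gaze["yaw"][fl], gaze["pitch"][fl])
    bdir = ball_pos[:n_fl] - eye[None, :]
    bdir = bdir / np.linalg.norm(bdir, axis=1, keepdims=True)
    cosang = np.clip(np.sum(gdir * bdir, axis=1), -1.0, 1.0)
    mean_err = float(np.degrees(np.arccos(cosang)).mean())
    logit = (config.success_intercept + skill
             + config.success_error_weight * mean_err
             + config.success_expectedness_weight * meta.expectedness)
    p = 1.0 / (1.0 + np.exp(-logit))
    return bool(rng.random() < p), mean_err


def simulate_trial(
    meta: TrialMeta,
    strategy: str,
    params: GazeStrategyParams,
    config: SimConfig,
    rng: np.random.Generator,
    pursuit_gain: float | None = None,
    lag: float | None = None,
    skill: float = 0.0,
) -> TrialRecording:
    """Assemble one complete trial recording (ball + gaze + outcome)."""
    t_flight, ball = simulate_ball(meta, config)
    gaze = simulate_gaze(meta, t_flight, ball, strategy, params, config, rng,
                         pursuit_gain=pursuit_gain, lag=lag)
    success, mean_err = simulate_outcome(meta, gaze, t_flight, ball, config, rng,
                                         skill=skill)
    t = gaze["t"]
    n = len(t)
    fl = gaze["flight_slice"]
    ball_full = np.full((n, 3), np.nan)
    ball_full[fl] = ball[:fl.stop - fl.start]
    gaze_dir = angles_to_vector(gaze["yaw"], gaze["pitch"])
    truth = dict(gaze["truth"], mean_angular_error=mean_err,
                 expectedness=meta.expectedness)
    return TrialRecording(
        meta=meta, t=t, gaze_dir=gaze_dir, ball_pos=ball_full,
        valid=gaze["valid"], eye_origin=np.asarray(config.eye_origin, dtype=float),
        tone_end_time=config.tone_lead,
        ball_release_time=config.tone_lead + meta.onset_delay,
        ball_end_time=config.tone_lead + meta.onset_delay + config.interception_delay,
        interception_success=success, truth=truth,
    )


def assign_strategies(config: SimConfig, seed: int | None = None) -> dict[int, str]:
    """Assign exactly round(strategy_mix * n) participants to "predictive"."""
    seed = config.rng_seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10_000,)))
    n_pred = _round_half_up(config.strategy_mix * config.n_participants)
    ids = rng.permutation(config.n_participants)
    return {int(pid): ("predictive" if i < n_pred else "pivot")
            for i, pid in enumerate(ids)}


def simulate_dataset(config: SimConfig, seed: int | None = None) -> list[TrialRecording]:
    """Simulate every trial of a full study dataset.

    Each participant draws individual pursuit gain, lag and side-commitment
    rate around their strategy's means, so participants form two clusters in
    tracking-metric space (the structure the strategy analyses look for).
    """
    seed = config.rng_seed if seed is None else seed
    strategies = assign_strategies(config, seed)
    schedule = make_schedule(config, seed)
    recordings: list[TrialRecording] = []
    per_participant: dict[int, tuple] = {}
    for pid in range(config.n_participants):
        rng = participant_rng(seed, pid + 100_000)
        strat = strategies[pid]
        params = config.predictive if strat == "predictive" else config.pivot
        gain = float(np.clip(rng.normal(params.pursuit_gain, params.gain_sd), 0.02, 1.3))
        lag = float(np.clip(rng.normal(params.lag, params.lag_sd), 0.0,
                            config.flight_duration * 0.8))
        commit = float(rng.uniform(*params.predict_rate_range))
        skill = float(rng.normal(0.0, config.success_skill_sd))
        per_participant[pid] = (strat, params, gain, lag, commit, skill, rng)
    for meta in schedule:
        (strat, params, gain, lag, commit, skill,
         rng) = per_participant[meta.participant_id]
        # a participant's commitment rate decides predictive vs central placement
        trial_params = GazeStrategyParams(
            pursuit_gain=params.pursuit_gain, lag=params.lag,
            catchup_threshold=params.catchup_threshold,
            pivot_drift_sd=params.pivot_drift_sd,
            predict_rate_range=(commit, commit),
            gain_sd=0.0, lag_sd=0.0,
        )
        recordings.append(simulate_trial(meta, strat, trial_params, config, rng,
                                         pursuit_gain=gain, lag=lag, skill=skill))
    return recordings


# --- dataset I/O -----------------------------------------------------------

def dataset_to_frame(recordings: list[TrialRecording]) -> pd.DataFrame:
    """Long-format sample table (one row per sample per trial)."""
    parts = []
    for rec in recordings:
        n = rec.n_samples
        parts.append(pd.DataFrame({
            "participant_id": rec.meta.participant_id,
            "block_id": rec.meta.block_id,
            "trial_id": rec.meta.trial_id,
            "t": rec.t,
            "gaze_x": rec.gaze_dir[:, 0], "gaze_y": rec.gaze_dir[:, 1],
            "gaze_z": rec.gaze_dir[:, 2],
            "ball_x": rec.ball_pos[:, 0], "ball_y": rec.ball_pos[:, 1],
            "ball_z": rec.ball_pos[:, 2],
            "valid": rec.valid.astype(int),
        }))
    return pd.concat(parts, ignore_index=True)


def trial_metadata(recordings: list[TrialRecording]) -> list[dict]:
    out = []
    for rec in recordings:
        out.append({
            "participant_id": rec.meta.participant_id,
            "block_id": rec.meta.block_id,
            "trial_id": rec.meta.trial_id,
            "release_side": rec.meta.release_side,
            "onset_delay": rec.meta.onset_delay,
            "p_left": rec.meta.p_left,
            "tone_end_time": rec.tone_end_time,
            "ball_release_time": rec.ball_release_time,
            "ball_end_time": rec.ball_end_time,
            "interception_success": rec.interception_success,
            "eye_origin": rec.eye_origin.tolist(),
            "truth": rec.truth,
        })
    return out


def write_dataset(recordings: list[TrialRecording], out_dir: str | Path) -> None:
    """Write samples.csv (long format) and metadata.json for a dataset."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset_to_frame(recordings).to_csv(out_dir / "samples.csv", index=False)
    with open(out_dir / "metadata.json", "w") as fh:
        json.dump(trial_metadata(recordings), fh, indent=1)


def read_dataset(in_dir: str | Path) -> list[TrialRecording]:
    """Reload a dataset written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    samples = pd.read_csv(in_dir / "samples.csv")
    with open(in_dir / "metadata.json") as fh:
        metas = json.load(fh)
    recordings = []
    grouped = samples.groupby(["participant_id", "block_id", "trial_id"], sort=False)
    lookup = {(m["participant_id"], m["block_id"], m["trial_id"]): m for m in metas}
    for key, df in grouped:
        m = lookup[key]
        meta = TrialMeta(m["participant_id"], m["block_id"], m["trial_id"],
                         m["release_side"], m["onset_delay"], m["p_left"])
        recordings.append(TrialRecording(
            meta=meta,
            t=df["t"].to_numpy(),
            gaze_dir=df[["gaze_x", "gaze_y", "gaze_z"]].to_numpy(),
            ball_pos=df[["ball_x", "ball_y", "ball_z"]].to_numpy(),
            valid=df["valid"].to_numpy().astype(bool),
            eye_origin=np.asarray(m["eye_origin"], dtype=float),
            tone_end_time=m["tone_end_time"],
            ball_release_time=m["ball_release_time"],
            ball_end_time=m["ball_end_time"],
            interception_success=m["interception_success"],
            truth=m.get("truth", {}),
        ))
    return recordings


def load_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from a YAML or JSON file (flat keys; nested strategy
    blocks under ``predictive`` / ``pivot``)."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
    for key in ("predictive", "pivot"):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = GazeStrategyParams(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in raw[key].items()
            })
    for key in ("blocks", "onset_delay_range", "saccade_duration_range", "eye_origin"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(tuple(b) if isinstance(b, list) else b for b in raw[key])
    return SimConfig(**raw)


def save_config(config: SimConfig, path: str | Path) -> None:
    path = Path(path)
    d = asdict(config)
    with open(path, "w") as fh:
        if path.suffix in (".yml", ".yaml"):
            yaml.safe_dump(d, fh)
        else:
            json.dump(d, fh, indent=1)
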