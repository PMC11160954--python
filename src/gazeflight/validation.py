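"""Parameter-recovery and calibration experiments on synthetic task data.

Every analysis stage of the pipeline is validated by generating trials with
known ground truth and measuring how well the estimators recover it:
pursuit-gain and lag recovery, saccade count recovery, type-I error and
slope recovery of the mixed logistic model, and a full-scale replication of
the two-strategy study design (mean-split recovery, MDS clustering).

These functions define the package's standard validation battery; the
acceptance script and test suite both run them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import strategy as strategy_mod
from .inference import fit_success_model
from .oculometrics import TaskGeometry, compute_trial_metrics, metrics_table
from .synthdata import (
    GazeStrategyParams,
    SimConfig,
    TrialMeta,
    assign_strategies,
    simulate_ball,
    simulate_dataset,
    simulate_trial,
)


def _clean_config(noise_sd: float = 0.0) -> SimConfig:
    return SimConfig(gaze_noise_sd=noise_sd, missing_rate=0.0,
                     onset_delay_range=(1.0, 1.0))


def _geometry(config: SimConfig) -> TaskGeometry:
    left, right = config.location_yaws
    return TaskGeometry(location_yaw_left=left, location_yaw_right=right)


def _controlled_trial(config, gain, lag, side, p_left, seed, catchup=None,
                      commit=1.0, drift_sd=0.0):
    params = GazeStrategyParams(
        pursuit_gain=gain, lag=lag, catchup_threshold=catchup,
        pivot_drift_sd=drift_sd, predict_rate_range=(commit, commit))
    meta = TrialMeta(0, 0, 0, side, config.onset_delay_range[0], p_left)
    rng = np.random.default_rng(seed)
    return simulate_trial(meta, "predictive", params, config, rng,
                          pursuit_gain=gain, lag=lag)


def flight_timing(config: SimConfig | None = None) -> dict:
    """Ball flight duration and mean speed measured from generated samples."""
    cfg = config or _clean_config()
    meta = TrialMeta(0, 0, 0, "right", 1.0, 0.5)
    t_flight, pos = simulate_ball(meta, cfg)
    dur = float(t_flight[-1] - t_flight[0])
    speed = float((pos[0, 2] - pos[-1, 2]) / dur)
    return {"flight_time_s": dur, "mean_speed_mps": speed,
            "release_distance_m": float(pos[0, 2] - pos[-1, 2])}


def gain_recovery(
    gains=(0.25, 0.5, 0.8, 1.0),
    noise_sd: float = 0.0,
    n_trials: int = 1,
    seed: int = 0,
) -> dict[float, float]:
    """Mean estimated pursuit gain per true gain (lag 0, saccades off)."""
    cfg = _clean_config(noise_sd)
    geom = _geometry(cfg)
    out = {}
    for g in gains:
        ests = []
        for i in range(n_trials):
            side = "left" if i % 2 == 0 else "right"
            rec = _controlled_trial(cfg, g, 0.0, side,
                                    1.0 if side == "left" else 0.0,
                                    seed=seed * 10_000 + i)
            ests.append(compute_trial_metrics(rec, geom)["gain"])
        out[g] = float(np.nanmean(ests))
    return out


def lag_recovery(lags_s=(0.025, 0.050, 0.100), seed: int = 0) -> dict[float, float]:
    """Estimated tracking lag (s) per imposed delay on noise-free trials."""
    cfg = _clean_config()
    geom = _geometry(cfg)
    out = {}
    for lag in lags_s:
        rec = _controlled_trial(cfg, 1.0, lag, "right", 0.0, seed=seed + 1)
        out[lag] = float(compute_trial_metrics(rec, geom)["lag"])
    return out


def saccade_count_recovery(
    n_trials: int = 24,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """Injected-vs-detected saccade counts on controlled predictive trials."""
    cfg = _clean_config(noise_sd)
    geom = _geometry(cfg)
    injected = detected = mismatch_trials = 0
    abs_errors = []
    for i in range(n_trials):
        rec = _controlled_trial(
            cfg, 0.85, 0.1, "right" if i % 2 else "left",
            0.7 if i % 3 else 0.3, seed=seed * 10_000 + i,
            catchup=6.0, commit=0.7, drift_sd=2.0)
        n_det = compute_trial_metrics(rec, geom)["n_saccades"]
        n_inj = rec.truth["n_saccades_injected"]
        injected += n_inj
        detected += n_det
        mismatch_trials += n_det != n_inj
        abs_errors.append(abs(n_det - n_inj))
    return {"injected": injected, "detected": detected,
            "mismatch_trials": mismatch_trials,
            "mean_abs_error": float(np.mean(abs_errors))}


def simulate_glmm_trials(
    rng: np.random.Generator,
    n_participants: int = 20,
    n_trials: int = 60,
    random_intercept_sd: float = 1.0,
    slope: float = 0.0,
    intercept: float = 0.5,
) -> pd.DataFrame:
    """Trial table from a known random-intercept logistic model."""
    rows = []
    for p in range(n_participants):
        u = rng.normal(0.0, random_intercept_sd)
        x = rng.normal(0.0, 1.0, n_trials)
        eta = intercept + u + slope * x
        y = rng.random(n_trials) < 1.0 / (1.0 + np.exp(-eta))
        rows.append(pd.DataFrame({"participant_id": p,
                                  "success": y.astype(int), "x": x}))
    return pd.concat(rows, ignore_index=True)


def type_i_error_rate(
    n_replicates: int = 200,
    n_participants: int = 20,
    n_trials: int = 60,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the single-predictor model under a null simulation."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        df = simulate_glmm_trials(rng, n_participants, n_trials, slope=0.0)
        res = fit_success_model(df, ["x"])
        rejections += res.p_values[1] < alpha
    return rejections / n_replicates


def slope_recovery(
    n_replicates: int = 50,
    true_slope: float = 0.5,
    n_participants: int = 20,
    n_trials: int = 60,
    seed: int = 0,
) -> float:
    """Mean standardized-beta estimate for a known effect on a unit-SD predictor."""
    rng = np.random.default_rng(seed)
    ests = []
    for _ in range(n_replicates):
        df = simulate_glmm_trials(rng, n_participants, n_trials, slope=true_slope)
        res = fit_success_model(df, ["x"])
        ests.append(res.standardized_betas[1])
    return float(np.mean(ests))


def study_replication(seed: int = 0, config: SimConfig | None = None) -> dict:
    """Full-scale two-strategy study: simulate, measure, aggregate, embed.

    Returns mean-split recovery against the generator's strategy assignment,
    the group sizes, MDS dimension-1 separability for strategy and for a
    mean-split performance label, and the leading variance proportions.
    """
    cfg = config or SimConfig(rng_seed=seed)
    geom = _geometry(cfg)
    truth = assign_strategies(cfg, seed)
    recordings = simulate_dataset(cfg, seed)
    metrics = metrics_table(recordings, geom)
    profiles = strategy_mod.build_profiles(metrics)
    labeled, grand_mean = strategy_mod.mean_split_strategy(profiles)
    labels = labeled["strategy"].to_numpy()
    accuracy = float(np.mean([
        labeled.set_index("participant_id")["strategy"].loc[p] == truth[p]
        for p in truth]))
    imputed = strategy_mod.impute_feature_means(labeled)
    emb = strategy_mod.classical_mds(imputed[strategy_mod.TRACKING_FEATURES])
    emb = strategy_mod.orient_embedding(emb, labels)
    d1 = emb.coordinates[:, 0]
    perf = np.where(labeled["interception_rate"]
                    > labeled["interception_rate"].mean(), "high", "low")
    return {
        "n_predictive": int((labels == "predictive").sum()),
        "n_pivot": int((labels == "pivot").sum()),
        "label_accuracy": accuracy,
        "strategy_separability": strategy_mod.threshold_separability(d1, labels),
        "performance_separability": strategy_mod.threshold_separability(d1, perf),
        "variance_proportions": emb.variance_proportions[:2].tolist(),
        "grand_mean_prediction_proportion": grand_mean,
        "interception_rate": float(metrics["success"].mean()),
        "metrics": metrics,
        "profiles": labeled,
    }
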