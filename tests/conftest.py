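import numpy as np
import pytest

import gazeflight as gf
from gazeflight.synthdata import GazeStrategyParams, TrialMeta


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, dropout-free task with a fixed onset delay."""
    return gf.SimConfig(gaze_noise_sd=0.0, missing_rate=0.0,
                        onset_delay_range=(1.0, 1.0))


@pytest.fixture(scope="session")
def geometry(clean_config):
    return gf.default_geometry(clean_config)


def make_trial(config, gain, lag, side="right", catchup=None, commit=1.0,
               strategy="predictive", p_left=0.5, seed=0, trial_id=0,
               drift_sd=0.0):
    """One controlled trial with known ground-truth tracking parameters."""
    params = GazeStrategyParams(
        pursuit_gain=gain, lag=lag, catchup_threshold=catchup,
        pivot_drift_sd=drift_sd, predict_rate_range=(commit, commit))
    meta = TrialMeta(0, 0, trial_id, side, config.onset_delay_range[0], p_left)
    rng = np.random.default_rng(seed)
    return gf.simulate_trial(meta, strategy, params, config, rng,
                             pursuit_gain=gain, lag=lag)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact multi-participant dataset with both strategies present."""
    cfg = gf.SimConfig(
        n_participants=8, blocks=((10, 0.5), (10, 0.8)),
        onset_delay_range=(0.2, 1.0), strategy_mix=0.5, rng_seed=5)
    return cfg, gf.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_metrics(small_dataset):
    cfg, recs = small_dataset
    return gf.metrics_table(recs, gf.default_geometry(cfg))
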