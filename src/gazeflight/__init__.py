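"""gazeflight: gaze-strategy analysis for virtual-reality manual interception.

The pipeline runs from raw gaze/ball time series to per-trial oculometric
measures (saccades, tracking coherence and lag, closed-loop pursuit gain,
pre-onset prediction), mixed-effects models of interception success, and
participant-level strategy clustering — together with a synthetic generator
of the two-location interception task for parameter-recovery validation.
"""

from .preprocess import (
    AngularTrace,
    KinematicTrace,
    FlightWindow,
    denoise,
    denoise_trace,
    vector_to_angles,
    angles_to_vector,
    ball_to_angles,
    gaze_to_angles,
    differentiate,
    flight_window,
)
from .synthdata import (
    SimConfig,
    GazeStrategyParams,
    TrialMeta,
    TrialRecording,
    make_schedule,
    simulate_ball,
    simulate_gaze,
    simulate_outcome,
    simulate_trial,
    simulate_dataset,
    assign_strategies,
    write_dataset,
    read_dataset,
    load_config,
    save_config,
)
from .oculometrics import (
    SaccadeEvent,
    TaskGeometry,
    detect_saccades,
    coherence_and_lag,
    pursuit_gain,
    classify_prediction,
    compute_trial_metrics,
    metrics_table,
    saccade_table,
)
from .inference import (
    ModelResult,
    GroupComparison,
    winsorize,
    fit_success_model,
    nakagawa_r2,
    compare_groups,
)
from .strategy import (
    MDSEmbedding,
    build_profiles,
    mean_split_strategy,
    classical_mds,
    orient_embedding,
    threshold_separability,
    impute_feature_means,
    strategy_report,
)

__version__ = "0.1.0"


def default_geometry(config: SimConfig | None = None) -> TaskGeometry:
    """Task geometry matching a simulation config (or the default task)."""
    cfg = config or SimConfig()
    left, right = cfg.location_yaws
    return TaskGeometry(location_yaw_left=left, location_yaw_right=right)
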