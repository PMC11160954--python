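"""Participant-level strategy analysis: profiles, mean split, classical MDS.

Each participant is summarized by their mean in-flight tracking metrics
(coherence, lag, gain, saccades per trial), interception rate and the
proportion of trials with a committed pre-onset prediction.  A mean split on
that proportion labels participants as using a *predictive* strategy (gaze
parked on an anticipated release location) or a *visual pivot* strategy
(gaze anchored centrally, ball monitored peripherally).  Classical (metric)
multidimensional scaling of the z-scored tracking profiles embeds
participants in a low-dimensional space in which strategy groups can be
inspected and compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import GroupComparison, compare_groups

TRACKING_FEATURES = ["coherence", "lag", "gain", "n_saccades"]

#: the five variables compared between strategy groups
COMPARISON_VARIABLES = ["interception_rate", "coherence", "lag", "gain", "n_saccades"]


@dataclass
class MDSEmbedding:
    coordinates: np.ndarray        # (n_participants, n_dims)
    eigenvalues: np.ndarray        # full spectrum, descending
    variance_proportions: np.ndarray  # over the positive spectrum, descending


def build_profiles(metrics: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-trial metrics to one profile row per participant.

    Means are taken over non-missing trials per metric; the prediction
    proportion is the fraction of classified trials with a committed (left or
    right) prediction.  Participants with zero valid trials are dropped with
    a warning.
    """
    rows = []
    for pid, g in metrics.groupby("participant_id"):
        n_classified = g["prediction_position"].notna().sum()
        if g[TRACKING_FEATURES].notna().sum().sum() == 0:
            warnings.warn(f"participant {pid} has no valid trials; excluded")
            continue
        rows.append({
            "participant_id": pid,
            "coherence": g["coherence"].mean(),
            "lag": g["lag"].mean(),
            "gain": g["gain"].mean(),
            "n_saccades": g["n_saccades"].mean(),
            "interception_rate": g["success"].mean(),
            "prediction_proportion": (
                (g["prediction"].notna()).sum() / n_classified
                if n_classified else np.nan),
            "n_trials": len(g),
        })
    return pd.DataFrame(rows)


def mean_split_strategy(profiles: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Label strategies by a mean split on the prediction proportion.

    Participants strictly above the grand mean are "predictive", the rest
    "pivot" (ties go to pivot).  Returns the labeled copy and the grand mean.
    """
    if len(profiles) < 2:
        raise ValueError("mean split needs at least 2 profiles")
    props = profiles["prediction_proportion"].to_numpy(float)
    grand_mean = float(np.nanmean(props))
    labeled = profiles.copy()
    labeled["strategy"] = np.where(props > grand_mean, "predictive", "pivot")
    if np.nanstd(props) == 0:
        warnings.warn("all prediction proportions identical; everyone labeled pivot")
    return labeled, grand_mean


def classical_mds(
    features: np.ndarray | pd.DataFrame,
    n_dims: int = 2,
    standardize: bool = True,
) -> MDSEmbedding:
    """Classical (Torgerson) MDS of a participants x features matrix.

    Features are z-scored (so no metric dominates by its units), pairwise
    Euclidean distances D are double-centered, B = -1/2 J D^2 J is
    eigendecomposed, and coordinates are eigenvectors scaled by the square
    roots of the top nonnegative eigenvalues.  Variance proportions are each
    eigenvalue over the sum of positive eigenvalues.  Coordinate signs are
    fixed so each dimension's largest-magnitude loading is positive.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 rows")
    if np.isnan(X).any():
        raise ValueError("MDS features contain missing values; impute upstream")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    n = X.shape[0]
    sq = np.sum(X**2, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.clip(D2, 0.0, None, out=D2)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(eigval.max(), 0) * 1e-12
    n_pos = int(positive.sum())
    if n_dims > n_pos:
        warnings.warn(f"requested {n_dims} dimensions but only {n_pos} positive "
                      "eigenvalues; truncating")
        n_dims = n_pos
    coords = eigvec[:, :n_dims] * np.sqrt(eigval[:n_dims])
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = eigval[positive].sum()
    var_prop = np.where(eigval > 0, eigval / pos_sum, 0.0)
    return MDSEmbedding(coordinates=coords, eigenvalues=eigval,
                        variance_proportions=var_prop)


def orient_embedding(embedding: MDSEmbedding, labels: np.ndarray,
                     positive_label: str = "predictive") -> MDSEmbedding:
    """Flip dimension signs so the given group's mean is positive on each axis."""
    coords = embedding.coordinates.copy()
    mask = np.asarray(labels) == positive_label
    if mask.any() and (~mask).any():
        for j in range(coords.shape[1]):
            if coords[mask, j].mean() < 0:
                coords[:, j] = -coords[:, j]
    return MDSEmbedding(coords, embedding.eigenvalues.copy(),
                        embedding.variance_proportions.copy())


def threshold_separability(scores: np.ndarray, labels: np.ndarray) -> float:
    """Best achievable accuracy of a single threshold on one coordinate.

    Used to quantify how linearly separable two groups are along an MDS
    dimension (1.0 = perfectly separable, ~0.5 + imbalance = chance).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("separability needs exactly 2 label values")
    y = labels == uniq[0]
    cuts = np.concatenate([[-np.inf], np.sort(scores)])
    best = 0.0
    for c in cuts:
        above = scores > c
        acc = max((above == y).mean(), (above == ~y).mean())
        best = max(best, acc)
    return float(best)


def impute_feature_means(profiles: pd.DataFrame,
                         features: list[str] = TRACKING_FEATURES) -> pd.DataFrame:
    """Column-mean imputation of missing tracking features before MDS."""
    out = profiles.copy()
    for f in features:
        out[f] = out[f].fillna(out[f].mean())
    return out


def strategy_report(
    profiles: pd.DataFrame,
    out_dir: str | Path,
    n_dims: int = 2,
) -> dict:
    """Run the full strategy analysis and write its tables and figures.

    Produces profiles.csv, embedding.csv, eigenvalues.csv, comparisons.csv
    and two scatter/distribution figures under ``out_dir``.  Returns the
    in-memory results (labeled profiles, embedding, comparisons).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labeled, grand_mean = mean_split_strategy(profiles)
    imputed = impute_feature_means(labeled)
    embedding = classical_mds(imputed[TRACKING_FEATURES], n_dims=n_dims)
    embedding = orient_embedding(embedding, labeled["strategy"].to_numpy())

    single_group = labeled["strategy"].nunique() < 2
    comparisons: list[GroupComparison] = []
    if not single_group:
        comparisons = compare_groups(labeled, labeled["strategy"],
                                     COMPARISON_VARIABLES)

    labeled.to_csv(out_dir / "profiles.csv", index=False)
    emb_df = pd.DataFrame(
        embedding.coordinates,
        columns=[f"dim{j + 1}" for j in range(embedding.coordinates.shape[1])])
    emb_df.insert(0, "participant_id", labeled["participant_id"].to_numpy())
    emb_df["strategy"] = labeled["strategy"].to_numpy()
    emb_df.to_csv(out_dir / "embedding.csv", index=False)
    pd.DataFrame({
        "eigenvalue": embedding.eigenvalues,
        "variance_proportion": embedding.variance_proportions,
    }).to_csv(out_dir / "eigenvalues.csv", index=False)
    comp_df = pd.DataFrame([{
        "variable": c.variable, "t": c.t_statistic, "df": c.df, "p": c.p_value,
        "cohens_d": c.cohens_d, "welch": c.welch,
        "mean_group_a": c.group_means[0], "mean_group_b": c.group_means[1],
    } for c in comparisons]) if comparisons else pd.DataFrame(
        [{"note": "single strategy group; comparisons not applicable"}])
    comp_df.to_csv(out_dir / "comparisons.csv", index=False)

    # MDS scatter colored by strategy and by a mean-split performance label
    perf_split = labeled["interception_rate"] > labeled["interception_rate"].mean()
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5), sharex=True, sharey=True)
    for ax, colour_by, title in (
        (axes[0], labeled["strategy"] == "predictive", "pre-onset strategy"),
        (axes[1], perf_split, "high vs low performance"),
    ):
        for val, col in ((True, "tab:orange"), (False, "tab:blue")):
            sel = colour_by.to_numpy() == val
            ax.scatter(embedding.coordinates[sel, 0],
                       embedding.coordinates[sel, 1] if n_dims > 1 else np.zeros(sel.sum()),
                       c=col, alpha=0.8, label=str(val))
        ax.set_xlabel("MDS dimension 1")
        ax.set_title(title)
        ax.legend(fontsize=8)
    axes[0].set_ylabel("MDS dimension 2")
    fig.tight_layout()
    fig.savefig(out_dir / "mds_scatter.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(labeled["prediction_proportion"].dropna(), bins=20)
    ax.axvline(grand_mean, color="k", ls="--", label="mean split")
    ax.set_xlabel("prediction proportion")
    ax.set_ylabel("participants")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "prediction_proportion.png", dpi=120)
    plt.close(fig)

    return {"profiles": labeled, "grand_mean": grand_mean,
            "embedding": embedding, "comparisons": comparisons}
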