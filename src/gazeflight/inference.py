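"""Statistical models linking tracking behavior to interception success.

The central model is a mixed-effects logistic regression of trial-level
interception success on one or more tracking metrics, with a random
intercept (optionally plus random slope) per participant.  Estimation uses
statsmodels' variational-Bayes binomial mixed GLM; Wald-style intervals and
p-values come from the posterior mean and SD of each fixed effect.
Variance explained is summarized with marginal and conditional R^2 for
GLMMs: the fixed-effect linear-predictor variance over (fixed + random +
pi^2/3), the logit-link distribution-specific variance.

Group-level contrasts (predictive vs visual-pivot strategies) use an
independent-samples t test, switching to Welch's form when an F-ratio test
rejects equal variances at alpha = 0.05, with Cohen's d on the pooled SD.
No multiple-testing correction is applied; the analyses are exploratory by
design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, sparse
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

LOGIT_RESIDUAL_VARIANCE = np.pi**2 / 3.0


@dataclass
class ModelResult:
    """Summary of one fitted mixed-effects logistic model."""

    predictors: list[str]
    coefficients: np.ndarray       # log-odds, includes intercept first
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    standardized_betas: np.ndarray  # NaN for the intercept
    marginal_r2: float
    conditional_r2: float
    n_obs: int
    n_groups: int
    random_spec: str
    converged: bool
    vc_variances: dict[str, float] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coefficients,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p": self.p_values,
            "std_beta": self.standardized_betas,
        }, index=["intercept"] + self.predictors)


@dataclass
class GroupComparison:
    variable: str
    t_statistic: float
    df: float
    p_value: float
    cohens_d: float
    welch: bool
    group_means: tuple[float, float]


def winsorize(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Replace values beyond mean +- k*SD with the nearer boundary.

    Mean and SD are those of the original sample, so the operation is a
    single deterministic pass (and hence idempotent).  NaNs pass through
    untouched; zero-variance input is returned unchanged.
    """
    x = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("winsorize needs at least 3 finite values")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        return x
    lo, hi = mu - k * sd, mu + k * sd
    x[finite] = np.clip(x[finite], lo, hi)
    return x


def _design(df: pd.DataFrame, predictors: list[str], outcome: str, group: str,
            random_spec: str):
    data = df[[outcome, group] + predictors].dropna().copy()
    y = data[outcome].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("outcome has no variance; cannot fit a logistic model")
    groups, group_idx = np.unique(data[group].to_numpy(), return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 participants for a mixed model")
    n = len(data)
    X = np.column_stack([np.ones(n)] + [data[p].to_numpy(float) for p in predictors])
    # random-effects design: indicator columns per participant, plus
    # participant-specific slope columns when requested
    ind = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), group_idx)), shape=(n, len(groups)))
    vc_blocks = [ind]
    vc_names = ["participant"]
    if random_spec == "intercept+slope":
        if len(predictors) != 1:
            raise ValueError("random slopes are supported for single-predictor models")
        slope_vals = data[predictors[0]].to_numpy(float)
        vc_blocks.append(sparse.csr_matrix(
            (slope_vals, (np.arange(n), group_idx)), shape=(n, len(groups))))
        vc_names.append(f"participant:{predictors[0]}")
    elif random_spec != "intercept":
        raise ValueError(f"unknown random_spec {random_spec!r}")
    exog_vc = sparse.hstack(vc_blocks, format="csr")
    ident = np.concatenate([np.full(len(groups), i) for i in range(len(vc_blocks))])
    return data, y, X, exog_vc, ident, vc_names, len(groups)


def fit_success_model(
    trials: pd.DataFrame,
    predictors: list[str],
    random_spec: str = "intercept",
    outcome: str = "success",
    group: str = "participant_id",
) -> ModelResult:
    """Fit a mixed-effects logistic regression of a binary outcome.

    Standardized betas multiply each coefficient by the SD of its predictor
    (binary predictors and the binary outcome are left unscaled).  The
    prediction-accuracy variant is obtained by filtering the table to
    classified trials upstream and passing a 0/1 ``prediction_correct``
    predictor with ``random_spec="intercept+slope"``.
    """
    data, y, X, exog_vc, ident, vc_names, n_groups = _design(
        trials, predictors, outcome, group, random_spec)
    model = BinomialBayesMixedGLM(y, X, exog_vc, ident,
                                  vcp_p=2.0, fe_p=2.0)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit_vb()
        except Exception as exc:  # noqa: BLE001 - surfaced, never silent
            raise RuntimeError(f"mixed logistic model failed to converge: {exc}") from exc
    k_fe = X.shape[1]
    coefs = np.asarray(fit.fe_mean, dtype=float)
    sds = np.asarray(fit.fe_sd, dtype=float)
    if not np.all(np.isfinite(coefs)) or not np.all(np.isfinite(sds)):
        converged = False
    z = coefs / sds
    p = 2 * stats.norm.sf(np.abs(z))
    ci_lo = coefs - 1.96 * sds
    ci_hi = coefs + 1.96 * sds
    std_betas = np.full(k_fe, np.nan)
    for j, name in enumerate(predictors, start=1):
        vals = data[name].to_numpy(float)
        if len(np.unique(vals)) > 2:
            std_betas[j] = coefs[j] * vals.std(ddof=1)
        else:
            std_betas[j] = coefs[j]
    vc_var = {name: float(np.exp(2.0 * m))
              for name, m in zip(vc_names, fit.vcp_mean)}
    marginal, conditional = nakagawa_r2(X, coefs, sum(vc_var.values()))
    return ModelResult(
        predictors=list(predictors),
        coefficients=coefs, ci_lower=ci_lo, ci_upper=ci_hi, p_values=p,
        standardized_betas=std_betas,
        marginal_r2=marginal, conditional_r2=conditional,
        n_obs=len(y), n_groups=n_groups, random_spec=random_spec,
        converged=converged, vc_variances=vc_var,
    )


def nakagawa_r2(X: np.ndarray, coefficients: np.ndarray,
                random_variance: float) -> tuple[float, float]:
    """Marginal and conditional R^2 for a logistic mixed model.

    marginal = var(X beta) / (var(X beta) + var_random + pi^2/3);
    conditional adds the random-effect variance to the numerator.
    """
    if not np.isfinite(random_variance) or random_variance < 0:
        raise ValueError("random-effect variance must be finite and nonnegative")
    eta = np.asarray(X) @ np.asarray(coefficients)
    var_f = float(np.var(eta))
    denom = var_f + random_variance + LOGIT_RESIDUAL_VARIANCE
    return var_f / denom, (var_f + random_variance) / denom


def variance_ratio_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F test of equal variances; returns the p-value."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or (va >= vb and vb > 0):
        f, d1, d2 = va / vb, len(a) - 1, len(b) - 1
    else:
        f, d1, d2 = vb / va, len(b) - 1, len(a) - 1
    return float(min(1.0, 2.0 * stats.f.sf(f, d1, d2)))


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def compare_groups(
    profiles: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    variables: list[str],
    alpha_variance: float = 0.05,
) -> list[GroupComparison]:
    """Two-group comparisons of participant-level variables.

    Student's t by default; Welch's t when the F-ratio variance test rejects
    equality at ``alpha_variance``.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(uniq)}")
    out = []
    for var in variables:
        vals = profiles[var].to_numpy(float)
        a = vals[labels == uniq[0]]
        b = vals[labels == uniq[1]]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"group size < 2 for variable {var!r}")
        welch = variance_ratio_test(a, b) < alpha_variance
        res = stats.ttest_ind(a, b, equal_var=not welch)
        if welch:
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        else:
            dof = len(a) + len(b) - 2
        out.append(GroupComparison(
            variable=var, t_statistic=float(res.statistic), df=float(dof),
            p_value=float(res.pvalue), cohens_d=cohens_d(a, b), welch=welch,
            group_means=(float(a.mean()), float(b.mean())),
        ))
    return out
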