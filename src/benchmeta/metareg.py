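"""Weighted meta-regression and intrastudy-regression validation.

The meta-regression model relates study-level outcomes to study-level
covariates:

    y_i = beta_0 + beta_1 x_{1,i} + ... + beta_n x_{n,i} + eta_i + eps_i

with intrastudy error eps_i ~ N(0, se_i^2) and eta_i = 0 (fixed) or
eta_i ~ N(0, tau2) (random). Coefficients come from weighted least
squares with w_i = 1/se_i^2 (fixed) or 1/(se_i^2 + tau2) (random), where
tau2 is the one-step method-of-moments estimate
(Q_residual - df)/c_total truncated at zero. The dispersion about the
regression line, Q_residual = sum w_i (theta_i - yhat_i)^2 with
fixed-effect weights, and the explained part Q_model = Q_total -
Q_residual decompose total heterogeneity exactly.

Because across-study relationships need not hold within studies
(aggregation bias), the interstudy coefficient should be validated
against the pooled within-study slope beta_intra obtained from studies
reporting several predictor levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import EffectSize
from .pooling import critical_value, estimate_tau2, fixed_effect_summary, pool

logger = logging.getLogger(__name__)

__all__ = ["MetaRegResult", "IntrastudySlope", "meta_regression",
           "intrastudy_regression", "build_design"]


@dataclass
class MetaRegResult:
    """Weighted meta-regression fit with heterogeneity decomposition."""

    beta: np.ndarray
    se_beta: np.ndarray
    ci_beta: List[Tuple[float, float]]
    coef_names: List[str]
    Q_total: float
    Q_residual: float
    Q_model: float
    p_residual: float
    p_model: float
    tau2_residual: float
    tau2_total: float
    R2_explained: float
    R2_raw: float
    model: str
    df_residual: int


@dataclass
class IntrastudySlope:
    """Within-study regression slope for one study."""

    study_id: str
    beta_intra: float
    se_intra: float
    n_points: int


def build_design(X: Union[np.ndarray, pd.DataFrame, Sequence],
                 n: int) -> Tuple[np.ndarray, List[str]]:
    """Assemble the design matrix with an intercept column.

    Accepts a 1-D/2-D array or a DataFrame; categorical (object) columns
    are reference-cell dummy coded with the lexicographically first level
    as reference.
    """
    if isinstance(X, pd.DataFrame):
        parts = []
        names: List[str] = []
        for col in X.columns:
            s = X[col]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                levels = sorted(s.astype(str).unique())
                ref = levels[0]
                logger.info("dummy coding %r with reference level %r", col, ref)
                for lev in levels[1:]:
                    parts.append((s.astype(str) == lev).to_numpy(dtype=float))
                    names.append(f"{col}[{lev}]")
            else:
                parts.append(s.to_numpy(dtype=float))
                names.append(str(col))
        mat = np.column_stack(parts) if parts else np.empty((len(X), 0))
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"x{i + 1}" for i in range(mat.shape[1])]
    if mat.shape[0] != n:
        raise ValueError("design matrix rows must match number of effects")
    design = np.column_stack([np.ones(n), mat])
    return design, ["intercept"] + names


def _wls(design: np.ndarray, y: np.ndarray, w: np.ndarray
         ) -> Tuple[np.ndarray, np.ndarray]:
    """Weighted LS solve; returns (beta, cov) with cov = (X'WX)^-1.

    The known-variance covariance convention is used: weights are assumed
    to be true inverse variances, so no residual-variance rescaling.
    """
    Xw = design * w[:, None]
    XtWX = design.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ y)
    cov = np.linalg.inv(XtWX)
    return beta, cov


def meta_regression(effects: Sequence[EffectSize],
                    X: Union[np.ndarray, pd.DataFrame, Sequence],
                    model: str = "random", tau2_method: str = "DL",
                    alpha: float = 0.05) -> MetaRegResult:
    """Fit the weighted meta-regression model and decompose heterogeneity.

    Parameters
    ----------
    X
        Covariate matrix (without intercept; one is added). DataFrames
        may mix continuous and categorical columns.
    model
        ``fixed`` (eta_i = 0) or ``random`` (eta_i ~ N(0, tau2) with the
        one-step moments tau2 from the fixed-weight residual fit).

    Notes
    -----
    ``Q_residual`` is always evaluated with fixed-effect weights at the
    fixed-weight fit so that Q_model + Q_residual = Q_total holds
    exactly; the reported coefficients use the requested model's weights.
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    theta = np.array([e.theta for e in effects])
    se = np.array([e.se for e in effects])
    N = len(theta)
    design, names = build_design(X, N)
    p = design.shape[1]
    if N <= p:
        raise ValueError(f"need more studies ({N}) than coefficients ({p})")
    if np.linalg.matrix_rank(design) < p:
        raise ValueError("design matrix is rank deficient (collinear columns)")

    w_fe, _, Q_total = fixed_effect_summary(theta, se)

    beta_fe, _ = _wls(design, theta, w_fe)
    resid_fe = theta - design @ beta_fe
    Q_residual = float(np.sum(w_fe * resid_fe ** 2))
    df_res = N - p
    c_total = float(np.sum(w_fe) - np.sum(w_fe ** 2) / np.sum(w_fe))
    tau2_res = max(0.0, (Q_residual - df_res) / c_total)

    if model == "fixed":
        w = w_fe
        tau2_used = 0.0
        beta, cov = beta_fe, _wls(design, theta, w_fe)[1]
    else:
        tau2_used = tau2_res
        w = 1.0 / (se ** 2 + tau2_used)
        beta, cov = _wls(design, theta, w)

    se_beta = np.sqrt(np.diag(cov))
    v = critical_value(alpha, df_res + 1, "t")  # t with df = N - p
    ci = [(b - v * s, b + v * s) for b, s in zip(beta, se_beta)]

    Q_model = Q_total - Q_residual
    p_residual = float(stats.chi2.sf(Q_residual, df_res))
    p_model = float(stats.chi2.sf(Q_model, p - 1)) if p > 1 else 1.0

    tau2_total = estimate_tau2(effects, tau2_method)
    r2_raw = (1.0 - tau2_res / tau2_total) * 100.0 if tau2_total > 0 else 0.0
    r2 = min(100.0, max(0.0, r2_raw))
    if r2_raw < 0:
        logger.info("R2_explained %.2f%% truncated to 0 (sampling noise)", r2_raw)

    return MetaRegResult(beta=beta, se_beta=se_beta, ci_beta=ci,
                         coef_names=names, Q_total=Q_total,
                         Q_residual=Q_residual, Q_model=Q_model,
                         p_residual=p_residual, p_model=p_model,
                         tau2_residual=tau2_res, tau2_total=tau2_total,
                         R2_explained=r2, R2_raw=r2_raw, model=model,
                         df_residual=df_res)


def intrastudy_regression(series: Mapping[str, Tuple[Sequence, Sequence, Sequence, Sequence]],
                          scheme: str = "random", tau2_method: str = "DL",
                          alpha: float = 0.05
                          ) -> Tuple[float, Tuple[float, float], List[IntrastudySlope]]:
    """Pool within-study slopes into an overall effect beta_intra.

    Parameters
    ----------
    series
        Mapping study_id -> (x, theta, sd, n) sequences of per-level
        summaries. Studies with fewer than 2 distinct x levels are
        skipped with a warning.

    Returns
    -------
    (beta_intra, ci, per_study)
        The pooled within-study slope with its CI, and the per-study
        slopes. beta_intra is directly comparable in sign and magnitude
        with the interstudy coefficient from :func:`meta_regression`.
    """
    slopes: List[IntrastudySlope] = []
    for sid, (x, th, sd, n) in series.items():
        x = np.asarray(x, dtype=float)
        th = np.asarray(th, dtype=float)
        if len(np.unique(x)) < 2:
            logger.warning("study %r skipped: fewer than 2 distinct x levels", sid)
            continue
        res = stats.linregress(x, th)
        stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        slopes.append(IntrastudySlope(study_id=sid, beta_intra=float(res.slope),
                                      se_intra=stderr, n_points=len(x)))
    if len(slopes) < 2:
        raise ValueError("intrastudy regression needs at least 2 usable studies")

    ses = np.array([s.se_intra for s in slopes])
    use_scheme = scheme
    if scheme in ("fixed", "random") and np.any(ses == 0):
        logger.warning("zero slope standard errors: pooling intrastudy slopes "
                       "unweighted instead of %r", scheme)
        use_scheme = "unweighted"
    eff = [EffectSize(s.study_id, s.beta_intra, s.se_intra, max(s.n_points, 1),
                      measure="absolute") for s in slopes]
    est = pool(eff, scheme=use_scheme, tau2_method=tau2_method, alpha=alpha)
    return est.theta_hat, est.ci, slopes
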