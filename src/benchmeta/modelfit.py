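"""Monte-Carlo error-propagation fitting of complex input-output models.

Studies reporting a response curve give, at each predictor level x_j, a
summary (theta_j, sd_j, n_j). To propagate the reported uncertainty into
model-parameter uncertainty without analytic error-propagation formulas,
each Monte-Carlo iteration draws n_j pseudo-observations from
N(theta_j, sd_j^2) per level, averages them into theta_j*, and fits the
chosen model y = f(x, beta) to (x, theta*) by damped nonlinear least
squares. Over M iterations this yields a distribution of parameter
estimates whose mean converges to E(beta) as M grows; its spread sd(beta)
is the propagated parameter uncertainty. Reliable fits show unimodal,
approximately normal parameter distributions and a high R^2 of the
mean-parameter curve.

Five standard models are registered: linear, quadratic (vertex form),
exponential, Michaelis-Menten and the sigmoidal Hill function.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .datatypes import CurveDataset, ModelFitResult, ModelSpec

logger = logging.getLogger(__name__)

__all__ = ["MODELS", "get_model", "mc_fit", "fit_quality"]


def _f_linear(x, b1, b2):
    return b1 * x + b2


def _init_linear(x, y):
    return tuple(np.polyfit(x, y, 1))


def _f_quadratic(x, b1, b2, b3):
    return b1 * (x - b2) ** 2 + b3


def _init_quadratic(x, y):
    a, b, c = np.polyfit(x, y, 2)
    if abs(a) < 1e-12:
        return (1e-6, float(np.mean(x)), float(np.mean(y)))
    return (a, -b / (2 * a), c - b ** 2 / (4 * a))


def _f_exponential(x, b1, b2):
    return b1 * np.exp(b2 * x)


def _init_exponential(x, y):
    mask = y > 0
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(x[mask], np.log(y[mask]), 1)
        return (math.exp(intercept), slope)
    return (float(np.max(np.abs(y)) or 1.0), -0.1)


def _half_max_x(x, y):
    """x at half-maximal response, linearly interpolated."""
    ymax = np.max(y)
    half = ymax / 2.0
    order = np.argsort(x)
    xs, ys = np.asarray(x)[order], np.asarray(y)[order]
    for i in range(len(xs) - 1):
        y0, y1 = ys[i], ys[i + 1]
        if (y0 - half) * (y1 - half) <= 0 and y0 != y1:
            return float(xs[i] + (half - y0) / (y1 - y0) * (xs[i + 1] - xs[i]))
    return float(np.median(xs[xs > 0])) if np.any(xs > 0) else 1.0


def _f_mm(x, b1, b2):
    return b1 * x / (b2 + x)


def _init_mm(x, y):
    return (float(np.max(y)), _half_max_x(x, y))


def _f_hill(x, b1, b2, b3):
    return b1 * x ** b3 / (b2 ** b3 + x ** b3)


def _init_hill(x, y):
    b1, b2 = _init_mm(x, y)
    return (b1, b2, 1.0)


MODELS: Dict[str, ModelSpec] = {
    "linear": ModelSpec("linear", _f_linear, 2, ("slope", "intercept"), _init_linear),
    "quadratic_vertex": ModelSpec("quadratic_vertex", _f_quadratic, 3,
                                  ("curvature", "x_vertex", "y_vertex"), _init_quadratic),
    "exponential": ModelSpec("exponential", _f_exponential, 2,
                             ("amplitude", "rate"), _init_exponential),
    "michaelis_menten": ModelSpec("michaelis_menten", _f_mm, 2,
                                  ("v_max", "k_m"), _init_mm),
    "hill": ModelSpec("hill", _f_hill, 3, ("e_max", "ec50", "hill_coef"), _init_hill),
}


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise ValueError(f"unknown model {model_id!r}; "
                         f"available: {sorted(MODELS)}") from None


def mc_fit(data: CurveDataset, spec: ModelSpec, M: int = 400, seed: int = 0,
           truncate_at_zero: bool = False) -> ModelFitResult:
    """Monte-Carlo error-propagation fit.

    Parameters
    ----------
    data
        Per-level summaries (x_j, theta_j, sd_j, n_j); needs at least as
        many levels as model parameters.
    M
        Number of resampling iterations (400 is a practical default for
        stable parameter means and sds).
    seed
        Seeds one root generator; each iteration uses a deterministically
        spawned substream, so increasing M extends rather than reshuffles
        the sequence.
    truncate_at_zero
        Clip pseudo-observations at zero for physically nonnegative
        quantities. Off by default: the sampling model is plain normal.

    Non-converging iterations (optimizer failure or non-finite estimates)
    are dropped and accounted for in ``converged_fraction``.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    if data.k < spec.n_params:
        raise ValueError(f"model {spec.model_id!r} needs at least "
                         f"{spec.n_params} predictor levels, got {data.k}")
    if M < 1:
        raise ValueError("M must be >= 1")

    root = np.random.SeedSequence(seed)
    children = root.spawn(M)
    draws = []
    for m in range(M):
        rng = np.random.default_rng(children[m])
        theta_star = np.empty(data.k)
        for j in range(data.k):
            obs = rng.normal(data.theta[j], data.sd[j], size=data.n[j])
            if truncate_at_zero:
                obs = np.clip(obs, 0.0, None)
            theta_star[j] = obs.mean()
        try:
            with np.errstate(all="ignore"):
                p0 = spec.initializer(data.x, theta_star)
                beta, _ = optimize.curve_fit(spec.func, data.x, theta_star,
                                             p0=p0, maxfev=5000)
            if not np.all(np.isfinite(beta)):
                raise RuntimeError("non-finite estimate")
            draws.append(beta)
        except (RuntimeError, ValueError, TypeError):
            continue

    if not draws:
        raise RuntimeError(f"all {M} Monte-Carlo iterations failed to converge")
    draws = np.asarray(draws)
    beta_mean = draws.mean(axis=0)
    beta_sd = draws.std(axis=0, ddof=1) if len(draws) > 1 else np.zeros(spec.n_params)
    result = ModelFitResult(model_id=spec.model_id, beta_mean=beta_mean,
                            beta_sd=beta_sd, draws=draws, M=M,
                            converged_fraction=len(draws) / M)
    if len(draws) >= 10:
        r2, flags = fit_quality(result, data)
        result.r2, result.normality_flags = r2, flags
    else:
        result.r2 = _r2(spec, beta_mean, data)
    return result


def _r2(spec: ModelSpec, beta: np.ndarray, data: CurveDataset) -> float:
    pred = spec.func(data.x, *beta)
    ss_res = float(np.sum((data.theta - pred) ** 2))
    ss_tot = float(np.sum((data.theta - data.theta.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res < 1e-24 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_quality(result: ModelFitResult, data: CurveDataset,
                alpha: float = 0.05) -> Tuple[float, Sequence[bool]]:
    """Goodness of fit (R^2 of the mean-parameter curve against the
    reported means) and per-parameter normality flags.

    Each parameter's converged draws are tested for normality
    (Shapiro-Wilk at ``alpha``); a True flag means the distribution is
    consistent with normal, the hallmark of a reliable propagation.
    Degenerate (constant) draw columns pass by construction. Requires at
    least 10 draws.
    """
    if result.draws.shape[0] < 10:
        raise ValueError("normality assessment needs at least 10 draws")
    spec = get_model(result.model_id)
    r2 = _r2(spec, result.beta_mean, data)
    flags = []
    for col in result.draws.T:
        if np.ptp(col) < 1e-12 * max(1.0, abs(col[0])):
            flags.append(True)
            continue
        _, p = stats.shapiro(col)
        flags.append(bool(p > alpha))
    return r2, flags
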