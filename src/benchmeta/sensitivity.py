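"""Bias diagnostics and heterogeneity sensitivity analyses.

Provides funnel-plot data (effect vs precision with the expected
no-bias CI contour), Baujat decomposition of each study's contribution
to heterogeneity and to the pooled effect, single-study exclusion, and
cumulative-study exclusion with the homogeneity threshold T_H — the
percentage of studies that must be removed (always the study whose
removal maximally reduces Cochran's Q) before the Q-test stops being
significant.

Q is always computed with fixed-effect weights; the per-step pooled
estimate honours the caller's chosen weighting scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .datatypes import EffectSize
from .pooling import critical_value, fixed_effect_summary, pool

logger = logging.getLogger(__name__)

__all__ = [
    "FunnelData",
    "BaujatPoint",
    "ExclusionTrace",
    "HomogeneityThreshold",
    "funnel",
    "baujat",
    "single_exclusion",
    "cumulative_exclusion",
]


@dataclass
class FunnelData:
    """Per-study (theta, 1/se) with fixed/random reference lines.

    ``ci_bounds(se)`` returns the expected 95% no-bias contour around the
    fixed-effect line at a given standard error; ``outside`` flags
    studies outside the contour at their own se.
    """

    theta: np.ndarray
    precision: np.ndarray
    fixed_line: float
    random_line: float
    ci_bounds: Callable[[float], Tuple[float, float]]
    outside: np.ndarray


@dataclass
class BaujatPoint:
    """x: contribution to heterogeneity; y: influence on the pooled effect."""

    study_id: str
    x: float
    y: float


@dataclass
class ExclusionTrace:
    """One sensitivity-analysis step: statistics after an omission."""

    step: int
    removed_id: str
    Q: float
    H2: float
    I2: float
    theta_hat: float
    ci: Tuple[float, float]
    p_Q: float


@dataclass
class HomogeneityThreshold:
    """Percentage of studies removed before the Q-test p exceeds alpha."""

    T_H: float
    steps_to_homogeneity: int
    reached: bool = True


def _het_stats(theta: np.ndarray, se: np.ndarray) -> Tuple[float, float, float, float]:
    _, _, Q = fixed_effect_summary(theta, se)
    df = len(theta) - 1
    p = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0
    H2 = max(1.0, Q / df) if df > 0 else 1.0
    I2 = (H2 - 1.0) / H2 * 100.0
    return Q, H2, I2, p


def funnel(effects: Sequence[EffectSize],
           pooled_fixed=None, pooled_random=None,
           alpha: float = 0.05) -> FunnelData:
    """Funnel-plot data: effects against precision 1/se.

    In the absence of bias, studies scatter symmetrically around the
    fixed-effect line, with less precise studies spreading wider; the
    contour theta_FE +/- v * se delimits the expected spread.
    """
    if len(effects) < 2:
        raise ValueError("funnel requires at least 2 studies")
    theta = np.array([e.theta for e in effects])
    se = np.array([e.se for e in effects])
    if np.any(se <= 0):
        raise ValueError("funnel requires positive se for every study")
    if pooled_fixed is None:
        pooled_fixed = pool(effects, scheme="fixed", alpha=alpha)
    if pooled_random is None:
        pooled_random = pool(effects, scheme="random", alpha=alpha)
    v = critical_value(alpha, len(theta), "z")
    fe = pooled_fixed.theta_hat

    def ci_bounds(s: float) -> Tuple[float, float]:
        return (fe - v * s, fe + v * s)

    outside = np.abs(theta - fe) > v * se
    return FunnelData(theta=theta, precision=1.0 / se, fixed_line=fe,
                      random_line=pooled_random.theta_hat,
                      ci_bounds=ci_bounds, outside=outside)


def baujat(effects: Sequence[EffectSize]) -> List[BaujatPoint]:
    """Per-study heterogeneity contribution and influence coordinates.

    x_i = (theta_i - theta_FE)^2 / se_i^2 is study i's share of Q
    (the x coordinates sum to Q exactly); y_i = (theta_FE(-i) -
    theta_FE)^2 / se(theta_FE(-i))^2 measures the shift of the pooled
    fixed-effect estimate when study i is left out, in units of the
    leave-one-out variance.
    """
    if len(effects) < 3:
        raise ValueError("Baujat decomposition requires at least 3 studies")
    theta = np.array([e.theta for e in effects])
    se = np.array([e.se for e in effects])
    w, theta_fe, _ = fixed_effect_summary(theta, se)
    points = []
    for i, e in enumerate(effects):
        x = float(w[i] * (theta[i] - theta_fe) ** 2)
        mask = np.arange(len(theta)) != i
        w_i = w[mask]
        theta_minus = float(np.sum(w_i * theta[mask]) / np.sum(w_i))
        var_minus = 1.0 / float(np.sum(w_i))
        y = float((theta_minus - theta_fe) ** 2 / var_minus)
        points.append(BaujatPoint(study_id=e.study_id, x=x, y=y))
    return points


def single_exclusion(effects: Sequence[EffectSize], scheme: str = "random",
                     tau2_method: str = "DL", alpha: float = 0.05
                     ) -> List[ExclusionTrace]:
    """Leave-one-out sensitivity: recompute the pooled estimate and
    heterogeneity statistics with each single study omitted."""
    if len(effects) < 3:
        raise ValueError("single-study exclusion requires at least 3 studies")
    traces = []
    for i, e in enumerate(effects):
        rest = [f for j, f in enumerate(effects) if j != i]
        theta = np.array([f.theta for f in rest])
        se = np.array([f.se for f in rest])
        Q, H2, I2, p = _het_stats(theta, se)
        est = pool(rest, scheme=scheme, tau2_method=tau2_method, alpha=alpha)
        traces.append(ExclusionTrace(step=i, removed_id=e.study_id, Q=Q,
                                     H2=H2, I2=I2, theta_hat=est.theta_hat,
                                     ci=est.ci, p_Q=p))
    return traces


def cumulative_exclusion(effects: Sequence[EffectSize], alpha: float = 0.05,
                         scheme: str = "fixed", tau2_method: str = "DL"
                         ) -> Tuple[List[ExclusionTrace], HomogeneityThreshold]:
    """Sequentially remove the study whose removal maximally reduces Q.

    Removal stops as soon as the Q-test p-value exceeds ``alpha``
    (homogeneity attained) or only two studies remain. The homogeneity
    threshold T_H is the percentage of the original studies removed
    before homogeneity was first reached. Ties in the Q reduction are
    broken toward the lowest-index study and logged.
    """
    if len(effects) < 3:
        raise ValueError("cumulative exclusion requires at least 3 studies")
    remaining = list(effects)
    N0 = len(effects)
    traces: List[ExclusionTrace] = []
    steps = 0
    reached = False

    theta = np.array([e.theta for e in remaining])
    se = np.array([e.se for e in remaining])
    _, _, _, p = _het_stats(theta, se)
    if p > alpha:
        reached = True
    else:
        while len(remaining) > 2:
            theta = np.array([e.theta for e in remaining])
            se = np.array([e.se for e in remaining])
            Q_now, _, _, _ = _het_stats(theta, se)
            drops = []
            for i in range(len(remaining)):
                mask = np.arange(len(remaining)) != i
                if mask.sum() >= 2:
                    _, _, Q_minus = fixed_effect_summary(theta[mask], se[mask])
                else:
                    Q_minus = 0.0
                drops.append(Q_now - Q_minus)
            drops = np.asarray(drops)
            j = int(np.argmax(drops))
            if np.sum(np.isclose(drops, drops[j], rtol=0, atol=1e-12)) > 1:
                logger.info("tie in Q reduction at step %d; removing lowest-index "
                            "study %r", steps + 1, remaining[j].study_id)
            removed = remaining.pop(j)
            steps += 1
            theta = np.array([e.theta for e in remaining])
            se = np.array([e.se for e in remaining])
            Q, H2, I2, p = _het_stats(theta, se)
            est = pool(remaining, scheme=scheme, tau2_method=tau2_method, alpha=alpha)
            traces.append(ExclusionTrace(step=steps, removed_id=removed.study_id,
                                         Q=Q, H2=H2, I2=I2,
                                         theta_hat=est.theta_hat, ci=est.ci, p_Q=p))
            if p > alpha:
                reached = True
                break
        if not reached:
            logger.warning("homogeneity not attained before reaching 2 studies")

    T_H = 100.0 * steps / N0
    return traces, HomogeneityThreshold(T_H=T_H, steps_to_homogeneity=steps,
                                        reached=reached)
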