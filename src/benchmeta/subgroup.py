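"""Subgroup heterogeneity decomposition and multiple-comparison control.

Partitioning studies by a categorical covariate splits Cochran's Q into
the within-group component

    Q_within = sum_j sum_{i in j} w_i (theta_i - theta_FE,j)^2

and the explained component Q_between = Q_total - Q_within, each
referred to chi^2 (df = S - 1 between, N - S within). The residual
between-study variance pooled over subgroups,

    tau2_within = (sum_j Q_j - sum_j df_j) / sum_j c_j,
    c_j = sum w - sum w^2 / sum w   (within group j),

feeds R^2_explained = (1 - tau2_within / tau2_total) * 100%, the percent
of total heterogeneity explained by the covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .datatypes import EffectSize, HeterogeneityReport, PooledEstimate
from .pooling import estimate_tau2, fixed_effect_summary, heterogeneity, pool

logger = logging.getLogger(__name__)

__all__ = ["SubgroupResult", "subgroup_analysis", "bonferroni"]


@dataclass
class SubgroupResult:
    """Per-covariate subgroup decomposition of heterogeneity."""

    covariate: str
    groups: Dict[str, Tuple[PooledEstimate, Optional[HeterogeneityReport], int]]
    Q_total: float
    Q_between: float
    Q_within: float
    p_between: float
    p_within: float
    tau2_within: float
    tau2_total: float
    R2_explained: float
    R2_raw: float  # pre-truncation value, kept for diagnostics


def _labels_for(effects: Sequence[EffectSize],
                labels: Union[Mapping[str, str], Sequence]) -> List[str]:
    if isinstance(labels, Mapping):
        missing = [e.study_id for e in effects if e.study_id not in labels]
        if missing:
            raise ValueError(f"covariate value missing for studies: {missing}")
        return [str(labels[e.study_id]) for e in effects]
    if len(labels) != len(effects):
        raise ValueError("labels sequence must match effects")
    return [str(l) for l in labels]


def subgroup_analysis(effects: Sequence[EffectSize],
                      labels: Union[Mapping[str, str], Sequence],
                      covariate: str = "covariate",
                      scheme: str = "random", tau2_method: str = "DL",
                      alpha: float = 0.05) -> SubgroupResult:
    """Decompose heterogeneity by a categorical covariate.

    Parameters
    ----------
    labels
        Either a mapping study_id -> group label or a sequence aligned
        with ``effects``.
    scheme, tau2_method
        Control how each subgroup's pooled estimate is computed; the Q
        decomposition itself always uses fixed-effect weights.
    """
    labs = _labels_for(effects, labels)
    levels = sorted(set(labs))
    if len(levels) < 2:
        raise ValueError("subgroup analysis needs at least 2 groups "
                         f"(covariate {covariate!r} has a single level)")
    theta = np.array([e.theta for e in effects])
    se = np.array([e.se for e in effects])
    _, _, Q_total = fixed_effect_summary(theta, se)
    N, S = len(effects), len(levels)

    Q_within = 0.0
    sum_df = 0
    sum_c = 0.0
    groups: Dict[str, Tuple[PooledEstimate, Optional[HeterogeneityReport], int]] = {}
    for lev in levels:
        idx = [i for i, l in enumerate(labs) if l == lev]
        sub = [effects[i] for i in idx]
        th_j, se_j = theta[idx], se[idx]
        w_j = 1.0 / se_j ** 2
        _, _, Q_j = fixed_effect_summary(th_j, se_j)
        Q_within += Q_j
        sum_df += len(sub) - 1
        sum_c += float(np.sum(w_j) - np.sum(w_j ** 2) / np.sum(w_j))
        est = pool(sub, scheme=scheme, tau2_method=tau2_method, alpha=alpha)
        het = heterogeneity(sub, alpha=alpha) if len(sub) >= 2 else None
        if len(sub) == 1:
            logger.warning("subgroup %r contains a single study", lev)
        groups[lev] = (est, het, len(sub))

    Q_between = Q_total - Q_within
    p_between = float(stats.chi2.sf(Q_between, S - 1))
    p_within = float(stats.chi2.sf(Q_within, N - S)) if N - S > 0 else 1.0

    tau2_within = max(0.0, (Q_within - sum_df) / sum_c) if sum_c > 0 else 0.0
    tau2_total = estimate_tau2(effects, tau2_method)
    if tau2_total > 0:
        r2_raw = (1.0 - tau2_within / tau2_total) * 100.0
    else:
        r2_raw = 0.0
    r2 = min(100.0, max(0.0, r2_raw))
    if r2_raw < 0:
        logger.info("R2_explained %.2f%% truncated to 0 (sampling noise)", r2_raw)

    return SubgroupResult(covariate=covariate, groups=groups, Q_total=Q_total,
                          Q_between=Q_between, Q_within=Q_within,
                          p_between=p_between, p_within=p_within,
                          tau2_within=tau2_within, tau2_total=tau2_total,
                          R2_explained=r2, R2_raw=r2_raw)


def bonferroni(alpha: float, m: int) -> float:
    """Adjusted significance threshold alpha* = alpha / m for m comparisons.

    Downstream confidence intervals are built with the critical value at
    alpha* in place of alpha.
    """
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m
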