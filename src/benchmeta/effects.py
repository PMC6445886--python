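"""Study-level effect sizes and log10 forward/back transformation.

Four effect-size measures are supported:

* ``absolute`` — mean outcome, or mean difference when a control arm is
  reported;
* ``standardized`` — Hedges' g, the mean difference in pooled-sd units
  with the small-sample correction factor 1 - 3/(4(nc+nr) - 9);
* ``normalized`` — percent difference from baseline, (tr - ctrl)/ctrl;
* ``ratio`` — response ratio tr/ctrl.

Skewed raw-scale data can be synthesized on the log10 scale: the forward
transform maps (theta, se) to (Theta, se(Theta)) assuming lognormality,
and three back-transformations (geometric, naive, taylor) return pooled
log-scale results to the raw scale, the geometric one with asymmetric
confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats

from .datatypes import Dataset, EffectSize, LogEffect, StudyRecord

logger = logging.getLogger(__name__)

__all__ = [
    "effect_size",
    "effects_from_dataset",
    "to_log",
    "from_log",
    "BackTransformed",
    "aggregate_common_outcomes",
    "MEASURES",
]

MEASURES = ("absolute", "standardized", "normalized", "ratio")


def _pooled_sd(r: StudyRecord) -> float:
    """Pooled standard deviation across the two arms."""
    num = (r.n_control - 1) * r.sd_control ** 2 + (r.n_treatment - 1) * r.sd_treatment ** 2
    return math.sqrt(num / (r.n_control + r.n_treatment - 2))


def effect_size(record: StudyRecord, measure: str = "absolute",
                scale: str = "raw") -> EffectSize:
    """Compute the study-level effect size theta_i and its standard error.

    Parameters
    ----------
    record
        The study's reported arms.
    measure
        One of ``absolute``, ``standardized``, ``normalized``, ``ratio``.
        All but control-free ``absolute`` require a control arm.

    Raises
    ------
    ValueError
        Missing control arm for a comparative measure, zero control mean
        for normalized/ratio measures, or per-arm n < 2 for the
        standardized measure (pooled sd undefined).
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    r = record
    nr = r.n_treatment

    if measure == "absolute":
        if not r.has_control:
            theta = r.mean_treatment
            se = r.sd_treatment / math.sqrt(nr)
            return EffectSize(r.study_id, theta, se, nr, measure, scale)
        nc = r.n_control
        if nr < 2 or nc < 2:
            raise ValueError(
                f"study {r.study_id!r}: absolute difference needs n >= 2 per arm "
                "for the pooled sd")
        sd_p = _pooled_sd(r)
        theta = r.mean_treatment - r.mean_control
        se = math.sqrt((nc + nr) / (nc * nr)) * sd_p
        return EffectSize(r.study_id, theta, se, nr + nc, measure, scale)

    if not r.has_control:
        raise ValueError(f"study {r.study_id!r}: measure {measure!r} requires a control arm")
    nc = r.n_control

    if measure == "standardized":
        if nr < 2 or nc < 2:
            raise ValueError(
                f"study {r.study_id!r}: standardized measure needs n >= 2 per arm")
        sd_p = _pooled_sd(r)
        if sd_p == 0:
            raise ValueError(f"study {r.study_id!r}: zero pooled sd")
        correction = 1.0 - 3.0 / (4.0 * (nc + nr) - 9.0)
        theta = (r.mean_treatment - r.mean_control) / sd_p * correction
        se = math.sqrt((nc + nr) / (nc * nr) + theta ** 2 / (2.0 * ((nc + nr) - 3.94)))
        return EffectSize(r.study_id, theta, se, nr + nc, measure, scale)

    if r.mean_control == 0:
        raise ValueError(
            f"study {r.study_id!r}: control mean is zero; {measure} measure undefined")

    if measure == "normalized":
        theta = (r.mean_treatment - r.mean_control) / r.mean_control
        if r.mean_treatment == 0:
            raise ValueError(
                f"study {r.study_id!r}: treatment mean is zero; normalized se undefined")
        se = math.sqrt((r.sd_control / r.mean_control) ** 2 / nc
                       + (r.sd_treatment / r.mean_treatment) ** 2 / nr)
        return EffectSize(r.study_id, theta, se, nr + nc, measure, scale)

    # ratio
    theta = r.mean_treatment / r.mean_control
    var = (r.mean_treatment ** 2 / r.mean_control ** 2) * (
        r.sd_treatment ** 2 / (nr * r.mean_treatment ** 2)
        + r.sd_control ** 2 / (nc * r.mean_control ** 2))
    return EffectSize(r.study_id, theta, math.sqrt(var), nr + nc, measure, scale)


def effects_from_dataset(dataset: Dataset, measure: str = "absolute") -> List[EffectSize]:
    """Vector convenience: one EffectSize per record, inheriting the scale."""
    return [effect_size(r, measure, scale=dataset.scale) for r in dataset]


def to_log(effect: EffectSize) -> LogEffect:
    """Forward log10 transform of a raw-scale effect.

    Assuming the outcome is lognormal, se(Theta) = sqrt(log10(cv^2 + 1))
    with cv = se/theta, and Theta = log10(theta) - se(Theta)^2 / 2.
    Requires theta > 0.
    """
    if effect.theta <= 0:
        raise ValueError(f"study {effect.study_id!r}: log transform needs theta > 0")
    se_log = math.sqrt(math.log10(effect.se ** 2 / effect.theta ** 2 + 1.0))
    Theta = math.log10(effect.theta) - se_log ** 2 / 2.0
    return LogEffect(study_id=effect.study_id, Theta=Theta, se_log=se_log)


@dataclass
class BackTransformed:
    """Raw-scale point estimate, se and CI recovered from the log10 scale."""

    theta_hat: float
    se: float
    ci: Tuple[float, float]
    method: str
    #: conventions used for the naive/taylor forms (see docs/methods.md)
    n_ref: Optional[int] = None


def from_log(Theta_hat: float, se_hat: float, n_ref: int = 1,
             method: str = "geometric", alpha: float = 0.05,
             critical_value: Optional[float] = None) -> BackTransformed:
    """Back-transform a pooled log10-scale estimate to the raw scale.

    Methods
    -------
    geometric
        theta = 10^Theta (approximates the median); asymmetric CI
        10^(Theta +/- v se); se recovered from the CI width as
        (hi - lo)/(2v).
    naive
        theta = 10^(Theta + se^2/2);
        se = sqrt((10^(se^2) - 1) 10^(2 Theta + se^2) / n_ref).
    taylor
        Same point estimate; se = sqrt(10^(2 Theta + se^2) se^2
        (1 + se^2/2) / n_ref).

    The naive/taylor forms use sd(Theta_hat) = ``se_hat`` and a 1/sqrt(n)
    factor with n = ``n_ref`` (the pooled total sample size when applied
    at the meta-analytic level).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_ref < 1:
        raise ValueError("n_ref must be >= 1")
    v = critical_value if critical_value is not None else stats.norm.ppf(1 - alpha / 2)
    sd2 = se_hat ** 2

    if method == "geometric":
        theta = 10.0 ** Theta_hat
        lo = 10.0 ** (Theta_hat - v * se_hat)
        hi = 10.0 ** (Theta_hat + v * se_hat)
        se = (hi - lo) / (2.0 * v)
        return BackTransformed(theta, se, (lo, hi), method, n_ref)

    if method == "naive":
        theta = 10.0 ** (Theta_hat + sd2 / 2.0)
        se = math.sqrt((10.0 ** sd2 - 1.0) * 10.0 ** (2.0 * Theta_hat + sd2) / n_ref)
    elif method == "taylor":
        theta = 10.0 ** (Theta_hat + sd2 / 2.0)
        se = math.sqrt(10.0 ** (2.0 * Theta_hat + sd2) * sd2 * (1.0 + sd2 / 2.0) / n_ref)
    else:
        raise ValueError(f"unknown back-transformation method {method!r}")
    lo, hi = theta - v * se, theta + v * se
    return BackTransformed(theta, se, (lo, hi), method, n_ref)


def aggregate_common_outcomes(dataset: Dataset, key: str) -> Dataset:
    """Pool multiple reports of a common outcome within one study.

    Records sharing the same value of covariate ``key`` are merged by the
    sample-size-weighted mean; the merged sd is the n-weighted
    root-mean-square of the arm sds and n values are summed. Control arms
    are merged the same way when all members report them.
    """
    groups: dict = {}
    order: list = []
    for r in dataset:
        g = r.covariates.get(key, r.study_id)
        if g not in groups:
            groups[g] = []
            order.append(g)
        groups[g].append(r)

    merged = []
    for g in order:
        members = groups[g]
        if len(members) == 1:
            merged.append(members[0])
            continue
        n = np.array([m.n_treatment for m in members], dtype=float)
        mean = float(np.average([m.mean_treatment for m in members], weights=n))
        sd = float(np.sqrt(np.average([m.sd_treatment ** 2 for m in members], weights=n)))
        rec = dict(study_id=str(g), mean_treatment=mean, sd_treatment=sd,
                   n_treatment=int(n.sum()),
                   covariates={key: g}, quality=members[0].quality)
        if all(m.has_control for m in members):
            ncv = np.array([m.n_control for m in members], dtype=float)
            rec["mean_control"] = float(
                np.average([m.mean_control for m in members], weights=ncv))
            rec["sd_control"] = float(
                np.sqrt(np.average([m.sd_control ** 2 for m in members], weights=ncv)))
            rec["n_control"] = int(ncv.sum())
        merged.append(StudyRecord(**rec))
    return Dataset(records=merged, label=dataset.label, scale=dataset.scale)
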