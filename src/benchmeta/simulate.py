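"""Synthetic study-level data generators with known ground truth.

Every analysis in the toolbox can be exercised without any external
dataset: the generators draw study sets from the random-effects model
(per-study true effect mu_i ~ N(mu, tau2), observed effect
theta_i ~ N(mu_i, se_i^2)), optionally with subgroup shifts, regression
covariates, a lognormal raw scale, or dose-response curves for the
Monte-Carlo fitting module. Reported sd and n are consistent with the
generative se (sd = se * sqrt(n)); n and se are drawn independently by
default so that the sd^2-vs-n diagnostic sees its null, unless
``confound_sd_n`` is set to emulate unreliable uncertainty reporting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .datatypes import CurveDataset, Dataset, ModelSpec, StudyRecord
from .modelfit import get_model

logger = logging.getLogger(__name__)

__all__ = ["SimulationSpec", "simulate_meta_dataset", "simulate_subgrouped",
           "simulate_regression_dataset", "simulate_dose_response"]


@dataclass
class SimulationSpec:
    """Generative conditions for a synthetic meta-analytic dataset.

    Defaults mirror a well-behaved mid-sized basic-research meta-analysis:
    a mean effect of 1 with moderate between-study variance (tau2 = 0.25),
    per-study standard errors uniform on (0.1, 0.5) and sample sizes of
    3-12 independent experiments per study.
    """

    mu: float = 1.0
    tau2: float = 0.25
    N: int = 20
    se_dist: Tuple[float, float] = (0.1, 0.5)
    n_dist: Tuple[int, int] = (3, 12)
    distribution: str = "normal"  # normal | lognormal
    confound_sd_n: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not (0 < self.se_dist[0] <= self.se_dist[1]):
            raise ValueError("se_dist must be a positive (low, high) range")
        if not (1 <= self.n_dist[0] <= self.n_dist[1]):
            raise ValueError("n_dist must be an integer range with low >= 1")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError("distribution must be 'normal' or 'lognormal'")


def _draw_records(spec: SimulationSpec, rng: np.random.Generator,
                  mu_shift: Optional[np.ndarray] = None,
                  covariates: Optional[Sequence[Mapping]] = None,
                  id_offset: int = 0):
    shift = np.zeros(spec.N) if mu_shift is None else np.asarray(mu_shift, dtype=float)
    se = rng.uniform(spec.se_dist[0], spec.se_dist[1], size=spec.N)
    n = rng.integers(spec.n_dist[0], spec.n_dist[1] + 1, size=spec.N)
    if spec.confound_sd_n:
        # unreliable reporting: make sd^2 grow with n, keeping se = sd/sqrt(n)
        sd = np.sqrt(0.1 * n) * rng.uniform(0.8, 1.2, size=spec.N)
        se = sd / np.sqrt(n)
    mu_i = rng.normal(spec.mu + shift, math.sqrt(spec.tau2), size=spec.N)
    theta = rng.normal(mu_i, se)
    records = []
    for i in range(spec.N):
        sd_i = se[i] * math.sqrt(n[i])
        mean_i, sd_rep = float(theta[i]), float(sd_i)
        if spec.distribution == "lognormal":
            mean_raw = 10.0 ** theta[i]
            sd_rep = float(math.log(10.0) * mean_raw * sd_i)  # delta method
            mean_i = float(mean_raw)
        covs = dict(covariates[i]) if covariates is not None else {}
        records.append(StudyRecord(
            study_id=f"S{id_offset + i + 1:04d}", mean_treatment=mean_i,
            sd_treatment=sd_rep, n_treatment=int(n[i]), covariates=covs))
    return records


def simulate_meta_dataset(spec: SimulationSpec) -> Dataset:
    """Draw one study set from the random-effects model.

    In lognormal mode the normal draws are taken to live on the log10
    scale and are exponentiated, producing positively skewed raw-scale
    data; the reported sd is mapped to the raw scale by the delta method.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    records = _draw_records(spec, rng)
    return Dataset(records=records, label="simulated", scale="raw")


def simulate_subgrouped(spec: SimulationSpec,
                        group_offsets: Mapping[str, float],
                        covariate: str = "group") -> Dataset:
    """Random-effects studies with group-shifted means.

    Group g's true mean is mu + offset_g; studies are split as evenly as
    possible across groups and carry the group label as a categorical
    covariate. Single-study groups are generated but flagged.
    """
    if len(group_offsets) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(spec.seed)
    labels = sorted(group_offsets)
    sizes = np.full(len(labels), spec.N // len(labels))
    sizes[:spec.N % len(labels)] += 1
    if np.any(sizes == 0):
        raise ValueError("empty group: N too small for the number of groups")
    if np.any(sizes == 1):
        logger.warning("subgroup with a single study generated")
    assign = np.repeat(np.arange(len(labels)), sizes)
    shift = np.array([group_offsets[labels[a]] for a in assign])
    covs = [{covariate: labels[a]} for a in assign]
    records = _draw_records(spec, rng, mu_shift=shift, covariates=covs)
    return Dataset(records=records, label="simulated-subgroups", scale="raw")


def simulate_regression_dataset(spec: SimulationSpec, slope: float,
                                x_range: Tuple[float, float] = (0.0, 1.0),
                                covariate: str = "x") -> Dataset:
    """Random-effects studies whose true means follow mu + slope * x_i."""
    rng = np.random.default_rng(spec.seed)
    x = rng.uniform(x_range[0], x_range[1], size=spec.N)
    covs = [{covariate: float(v)} for v in x]
    records = _draw_records(spec, rng, mu_shift=slope * x, covariates=covs)
    return Dataset(records=records, label="simulated-regression", scale="raw")


def simulate_dose_response(spec_model, beta_true: Sequence[float],
                           x_levels: Sequence[float], sd, n,
                           seed: int = 0) -> CurveDataset:
    """Per-level curve data theta_j = f(x_j, beta) + noise.

    The reported sd is the generative per-observation sd; the noise on
    the reported mean theta_j therefore has standard deviation
    sd_j/sqrt(n_j), consistent with theta_j being an n_j-observation
    average.
    """
    spec = get_model(spec_model) if isinstance(spec_model, str) else spec_model
    x = np.asarray(x_levels, dtype=float)
    if len(x) < spec.n_params:
        raise ValueError(f"need at least {spec.n_params} x levels for "
                         f"model {spec.model_id!r}")
    sd = np.broadcast_to(np.asarray(sd, dtype=float), x.shape).copy()
    n = np.broadcast_to(np.asarray(n, dtype=int), x.shape).copy()
    rng = np.random.default_rng(seed)
    clean = np.asarray(spec.func(x, *beta_true), dtype=float)
    theta = clean + rng.normal(0.0, sd / np.sqrt(n))
    return CurveDataset(x=x, theta=theta, sd=sd, n=n)
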