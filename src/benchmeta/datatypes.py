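"""Core domain types shared across the toolbox.

The central objects mirror how study-level evidence is reported in basic
research: per-study means, standard deviations and sample sizes for an
intervention arm and an optional control arm (:class:`StudyRecord`), the
derived per-study effect sizes (:class:`EffectSize`), and the pooled
summary (:class:`PooledEstimate`) with its heterogeneity companion
(:class:`HeterogeneityReport`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "StudyRecord",
    "Dataset",
    "QualityScore",
    "EffectSize",
    "LogEffect",
    "PooledEstimate",
    "HeterogeneityReport",
    "CoverageResult",
    "WeightedHistogram",
    "CurveDataset",
    "ModelSpec",
    "ModelFitResult",
]

N_QUALITY_ITEMS = 8


@dataclass
class StudyRecord:
    """One study's reported arms, covariates and quality checklist.

    The treatment arm (mean, sd, n) is mandatory; the control arm is
    all-or-none. ``quality`` is an ordered checklist of exactly eight
    booleans (peer review, complete statistics, randomization, blinding,
    a-priori power, dose-response, regulatory compliance, objective
    alignment with the review question).
    """

    study_id: str
    mean_treatment: float
    sd_treatment: float
    n_treatment: int
    mean_control: Optional[float] = None
    sd_control: Optional[float] = None
    n_control: Optional[int] = None
    covariates: Mapping[str, Any] = field(default_factory=dict)
    quality: Sequence[bool] = field(default_factory=lambda: [True] * N_QUALITY_ITEMS)

    def __post_init__(self) -> None:
        if self.n_treatment < 1:
            raise ValueError(
                f"study {self.study_id!r}: n_treatment must be >= 1, got {self.n_treatment}"
            )
        if self.sd_treatment < 0:
            raise ValueError(f"study {self.study_id!r}: sd_treatment must be >= 0")
        ctrl = (self.mean_control, self.sd_control, self.n_control)
        present = [c is not None for c in ctrl]
        if any(present) and not all(present):
            raise ValueError(
                f"study {self.study_id!r}: partial control arm "
                "(mean_control, sd_control, n_control must all be present or all absent)"
            )
        if self.has_control:
            if self.n_control < 1:
                raise ValueError(f"study {self.study_id!r}: n_control must be >= 1")
            if self.sd_control < 0:
                raise ValueError(f"study {self.study_id!r}: sd_control must be >= 0")
        if len(self.quality) != N_QUALITY_ITEMS:
            raise ValueError(
                f"study {self.study_id!r}: quality checklist must have exactly "
                f"{N_QUALITY_ITEMS} entries, got {len(self.quality)}"
            )

    @property
    def has_control(self) -> bool:
        return self.mean_control is not None


@dataclass
class Dataset:
    """Ordered collection of :class:`StudyRecord` with a scale tag."""

    records: Sequence[StudyRecord]
    label: str = ""
    scale: str = "raw"  # raw | log10

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValueError("Dataset must contain at least one record")
        ids = [r.study_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate study_ids: {dupes}")
        if self.scale not in ("raw", "log10"):
            raise ValueError(f"scale must be 'raw' or 'log10', got {self.scale!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class QualityScore:
    """Aggregate quality score: the count of satisfied checklist items."""

    study_id: str
    score: int

    def __post_init__(self) -> None:
        if not 0 <= self.score <= N_QUALITY_ITEMS:
            raise ValueError(f"score must be in 0..{N_QUALITY_ITEMS}")


@dataclass
class EffectSize:
    """Study-level effect size theta_i with its standard error.

    ``measure`` is one of absolute, standardized (Hedges' g), normalized
    (percent difference) or ratio (response ratio); ``scale`` tracks
    whether the value lives on the raw or log10 scale.
    """

    study_id: str
    theta: float
    se: float
    n_total: int
    measure: str = "absolute"
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError(f"study {self.study_id!r}: se must be >= 0")
        if self.n_total < 1:
            raise ValueError(f"study {self.study_id!r}: n_total must be >= 1")


@dataclass
class LogEffect:
    """Effect size on the log10 scale (capital Theta convention)."""

    study_id: str
    Theta: float
    se_log: float

    def __post_init__(self) -> None:
        if self.se_log < 0:
            raise ValueError("se_log must be >= 0")


@dataclass
class PooledEstimate:
    """Global (pooled) effect with CI, weights and model metadata.

    Under the fixed-effect scheme ``theta_hat`` estimates the single true
    effect gamma; under random effects it estimates the mean mu of the
    distribution of true effects, whose variance is ``tau2``. The model
    contract is theta_i = mu_i + eps_i with eps_i ~ N(0, se_i^2) within
    studies and mu_i ~ N(mu, tau2) between studies.
    """

    theta_hat: float
    se_hat: float
    ci: Tuple[float, float]
    weights: np.ndarray
    tau2: float
    scheme: str
    alpha: float
    critical_value: float
    dist: str
    n_studies: int
    tau2_method: Optional[str] = None
    scale: str = "raw"

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo - 1e-12 <= self.theta_hat <= hi + 1e-12):
            raise ValueError("CI must bracket theta_hat")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")


@dataclass
class HeterogeneityReport:
    """Q / H^2 / I^2 heterogeneity summary plus the tau^2 estimator suite."""

    Q: float
    df: int
    p: float
    H2: float
    H2_ci: Optional[Tuple[float, float]]
    I2: float
    I2_ci: Optional[Tuple[float, float]]
    tau2_by_estimator: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.H2 < 1:
            raise ValueError("H2 is truncated at 1")
        if not 0 <= self.I2 < 100 + 1e-9:
            raise ValueError("I2 must lie in [0, 100)")


@dataclass
class CoverageResult:
    """Proportion of study-level CIs overlapping the pooled CI."""

    covered: int
    total: int
    proportion: float

    def __post_init__(self) -> None:
        if self.covered > self.total:
            raise ValueError("covered cannot exceed total")


@dataclass
class WeightedHistogram:
    """Weight-normalized effect-size histogram (frequencies sum to 1)."""

    bin_edges: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.P)) - 1.0) > 1e-12:
            raise ValueError("weighted frequencies must sum to 1")


@dataclass
class CurveDataset:
    """Per-level summary data (x_j, theta_j, sd_j, n_j) for curve fitting."""

    x: np.ndarray
    theta: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        k = len(self.x)
        if not (len(self.theta) == len(self.sd) == len(self.n) == k):
            raise ValueError("x, theta, sd, n must have equal length")
        if np.any(self.sd < 0):
            raise ValueError("sd must be >= 0")
        if np.any(self.n < 1):
            raise ValueError("n must be >= 1")

    @property
    def k(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class ModelSpec:
    """A named input-output model y = f(x, beta) with initializer."""

    model_id: str
    func: Any
    n_params: int
    param_names: Tuple[str, ...]
    initializer: Any

    def __post_init__(self) -> None:
        if len(self.param_names) != self.n_params:
            raise ValueError("param_names length must equal n_params")


@dataclass
class ModelFitResult:
    """Monte-Carlo error-propagation fit summary.

    ``draws`` holds one row of parameter estimates per converged
    iteration; ``beta_mean``/``beta_sd`` summarize that distribution.
    """

    model_id: str
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    draws: np.ndarray
    M: int
    converged_fraction: float
    r2: Optional[float] = None
    normality_flags: Optional[Sequence[bool]] = None

    def __post_init__(self) -> None:
        if self.draws.shape[0] > self.M:
            raise ValueError("cannot have more converged draws than iterations")
        if not np.all(np.isfinite(self.beta_mean)):
            raise ValueError("beta_mean must be finite")
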