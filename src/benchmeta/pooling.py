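"""Pooling, between-study variance estimation and heterogeneity statistics.

Model
-----
Study i reports theta_i with standard error se_i. Under the fixed-effect
model every study samples one true effect gamma (theta_i = gamma + eps_i,
eps_i ~ N(0, se_i^2)); under random effects each study samples its own
true effect mu_i ~ N(mu, tau2) so that theta_i = mu_i + eps_i. The pooled
estimate is the weighted mean

    theta_hat = sum(w_i theta_i) / sum(w_i)

with w_i = 1/se_i^2 (fixed), 1/(se_i^2 + tau2) (random), n_i
(sample-size weighting), or equal (unweighted), and
se(theta_hat) = 1/sqrt(sum w_i) for the inverse-variance schemes.

tau2 estimators
---------------
Six method-of-moments/iterative estimators of the between-study variance
are provided: DerSimonian-Laird (DL), Hunter-Schmidt (HS), Hedges (H),
Hartung-Makambi (HM), Sidik-Jonkman (SJ) and the iterative Paule-Mandel
(PM). Negative estimates are truncated at zero.

Heterogeneity
-------------
Cochran's Q (fixed-effect weights) feeds the magnitude measures
H^2 = Q/df (truncated below at 1) and I^2 = (H^2 - 1)/H^2 * 100%, each
with large-sample confidence intervals on the ln(H) scale.
"""

from __future__ import annotations

import logging
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .datatypes import (CoverageResult, EffectSize, HeterogeneityReport,
                        PooledEstimate, StudyRecord, WeightedHistogram)

logger = logging.getLogger(__name__)

__all__ = [
    "critical_value",
    "estimate_tau2",
    "pool",
    "heterogeneity",
    "coverage",
    "weighted_histogram",
    "weighting_diagnostic",
    "fixed_effect_summary",
    "TAU2_METHODS",
    "SCHEMES",
]

TAU2_METHODS = ("DL", "HS", "H", "HM", "SJ", "PM")
SCHEMES = ("fixed", "random", "sample_size", "unweighted")


def critical_value(alpha: float, n_studies: int, dist: str = "z") -> float:
    """Two-sided critical value v_{1-alpha/2} from the z or t distribution.

    The t distribution uses df = N - 1 and is the conservative choice for
    small meta-analyses; it converges to z as N grows (e.g. at alpha=0.05:
    2.78 for N=5, 2.26 for N=10, 2.05 for N=30, 1.98 for N=100 vs z=1.96).
    ``dist='auto'`` selects t below 30 studies and z otherwise.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if dist == "auto":
        dist = "t" if n_studies < 30 else "z"
    if dist == "z":
        return float(stats.norm.ppf(1 - alpha / 2))
    if dist == "t":
        if n_studies < 2:
            raise ValueError("t critical value requires at least 2 studies")
        return float(stats.t.ppf(1 - alpha / 2, df=n_studies - 1))
    raise ValueError(f"unknown distribution {dist!r}; expected 'z', 't' or 'auto'")


def _arrays(effects: Sequence[EffectSize]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = np.array([e.theta for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    n = np.array([e.n_total for e in effects], dtype=float)
    return theta, se, n


def _check_scale(effects: Sequence[EffectSize]) -> str:
    scales = {e.scale for e in effects}
    if len(scales) > 1:
        raise ValueError(f"effects mix scales {sorted(scales)}")
    return scales.pop() if scales else "raw"


def fixed_effect_summary(theta: np.ndarray, se: np.ndarray
                         ) -> Tuple[np.ndarray, float, float]:
    """Fixed-effect weights, estimate and Cochran's Q for raw arrays."""
    if np.any(se <= 0):
        raise ValueError("fixed-effect weights require strictly positive se")
    w = 1.0 / se ** 2
    theta_fe = float(np.sum(w * theta) / np.sum(w))
    Q = float(np.sum(w * (theta - theta_fe) ** 2))
    return w, theta_fe, Q


def estimate_tau2(effects: Sequence[EffectSize], method: str = "DL") -> float:
    """Estimate the between-study variance tau^2.

    All estimators are truncated at zero. ``PM`` solves
    sum w_i(tau2) (theta_i - theta_hat(tau2))^2 = N - 1 by bisection
    (tolerance 1e-8, at most 200 iterations).
    """
    if method not in TAU2_METHODS:
        raise ValueError(f"unknown tau2 method {method!r}; expected one of {TAU2_METHODS}")
    if len(effects) < 2:
        raise ValueError("tau2 estimation requires at least 2 studies")
    theta, se, _ = _arrays(effects)
    if np.any(se <= 0):
        raise ValueError("tau2 estimation requires positive se for every study")
    N = len(theta)
    w, theta_fe, Q = fixed_effect_summary(theta, se)
    c = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))

    if method == "DL":
        tau2 = (Q - (N - 1)) / c
    elif method == "HS":
        tau2 = (Q - N) / float(np.sum(w))
    elif method == "H":
        # variance-component form: sample variance of theta minus the
        # mean within-study variance
        tau2 = float(np.var(theta, ddof=1) - np.mean(se ** 2))
    elif method == "HM":
        tau2 = Q ** 2 / ((2.0 * (N - 1) + Q) * c)
    elif method == "SJ":
        theta_bar = float(np.mean(theta))
        tau0 = float(np.sum((theta - theta_bar) ** 2) / N)
        if tau0 == 0:
            return 0.0
        v = se ** 2 / tau0 + 1.0
        wv = 1.0 / v
        theta_v = float(np.sum(wv * theta) / np.sum(wv))
        tau2 = float(np.sum(wv * (theta - theta_v) ** 2) / (N - 1))
    else:  # PM
        df = N - 1

        def q_gen(t2: float) -> float:
            wt = 1.0 / (se ** 2 + t2)
            th = np.sum(wt * theta) / np.sum(wt)
            return float(np.sum(wt * (theta - th) ** 2))

        if q_gen(0.0) <= df:
            return 0.0
        lo, hi = 0.0, 10.0 * float(np.max(se ** 2)) + float(np.var(theta)) + 1e-12
        while q_gen(hi) > df:  # widen until the root is bracketed
            hi *= 2.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if abs(q_gen(mid) - df) < 1e-8:
                return mid
            if q_gen(mid) > df:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    return max(0.0, float(tau2))


def pool(effects: Sequence[EffectSize], scheme: str = "random",
         tau2_method: str = "DL", alpha: float = 0.05, dist: str = "auto",
         tau2: Optional[float] = None) -> PooledEstimate:
    """Pool study-level effects into a global estimate with CI.

    Parameters
    ----------
    scheme
        ``fixed`` | ``random`` | ``sample_size`` | ``unweighted``.
    tau2
        Override for the between-study variance (random scheme); when
        omitted it is estimated with ``tau2_method``.
    dist
        ``z``, ``t`` or ``auto`` (t below 30 studies).

    Notes
    -----
    For the sample-size scheme the pooled standard error pools the
    study-level variances with weights (n_i - 1):
    se = sqrt(sum se_i^2 (n_i - 1) / sum (n_i - 1)). For the unweighted
    scheme se = sd(theta_i)/sqrt(N).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if len(effects) == 0:
        raise ValueError("cannot pool an empty set of effects")
    scale = _check_scale(effects)
    theta, se, n = _arrays(effects)
    N = len(theta)

    if N == 1:
        v = critical_value(alpha, N, "z" if dist in ("auto", "t") else dist)
        if dist in ("auto", "t"):
            logger.warning("single study: falling back to z critical value")
        th, s = float(theta[0]), float(se[0])
        return PooledEstimate(th, s, (th - v * s, th + v * s),
                             np.ones(1), 0.0, scheme, alpha, v,
                             "z" if dist in ("auto", "t") else dist, 1,
                             tau2_method if scheme == "random" else None, scale)

    t2 = 0.0
    if scheme in ("fixed", "random"):
        if np.any(se <= 0):
            raise ValueError("inverse-variance weighting requires positive se "
                             "for every study (zero se implies infinite weight)")
        if scheme == "random":
            t2 = float(tau2) if tau2 is not None else estimate_tau2(effects, tau2_method)
            if t2 < 0:
                raise ValueError("tau2 must be >= 0")
        w = 1.0 / (se ** 2 + t2)
        se_hat = 1.0 / math.sqrt(float(np.sum(w)))
    elif scheme == "sample_size":
        w = n.copy()
        dofs = n - 1.0
        if np.sum(dofs) <= 0:
            raise ValueError("sample-size pooled se requires some n_i > 1")
        se_hat = math.sqrt(float(np.sum(se ** 2 * dofs) / np.sum(dofs)))
    else:  # unweighted
        w = np.ones(N)
        se_hat = float(np.std(theta, ddof=1) / math.sqrt(N))

    theta_hat = float(np.sum(w * theta) / np.sum(w))
    if dist == "auto":
        dist = "t" if N < 30 else "z"
    v = critical_value(alpha, N, dist)
    ci = (theta_hat - v * se_hat, theta_hat + v * se_hat)
    return PooledEstimate(theta_hat, se_hat, ci, w, t2, scheme, alpha, v,
                          dist, N, tau2_method if scheme == "random" else None,
                          scale)


def heterogeneity(effects: Sequence[EffectSize], alpha: float = 0.05
                  ) -> HeterogeneityReport:
    """Quantify between-study heterogeneity (Q, H^2, I^2, tau^2 suite).

    Q uses fixed-effect weights and is referred to chi^2 with df = N - 1.
    H^2 = Q/df, truncated below at 1; its CI exponentiates
    ln(H) +/- z * sqrt((1/(2(df-1))) (1 - 1/(3 df^2))) and squares the
    bounds (undefined for df = 1, reported as None with a warning).
    I^2 = (H^2 - 1)/H^2 * 100 with its CI mapped from the H^2 CI and
    floored at 0.
    """
    if len(effects) < 2:
        raise ValueError("heterogeneity requires at least 2 studies")
    theta, se, _ = _arrays(effects)
    _, _, Q = fixed_effect_summary(theta, se)
    N = len(theta)
    df = N - 1
    p = float(stats.chi2.sf(Q, df))
    H2 = max(1.0, Q / df)
    I2 = (H2 - 1.0) / H2 * 100.0

    H2_ci = I2_ci = None
    if df >= 2:
        z = stats.norm.ppf(1 - alpha / 2)
        se_lnH = math.sqrt((1.0 / (2.0 * (df - 1))) * (1.0 - 1.0 / (3.0 * df ** 2)))
        lnH = 0.5 * math.log(max(Q / df, 1e-300))
        lo = max(1.0, math.exp(lnH - z * se_lnH) ** 2)
        hi = max(1.0, math.exp(lnH + z * se_lnH) ** 2)
        H2_ci = (lo, hi)
        I2_ci = ((lo - 1.0) / lo * 100.0, (hi - 1.0) / hi * 100.0)
    else:
        logger.warning("H2/I2 confidence intervals undefined for df = 1")

    tau2_map = {m: estimate_tau2(effects, m) for m in TAU2_METHODS}
    return HeterogeneityReport(Q=Q, df=df, p=p, H2=H2, H2_ci=H2_ci,
                               I2=I2, I2_ci=I2_ci, tau2_by_estimator=tau2_map)


def coverage(effects: Sequence[EffectSize], pooled: PooledEstimate,
             alpha: float = 0.05) -> CoverageResult:
    """Proportion of study-level CIs that overlap the pooled CI.

    Study i is covered iff |theta_hat - theta_i| <= v se(theta_hat)
    + v se(theta_i). Coverage well below 1 - alpha flags inconsistency
    between study-level and meta-analytic inference.
    """
    scale = _check_scale(effects)
    if scale != pooled.scale:
        raise ValueError(
            f"scale mismatch: effects on {scale!r}, pooled estimate on {pooled.scale!r}")
    theta, se, _ = _arrays(effects)
    v = critical_value(alpha, len(theta), pooled.dist)
    dist = np.abs(pooled.theta_hat - theta)
    covered = int(np.sum(dist <= v * pooled.se_hat + v * se))
    return CoverageResult(covered=covered, total=len(theta),
                          proportion=covered / len(theta))


def weighted_histogram(effects: Sequence[EffectSize],
                       weights: Sequence[float],
                       n_bins: Optional[int] = None) -> WeightedHistogram:
    """Weight-normalized histogram of study-level effects.

    Each bin's frequency is the sum of the weights of the studies falling
    in it, normalized by the total weight, so the frequencies sum to 1.
    The default bin count follows the Freedman-Diaconis rule on the
    unweighted effects.
    """
    theta, _, _ = _arrays(effects)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(theta):
        raise ValueError("weights must match effects")
    if np.any(w < 0) or np.sum(w) <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    if n_bins is None:
        edges = np.histogram_bin_edges(theta, bins="fd")
    else:
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        edges = np.histogram_bin_edges(theta, bins=n_bins)
    counts, edges = np.histogram(theta, bins=edges, weights=w)
    return WeightedHistogram(bin_edges=edges, P=counts / counts.sum())


def weighting_diagnostic(records: Sequence[StudyRecord], alpha: float = 0.05
                         ) -> Tuple[float, float, str]:
    """sd^2-vs-n reliability diagnostic for choosing a weighting scheme.

    Reported standard deviations should be descriptive statistics,
    independent of sample size; an association between sd(theta_i)^2 and
    n_i indicates unreliable uncertainty reporting, in which case
    sample-size weighting is recommended over inverse variance.

    Returns ``(slope, p_value, recommendation)`` from an ordinary
    regression of sd^2 on n, with recommendation ``"sample_size"`` when
    the slope is significantly nonzero at ``alpha`` and
    ``"inverse_variance"`` otherwise.
    """
    if len(records) < 3:
        raise ValueError("weighting diagnostic requires at least 3 studies")
    n = np.array([r.n_treatment for r in records], dtype=float)
    sd2 = np.array([r.sd_treatment ** 2 for r in records], dtype=float)
    if np.ptp(n) == 0:
        logger.warning("constant n across studies: sd^2-n slope undefined; "
                       "defaulting to inverse-variance recommendation")
        return (float("nan"), float("nan"), "inverse_variance")
    res = stats.linregress(n, sd2)
    rec = "sample_size" if res.pvalue < alpha else "inverse_variance"
    return (float(res.slope), float(res.pvalue), rec)
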