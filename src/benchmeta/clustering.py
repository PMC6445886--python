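"""Cluster-covariate dependence analysis.

Unsupervised k-means partitions study-level effects into natural
groupings; Pearson's chi-squared test of independence then asks whether
cluster memberships coincide with known categorical covariates. The
chi-squared approximation is flagged invalid unless at least 80% of
covariate-cluster cells have an expected count of at least 5. Clustering
is deliberately unweighted — study-level precisions do not bias the
partition — and always converges to some partition, so results are
exploratory and require covariate support before interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .datatypes import EffectSize

logger = logging.getLogger(__name__)

__all__ = ["ClusterAssignment", "DependenceTest", "kmeans_cluster",
           "dependence_test", "effect_features", "elbow_report"]


@dataclass
class ClusterAssignment:
    """k-means labels for each study plus the final inertia."""

    study_ids: List[str]
    labels: np.ndarray
    k: int
    inertia: float
    degenerate: bool = False


@dataclass
class DependenceTest:
    """Pearson chi^2 test of cluster membership vs a categorical covariate."""

    covariate: str
    chi2: float
    df: int
    p: float
    valid: bool
    table: pd.DataFrame


def effect_features(effects: Sequence[EffectSize], include_log_se: bool = False,
                    standardize: bool = True) -> pd.DataFrame:
    """Feature matrix for clustering: theta, optionally log(se), standardized."""
    data = {"theta": [e.theta for e in effects]}
    if include_log_se:
        data["log_se"] = [np.log(e.se) for e in effects]
    df = pd.DataFrame(data, index=[e.study_id for e in effects])
    if standardize:
        vals = StandardScaler().fit_transform(df.to_numpy())
        df = pd.DataFrame(vals, index=df.index, columns=df.columns)
    return df


def kmeans_cluster(features: Union[pd.DataFrame, np.ndarray], k: int,
                   n_init: int = 10, seed: int = 0,
                   study_ids: Optional[Sequence[str]] = None) -> ClusterAssignment:
    """Best-of-``n_init`` k-means partition of the study-level features.

    Which features feed the clustering (effect size alone, or effect size
    plus kinetic/experimental parameters) is a dataset-level choice the
    caller makes; see :func:`effect_features` for the default
    construction. Deterministic given ``seed``.
    """
    if isinstance(features, pd.DataFrame):
        ids = list(features.index.astype(str))
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        ids = list(study_ids) if study_ids is not None else [str(i) for i in range(len(X))]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of studies ({len(X)})")

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    degenerate = len(np.unique(labels)) < k or np.allclose(np.ptp(X, axis=0), 0)
    if degenerate:
        logger.warning("degenerate clustering: identical features or empty cluster")
    return ClusterAssignment(study_ids=ids, labels=labels, k=k,
                             inertia=float(km.inertia_), degenerate=degenerate)


def elbow_report(features: Union[pd.DataFrame, np.ndarray],
                 k_range: Sequence[int] = range(2, 7), n_init: int = 10,
                 seed: int = 0) -> Dict[int, float]:
    """Inertia as a function of k, to support choosing k by elbow."""
    return {k: kmeans_cluster(features, k, n_init=n_init, seed=seed).inertia
            for k in k_range}


def dependence_test(assignment: ClusterAssignment,
                    covariate_values: Mapping[str, str],
                    covariate: str = "covariate") -> DependenceTest:
    """Pearson chi^2 independence test of clusters against a covariate.

    ``valid`` is False when fewer than 80% of cells have an expected
    count of at least 5; the statistic is still reported in that case but
    should be treated as unreliable.
    """
    values = []
    for sid in assignment.study_ids:
        if sid not in covariate_values:
            raise ValueError(f"covariate value missing for study {sid!r}")
        values.append(str(covariate_values[sid]))
    if len(set(values)) < 2:
        raise ValueError(f"covariate {covariate!r} has a single level")

    table = pd.crosstab(pd.Series(values, name=covariate),
                        pd.Series(assignment.labels, name="cluster"))
    chi2, p, df, expected = chi2_contingency(table.to_numpy(), correction=False)
    valid = bool(np.mean(expected >= 5) >= 0.8)
    if not valid:
        logger.warning("chi2 approximation unreliable: fewer than 80%% of cells "
                       "have expected count >= 5")
    return DependenceTest(covariate=covariate, chi2=float(chi2), df=int(df),
                          p=float(p), valid=valid, table=table)
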