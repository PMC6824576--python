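"""Two-step clustering with log-likelihood distance, and predictor importance.

Patients are grouped in two steps: a seeded k-means pass splits them into
many small pre-clusters, which are then merged agglomeratively; at every
step the pair whose merge costs the least log-likelihood is joined, until
the requested number of clusters (two, for this workflow) remains. The
merge cost between clusters j and s is

    d(j, s) = xi_j + xi_s - xi_<j,s>,
    xi_v    = -N_v * sum_k 1/2 * ln(sigma2_k + sigma2_vk),

with sigma2_k the global (population) variance of feature k and sigma2_vk
the within-cluster population variance; the global term guards the log at
zero within-cluster variance.

The cross-check logic: a parameter carrying a genuine group structure
separates the two unsupervised clusters strongly (high importance), while
a parameter dominated by random within-column anomalies does not — so low
clustering importance corroborates an entropy-based anomaly flag.
Importance is the per-parameter two-cluster Welch t-test evidence,
normalized: importance = (-log10 p) / max_param(-log10 p), in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .entropy import EntropyReport

_P_FLOOR = 1e-300  # guards -log10(p) when t is effectively infinite


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray  # 1-based cluster ids, 1 = largest cluster
    n_clusters: int
    degenerate: bool    # true when the data could not support k clusters


@dataclass(frozen=True)
class ClusterImportanceReport:
    parameters: tuple[str, ...]
    importance: np.ndarray    # in [0, 1]
    rank: np.ndarray          # 1 = most important
    p_values: np.ndarray
    labels: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.parameters,
            "importance": self.importance,
            "rank": self.rank,
            "p_value": self.p_values,
        })


def _xi(block: np.ndarray, global_var: np.ndarray) -> float:
    """Cluster log-likelihood term: block is (members, features)."""
    if block.shape[0] == 0:
        raise ValueError("empty cluster")
    var_within = block.var(axis=0)  # population (divide-by-N) variance
    return float(-block.shape[0] * 0.5 * np.log(global_var + var_within).sum())


def log_likelihood_distance(cluster_j, cluster_s, global_variances) -> float:
    """Merge cost d(j,s) = xi_j + xi_s - xi_<j,s> for continuous features."""
    a = np.asarray(cluster_j, dtype=float)
    b = np.asarray(cluster_s, dtype=float)
    # 1-D input = members of a single-feature cluster
    a = a.reshape(-1, 1) if a.ndim == 1 else a
    b = b.reshape(-1, 1) if b.ndim == 1 else b
    g = np.atleast_1d(np.asarray(global_variances, dtype=float))
    if np.any(g <= 0):
        raise ValueError("global variances must be positive")
    merged = np.vstack([a, b])
    return _xi(a, g) + _xi(b, g) - _xi(merged, g)


def two_step_cluster(
    matrix: np.ndarray,
    n_preclusters: int = 20,
    k: int = 2,
    seed: int = 0,
) -> ClusteringResult:
    """Pre-cluster with seeded k-means, then merge by log-likelihood distance.

    Cluster ids are renumbered by size (1 = largest; ties by first member).
    If the data cannot support ``k`` distinct clusters (e.g. all points
    identical) the result is flagged degenerate.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    if n < k:
        raise ValueError(f"{n} patients cannot form {k} clusters")
    if n_preclusters < k:
        raise ValueError("n_preclusters must be >= k")
    global_var = x.var(axis=0)
    usable = global_var > 0
    if not usable.any():
        return ClusteringResult(
            labels=np.ones(n, dtype=int), n_clusters=1, degenerate=True)
    xu = x[:, usable]
    gv = global_var[usable]

    m = min(n_preclusters, n)
    km = KMeans(n_clusters=m, random_state=seed, n_init=10)
    pre = km.fit_predict(xu)
    clusters = [np.flatnonzero(pre == c) for c in range(m)]
    clusters = [c for c in clusters if c.size > 0]

    while len(clusters) > k:
        best, best_pair = np.inf, (0, 1)
        xis = [_xi(xu[c], gv) for c in clusters]
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                merged = np.concatenate([clusters[i], clusters[j]])
                d = xis[i] + xis[j] - _xi(xu[merged], gv)
                if d < best:
                    best, best_pair = d, (i, j)
        i, j = best_pair
        clusters[i] = np.concatenate([clusters[i], clusters[j]])
        del clusters[j]

    degenerate = len(clusters) < k
    order = sorted(range(len(clusters)),
                   key=lambda c: (-clusters[c].size, clusters[c].min()))
    labels = np.zeros(n, dtype=int)
    for new_id, c in enumerate(order, start=1):
        labels[clusters[c]] = new_id
    return ClusteringResult(labels=labels, n_clusters=len(clusters),
                            degenerate=degenerate)


def predictor_importance(
    matrix: np.ndarray,
    labels: np.ndarray,
    parameter_names: Sequence[str] | None = None,
) -> ClusterImportanceReport:
    """Normalized two-cluster Welch-t importance per parameter."""
    x = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if ids.size != 2:
        raise ValueError(f"expected exactly 2 clusters, found {ids.size}")
    a = x[labels == ids[0]]
    b = x[labels == ids[1]]
    if min(a.shape[0], b.shape[0]) < 2:
        raise ValueError(
            "a cluster has a single member; importance is undefined "
            "(increase n_preclusters or inspect the clustering)")
    p = x.shape[1]
    if parameter_names is None:
        parameter_names = tuple(f"p{j}" for j in range(p))
    pvals = np.empty(p)
    for j in range(p):
        aj, bj = a[:, j], b[:, j]
        if np.ptp(np.concatenate([aj, bj])) == 0:
            pvals[j] = 1.0  # identical across clusters
            continue
        if aj.var() == 0 and bj.var() == 0:
            # constant within each cluster but different between: maximal
            # separation, zero within-variance; Welch t degenerates
            pvals[j] = _P_FLOOR
            continue
        t = stats.ttest_ind(aj, bj, equal_var=False)
        pvals[j] = float(t.pvalue) if np.isfinite(t.pvalue) else 1.0
    neg_log = -np.log10(np.clip(pvals, _P_FLOOR, 1.0))
    top = neg_log.max()
    importance = (neg_log / top if top > 0
                  else np.zeros_like(neg_log))
    importance = np.clip(importance, 0.0, 1.0)
    # rank 1 = most important; ties broken by parameter order
    order = np.lexsort((np.arange(p), -importance))
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    return ClusterImportanceReport(
        parameters=tuple(parameter_names),
        importance=importance,
        rank=rank,
        p_values=pvals,
        labels=labels.copy(),
    )


def anomaly_corroboration(
    entropy_report: EntropyReport,
    importance_report: ClusterImportanceReport,
    importance_cutoff: float = 0.05,
    low_fraction: float = 1 / 3,
) -> set[str]:
    """Parameters flagged by entropy AND of low clustering importance.

    A parameter counts as low-importance if its normalized score is at
    most ``importance_cutoff`` or it ranks in the lowest ``low_fraction``
    of the importance profile (rounded up). The rank route makes the
    notion robust to the scale of the importance transform, whose
    absolute values differ between implementations even when the ranking
    agrees; on a profile where the anomalous parameters sit near zero and
    the rest spread broadly upward, both routes select the same set.
    """
    ent = set(entropy_report.parameters)
    params = importance_report.parameters
    if not ent & set(params):
        raise ValueError("entropy and importance reports share no parameters")
    if not 0 <= low_fraction <= 1:
        raise ValueError("low_fraction must lie in [0, 1]")
    p = len(params)
    n_low = math.ceil(p * low_fraction)
    low = {
        name for name, v, r in zip(params, importance_report.importance,
                                   importance_report.rank)
        if v <= importance_cutoff or r > p - n_low
    }
    return set(entropy_report.flags) & low
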