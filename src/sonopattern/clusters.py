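"""Distance-based comparison clusterings: K-modes, Gower hierarchical, silhouette.

These are the benchmarks the model-based latent-class solution is compared
against. For an all-categorical table the Gower dissimilarity reduces to the
simple-matching distance: the fraction of features on which two patients
disagree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

__all__ = [
    "ClusterSolution",
    "kmodes_fit",
    "gower_dissimilarity",
    "hierarchical_fit",
    "average_silhouette",
]


@dataclass
class ClusterSolution:
    method: str
    k: int
    labels: np.ndarray          # 1-based cluster labels
    cost: float | None = None   # K-modes: total simple-matching mismatches
    merge_tree: np.ndarray | None = None  # hierarchical: scipy linkage matrix
    silhouette: float | None = None

    def shares(self) -> np.ndarray:
        _, counts = np.unique(self.labels, return_counts=True)
        return counts / self.labels.size


def _codes(features) -> np.ndarray:
    x = features.to_numpy() if isinstance(features, pd.DataFrame) else np.asarray(features)
    return x.astype(int)


def gower_dissimilarity(features) -> np.ndarray:
    """N x N Gower matrix; for categorical data d = (#mismatching features)/J."""
    x = _codes(features)
    n, J = x.shape
    d = np.zeros((n, n))
    for j in range(J):
        d += x[:, j, None] != x[None, :, j]
    return d / J


def _mismatch_to_modes(x: np.ndarray, modes: np.ndarray) -> np.ndarray:
    # n x k matrix of simple-matching distances to each mode
    return (x[:, None, :] != modes[None, :, :]).sum(axis=2)


def _column_modes(x: np.ndarray) -> np.ndarray:
    """Columnwise modal category; ties resolved to the lowest code."""
    out = np.empty(x.shape[1], dtype=int)
    for j in range(x.shape[1]):
        vals, counts = np.unique(x[:, j], return_counts=True)
        out[j] = vals[np.argmax(counts)]  # np.unique sorts, argmax takes first max
    return out


def kmodes_fit(features, k: int, n_init: int = 20, seed: int = 0, max_iter: int = 100) -> ClusterSolution:
    """K-modes clustering: minimize total simple-matching distance to modes.

    Best of ``n_init`` random initializations (modes seeded from distinct
    rows). Assignment ties go to the lowest cluster index; mode-update ties
    to the lowest category code; an emptied cluster is re-seeded with the
    point farthest from its current mode.
    """
    x = _codes(features)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError("require 1 <= k <= N")
    distinct = np.unique(x, axis=0)
    if k > distinct.shape[0]:
        raise ValueError(f"k={k} exceeds the {distinct.shape[0]} distinct rows")
    rng = np.random.default_rng(seed)
    best_labels, best_cost = None, np.inf
    for _ in range(max(1, n_init)):
        modes = distinct[rng.choice(distinct.shape[0], size=k, replace=False)].copy()
        labels = np.full(n, -1)
        for _ in range(max_iter):
            dist = _mismatch_to_modes(x, modes)
            new_labels = dist.argmin(axis=1)
            for c in range(k):  # empty-cluster repair
                if not np.any(new_labels == c):
                    far = int(np.argmax(dist[np.arange(n), new_labels]))
                    new_labels[far] = c
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                modes[c] = _column_modes(x[labels == c])
        cost = float(_mismatch_to_modes(x, modes)[np.arange(n), labels].sum())
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return ClusterSolution(method="kmodes", k=k, labels=best_labels + 1, cost=best_cost)


def hierarchical_fit(dissim: np.ndarray, k: int, linkage_method: str = "average") -> ClusterSolution:
    """Agglomerative clustering on a precomputed dissimilarity matrix, cut at k."""
    d = np.asarray(dissim, dtype=float)
    n = d.shape[0]
    if k > n:
        raise ValueError("k cannot exceed N")
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("dissim must be a symmetric matrix with zero diagonal")
    tree = linkage(squareform(d, checks=False), method=linkage_method)
    labels = fcluster(tree, t=k, criterion="maxclust")
    return ClusterSolution(method=f"hierarchical[{linkage_method}]", k=k, labels=labels, merge_tree=tree)


def average_silhouette(labels: np.ndarray, dissim: np.ndarray) -> float:
    """Mean silhouette s(i) = (b - a)/max(a, b) over patients.

    Computed from the precomputed dissimilarity matrix; members of singleton
    clusters contribute 0. Requires at least two non-empty clusters.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least two clusters")
    return float(np.mean(silhouette_samples(np.asarray(dissim, float), labels, metric="precomputed")))
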