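"""Clustering quality metrics implemented directly (silhouette, adjusted
Rand index), so the analysis path does not depend on an external ML stack.
Reference implementations from scikit-learn are used only as oracles in the
test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigurationError

__all__ = ["pairwise_distances", "silhouette_score", "adjusted_rand_index"]


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    """Dense Euclidean distance matrix (n, n)."""
    X = np.asarray(X, dtype=np.float64)
    return cdist(X, X)


def silhouette_score(
    labels: np.ndarray, X: np.ndarray | None = None, D: np.ndarray | None = None
) -> float:
    """Mean silhouette over samples.

    For sample i with intra-cluster mean distance a(i) (to the other members
    of its cluster) and b(i) the smallest mean distance to another cluster,
    s(i) = (b - a) / max(a, b); singleton clusters score 0. Pass either raw
    data ``X`` or a precomputed distance matrix ``D`` (reused across k when
    sweeping cluster counts).
    """
    labels = np.asarray(labels)
    if D is None:
        if X is None:
            raise ConfigurationError("silhouette_score needs X or D")
        D = pairwise_distances(X)
    n = len(labels)
    if D.shape != (n, n):
        raise ConfigurationError("distance matrix shape does not match labels")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ConfigurationError("silhouette requires at least 2 clusters")
    onehot = (labels[:, None] == uniq[None, :]).astype(np.float64)  # (n, k)
    counts = onehot.sum(axis=0)  # (k,)
    sums = D @ onehot  # (n, k): total distance from i to each cluster
    own = onehot.argmax(axis=1)
    own_count = counts[own]
    a = np.where(own_count > 1, sums[np.arange(n), own] / np.maximum(own_count - 1, 1), 0.0)
    mean_other = sums / counts[None, :]
    mean_other[np.arange(n), own] = np.inf
    b = mean_other.min(axis=1)
    s = np.where(own_count > 1, (b - a) / np.maximum(a, b), 0.0)
    return float(s.mean())


def adjusted_rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ConfigurationError("label arrays must have equal length")
    n = labels_a.size
    ua, ia = np.unique(labels_a, return_inverse=True)
    ub, ib = np.unique(labels_b, return_inverse=True)
    contingency = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(contingency, (ia, ib), 1)

    def comb2(x):
        return x * (x - 1) // 2

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
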