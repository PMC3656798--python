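"""Clustering evaluation: Rand Index and Silhouette Index.

The Rand Index counts unordered item pairs by their joint status in two
partitions — Z1 together in both, Z2 apart in both, Z3 together only in
the first, Z4 together only in the second — and returns
``(Z1 + Z2) / (Z1 + Z2 + Z3 + Z4)``, a value in [0, 1] (1 = identical
partitions up to relabeling).

The Silhouette Index averages ``s(p) = (y - x) / max(x, y)`` over points,
where x is a point's mean distance to the rest of its cluster and y its
smallest mean distance to any other cluster; values lie in [-1, 1] and
larger means tighter, better-separated clusters.  Points in singleton
clusters contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import ExpressionMatrix, Partition

__all__ = ["PairCounts", "pair_counts", "rand_index", "silhouette_index"]


@dataclass(frozen=True)
class PairCounts:
    """Pair-agreement tallies between two partitions of n items;
    Z1+Z2+Z3+Z4 = n(n-1)/2."""

    Z1: int  # same set in both
    Z2: int  # different sets in both
    Z3: int  # same in X, different in Y
    Z4: int  # different in X, same in Y

    @property
    def total(self) -> int:
        return self.Z1 + self.Z2 + self.Z3 + self.Z4


def _sorted_items(items) -> list:
    try:
        return sorted(items)
    except TypeError:  # mixed types: fall back to a stable string order
        return sorted(items, key=str)


def _aligned_labels(X: Partition, Y: Partition) -> tuple[np.ndarray, np.ndarray]:
    if set(X.items) != set(Y.items):
        raise ValueError("partitions cover different item sets")
    items = _sorted_items(X.items)
    lx = np.array([hash(X[i]) for i in items])
    ly = np.array([hash(Y[i]) for i in items])
    # re-encode as dense ints
    _, lx = np.unique(lx, return_inverse=True)
    _, ly = np.unique(ly, return_inverse=True)
    return lx, ly


def pair_counts(X: Partition, Y: Partition) -> PairCounts:
    """Count the four pair categories via the contingency table."""
    lx, ly = _aligned_labels(X, Y)
    n = len(lx)
    if n < 2:
        raise ValueError("need at least 2 items")
    cont = np.zeros((lx.max() + 1, ly.max() + 1), dtype=np.int64)
    np.add.at(cont, (lx, ly), 1)

    def pairs2(v: np.ndarray) -> int:
        return int((v.astype(np.int64) * (v - 1) // 2).sum())

    total = n * (n - 1) // 2
    z1 = pairs2(cont.ravel())
    same_x = pairs2(cont.sum(axis=1))
    same_y = pairs2(cont.sum(axis=0))
    z3 = same_x - z1
    z4 = same_y - z1
    z2 = total - z1 - z3 - z4
    return PairCounts(Z1=z1, Z2=z2, Z3=z3, Z4=z4)


def rand_index(X: Partition, Y: Partition) -> float:
    """Rand Index between two partitions of the same items."""
    pc = pair_counts(X, Y)
    return (pc.Z1 + pc.Z2) / pc.total


def silhouette_index(data, partition: Partition, metric: str = "euclidean",
                     precomputed: bool = False) -> float:
    """Mean silhouette width of a partition.

    ``data`` is an :class:`ExpressionMatrix` (genes are scored on their
    expression profiles across experiments) or an array of item feature
    vectors in the partition's sorted item order; with ``precomputed=True``
    it is instead a square distance matrix.  Requires at least two
    clusters; singleton-cluster points contribute 0.
    """
    items = _sorted_items(partition.items)
    labels = np.array([partition[i] for i in items], dtype=object)
    _, lab = np.unique([hash(l) for l in labels], return_inverse=True)
    n_clusters = lab.max() + 1
    if n_clusters < 2:
        raise ValueError("silhouette undefined for a single cluster")

    if isinstance(data, ExpressionMatrix):
        order = {g: idx for idx, g in enumerate(data.gene_ids)}
        feats = data.values.T[[order[i] for i in items]]
        dist = squareform(pdist(feats, metric=metric))
    elif precomputed:
        dist = np.asarray(data, dtype=float)
        if dist.shape != (len(items), len(items)):
            raise ValueError("distance matrix shape does not match item count")
    else:
        feats = np.asarray(data, dtype=float)
        dist = squareform(pdist(feats, metric=metric))

    n = len(items)
    sizes = np.bincount(lab, minlength=n_clusters)
    # mean distance from each point to each cluster
    sums = np.zeros((n, n_clusters))
    for c in range(n_clusters):
        sums[:, c] = dist[:, lab == c].sum(axis=1)
    s = np.zeros(n)
    for p in range(n):
        c = lab[p]
        if sizes[c] == 1:
            continue  # singleton convention: s = 0
        x = sums[p, c] / (sizes[c] - 1)
        others = [sums[p, c2] / sizes[c2] for c2 in range(n_clusters) if c2 != c]
        y = min(others)
        denom = max(x, y)
        s[p] = 0.0 if denom == 0 else (y - x) / denom
    return float(s.mean())
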