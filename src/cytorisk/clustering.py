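"""SOM metaclustering and automated cluster-number selection.

Cells are first mapped to the nodes of a small self-organizing map; the node
codebook vectors are then merged into k metaclusters by hierarchical
clustering (average linkage).  The appropriate k is chosen automatically by
sweeping a range of cluster numbers (default 5-50) and, for every clustering
feature, finding the smallest k whose size-weighted within-cluster variance
is within a small tolerance of that feature's minimum over the sweep; the
cohort-level optimum is the median of the per-feature optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .embedding import Embedding
from .io import CellTable, ValidationError
from .som import SelfOrganizingMap

__all__ = [
    "ClusterResult",
    "ClusterNumberSearch",
    "cluster_fixed_k",
    "intra_cluster_variance",
    "select_cluster_number",
]


@dataclass
class ClusterResult:
    """Per-cell metacluster labels (1..k) from one SOM clustering."""

    labels: np.ndarray
    k: int
    seed: int
    node_assignments: np.ndarray | None = None
    occupied_k: int | None = None  # < k when merging left empty labels

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.k):
            raise ValidationError("labels must lie in 1..k")
        if self.occupied_k is None:
            self.occupied_k = len(np.unique(self.labels))


@dataclass
class ClusterNumberSearch:
    """Outcome of the automated cluster-number sweep."""

    k_range: list[int]
    per_feature_variance: pd.DataFrame  # index: k, columns: features
    per_feature_optimum: pd.Series  # feature -> k*(f)
    k_opt: int

    def to_csv(self, path) -> None:
        out = self.per_feature_variance.copy()
        out.loc["k_star"] = self.per_feature_optimum
        out.to_csv(path)


def _train_som(
    embedding: Embedding, seed: int, som_shape: tuple[int, int] = (10, 10)
) -> tuple[SelfOrganizingMap, np.ndarray]:
    som = SelfOrganizingMap(shape=som_shape).fit(embedding.coords, seed=seed)
    return som, som.predict(embedding.coords)


def _metacluster_nodes(codebook: np.ndarray, k: int, Z: np.ndarray | None = None) -> np.ndarray:
    """Merge SOM nodes into k groups; returns node -> metacluster (1..k)."""
    if Z is None:
        Z = linkage(codebook, method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def cluster_fixed_k(
    embedding: Embedding,
    k: int,
    seed: int = 0,
    som_shape: tuple[int, int] = (10, 10),
) -> ClusterResult:
    """Cluster the embedded cells into k populations.

    Trains the SOM on the embedding coordinates, merges node codebook
    vectors into k metaclusters, and propagates node labels to cells.
    Deterministic under a fixed seed.
    """
    if k < 2:
        raise ValidationError("k must be at least 2")
    if embedding.n_cells == 0:
        raise ValidationError("embedding is empty")
    if k > embedding.n_cells:
        raise ValidationError("k exceeds the number of cells")
    som, nodes = _train_som(embedding, seed, som_shape)
    node_meta = _metacluster_nodes(som.codebook, k)
    labels = node_meta[nodes]
    return ClusterResult(labels=labels, k=k, seed=seed, node_assignments=nodes)


def intra_cluster_variance(
    table: CellTable, labels: np.ndarray, feature: str
) -> float:
    """Size-weighted mean within-cluster variance of one feature.

    V(f, k) = sum_c (n_c / N) var_c(f) with population variances, so that a
    single all-encompassing cluster gives exactly the total variance and a
    partition into singletons gives exactly 0.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != table.n_cells:
        raise ValidationError("labels must align with the table")
    x = table.values[:, table.marker_index(feature)]
    return _weighted_within_variance(x[:, None], labels)[0]


def _weighted_within_variance(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vector of size-weighted within-cluster variances, one per column."""
    N = X.shape[0]
    uniq, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv).astype(float)
    sums = np.empty((len(uniq), X.shape[1]))
    sq = np.empty_like(sums)
    for f in range(X.shape[1]):  # bincount per column beats scattered adds
        sums[:, f] = np.bincount(inv, weights=X[:, f], minlength=len(uniq))
        sq[:, f] = np.bincount(inv, weights=X[:, f] ** 2, minlength=len(uniq))
    means = sums / counts[:, None]
    var_c = sq / counts[:, None] - means**2  # population variance per cluster
    var_c = np.maximum(var_c, 0.0)
    out = (counts[:, None] / N * var_c).sum(axis=0)
    return out


def select_cluster_number(
    embedding: Embedding,
    table: CellTable,
    markers: Sequence[str],
    k_range: Sequence[int] | tuple[int, int] = (5, 50),
    elbow_tol: float = 0.03,
    structure_frac: float = 0.5,
    seed: int = 0,
    som_shape: tuple[int, int] = (10, 10),
) -> ClusterNumberSearch:
    """Automated cluster-number search over ``k_range``.

    For each k the cells are clustered once (fixed seed: a single SOM is
    trained and the node dendrogram is cut at each k) and the within-cluster
    variance V(f, k) of every clustering marker f is recorded on the arcsinh
    marker values.  V decreases essentially monotonically with k, so the
    "smallest number of clusters that minimises" it needs an operational
    elbow.  Per feature, with Vmin = min_k V(f, k) and Vtot = Var(f):

    * a feature whose variance is never reduced below
      ``(1 - structure_frac) * Vtot`` anywhere in the range carries no
      cluster structure (its curve is comparatively flat) and votes for
      the low end of the range;
    * otherwise k*(f) is the smallest k with
      V(f, k) <= Vmin + elbow_tol * (Vtot - Vmin), i.e. the first k that
      achieves essentially all of the variance reduction the range offers.

    The cohort-level k_opt is the (lower) median of the per-feature optima.
    """
    markers = list(markers)
    if not markers:
        raise ValidationError("markers must not be empty")
    if isinstance(k_range, tuple) and len(k_range) == 2:
        ks = list(range(int(k_range[0]), int(k_range[1]) + 1))
    else:
        ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValidationError("k_range is empty")
    if ks[0] < 2:
        raise ValidationError("cluster numbers must be >= 2")
    if ks[-1] > embedding.n_cells:
        raise ValidationError("k_range exceeds the number of cells")

    som, nodes = _train_som(embedding, seed, som_shape)
    Z = linkage(som.codebook, method="average")
    X = table.marker_matrix(markers)

    V = np.empty((len(ks), len(markers)))
    for i, k in enumerate(ks):
        node_meta = _metacluster_nodes(som.codebook, k, Z=Z)
        labels = node_meta[nodes]
        V[i] = _weighted_within_variance(X, labels)

    vtab = pd.DataFrame(V, index=pd.Index(ks, name="k"), columns=markers)
    vtot = X.var(axis=0)
    k_star = {}
    for j, f in enumerate(markers):
        col = vtab[f].to_numpy()
        vmin = col.min()
        if vmin > (1.0 - structure_frac) * vtot[j]:
            k_star[f] = ks[0]  # no cluster structure on this channel
            continue
        thr = vmin + elbow_tol * (vtot[j] - vmin)
        k_star[f] = ks[int(np.argmax(col <= thr))]
    opt = pd.Series(k_star, name="k_star")

    vals = np.sort(opt.to_numpy())
    k_opt = int(vals[(len(vals) - 1) // 2])  # lower median: integral, conservative
    k_opt = min(max(k_opt, ks[0]), ks[-1])
    return ClusterNumberSearch(
        k_range=ks, per_feature_variance=vtab, per_feature_optimum=opt, k_opt=k_opt
    )
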