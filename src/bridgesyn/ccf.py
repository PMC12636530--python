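"""Clustering-based cell-line feature (CCF) encoder.

Compresses the L x D_P enriched gene matrix G into |C| cluster-level rows via
a k-nearest-neighbour density-peaks clustering (DPC-KNN), then projects the
compressed matrix through a three-stage MLP into the shared fusion width.

DPC-KNN in brief: each gene's local density is an exponential of the mean
squared distance to its k nearest neighbours (self excluded); its separation
is the distance to the nearest strictly denser gene (or, for density maxima,
the farthest gene); cluster centers maximize density x separation; remaining
genes join their nearest center and each cluster is summarized by its mean
row.  Gene modules with coherent enriched-expression patterns therefore
collapse into single rows, shortening the sequence the fusion module sees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from . import nn
from .io_data import ContractError


class ConfigError(ValueError):
    pass


@dataclass
class CCFConfig:
    k: int = 8                 # neighbour count for the local density
    n_clusters: int = 32       # |C|, length of the compressed sequence
    hidden: int | None = None  # projector MLP width; None -> the fusion width
    representative: str = "mean"   # "mean" row or the "center" row per cluster

    def __post_init__(self):
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if self.representative not in ("mean", "center"):
            raise ConfigError(f"invalid representative {self.representative!r}")


@dataclass
class ClusterResult:
    density: np.ndarray        # rho, length L
    separation: np.ndarray     # delta, length L
    centers: list[int]         # |C| gene indices
    assignment: np.ndarray     # length L, values in [0, |C|)
    G_c: np.ndarray            # |C| x D_P compressed matrix

    def __post_init__(self):
        L = self.assignment.shape[0]
        if len(set(self.centers)) != len(self.centers):
            raise ContractError("cluster centers must be distinct")
        for rank, c in enumerate(self.centers):
            if self.assignment[c] != rank:
                raise ContractError(f"center {c} not assigned to its own cluster")
        if self.density is not None and self.density.shape[0] != L:
            raise ContractError("density length mismatch")


def local_density(G: np.ndarray, k: int) -> np.ndarray:
    """rho_i = exp(-(1/k) * sum of squared distances to the k nearest
    neighbours of gene i), self excluded.  Values lie in (0, 1]."""
    G = np.asarray(G, dtype=np.float64)
    L = G.shape[0]
    if k >= L:
        raise ConfigError(f"k={k} must be < number of genes L={L}")
    sq = squareform(pdist(G, metric="sqeuclidean"))
    np.fill_diagonal(sq, np.inf)            # exclude self from the KNN set
    knn_sq = np.partition(sq, k - 1, axis=1)[:, :k]
    return np.exp(-knn_sq.sum(axis=1) / k)


def separation_distance(G: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """delta_i: distance (plain Euclidean) to the nearest strictly denser
    gene, or the farthest gene when none is denser."""
    G = np.asarray(G, dtype=np.float64)
    rho = np.asarray(rho, dtype=np.float64)
    L = G.shape[0]
    if L < 2:
        raise ConfigError("separation distance needs at least 2 genes")
    dist = squareform(pdist(G, metric="euclidean"))
    delta = np.empty(L)
    for i in range(L):
        denser = rho > rho[i]
        denser[i] = False
        delta[i] = dist[i, denser].min() if denser.any() else dist[i].max()
    return delta


def select_centers(rho: np.ndarray, delta: np.ndarray, n_clusters: int) -> list[int]:
    """Indices of the n_clusters largest rho*delta scores (ties -> lower index)."""
    score = np.asarray(rho) * np.asarray(delta)
    L = score.shape[0]
    if n_clusters > L:
        raise ConfigError(f"n_clusters={n_clusters} exceeds L={L}")
    order = np.lexsort((np.arange(L), -score))
    return [int(i) for i in order[:n_clusters]]


def assign_and_aggregate(G: np.ndarray, centers: list[int],
                         rho: np.ndarray | None = None,
                         delta: np.ndarray | None = None,
                         representative: str = "mean",
                         max_refine: int = 100) -> ClusterResult:
    """Group every gene with the cluster whose centroid is closest.

    Seeded by nearest-center assignment (squared Euclidean, ties to the
    lower center rank), then refined Lloyd-style against the evolving
    cluster centroids until stable; each density-peak center stays anchored
    to its own cluster throughout.  Clusters are summarized by their mean
    row (or the center's own row)."""
    G = np.asarray(G, dtype=np.float64)
    L = G.shape[0]
    if not centers or any(c < 0 or c >= L for c in centers):
        raise ContractError(f"invalid centers {centers} for L={L}")
    d2 = cdist(G, G[centers], metric="sqeuclidean")
    assignment = d2.argmin(axis=1)          # argmin takes the lowest rank on ties
    for rank, c in enumerate(centers):
        assignment[c] = rank                # a center anchors its own cluster
    for _ in range(max_refine):
        means = np.stack([G[assignment == r].mean(axis=0)
                          for r in range(len(centers))])
        new = cdist(G, means, metric="sqeuclidean").argmin(axis=1)
        for rank, c in enumerate(centers):
            new[c] = rank
        if np.array_equal(new, assignment):
            break
        assignment = new
    if representative == "mean":
        G_c = np.stack([G[assignment == r].mean(axis=0)
                        for r in range(len(centers))])
    else:
        G_c = G[centers].copy()
    return ClusterResult(
        density=rho if rho is not None else np.zeros(L),
        separation=delta if delta is not None else np.zeros(L),
        centers=list(centers), assignment=assignment, G_c=G_c)


def dpc_knn(G: np.ndarray, config: CCFConfig) -> ClusterResult:
    """Full DPC-KNN pipeline on an enriched gene matrix."""
    rho = local_density(G, config.k)
    delta = separation_distance(G, rho)
    centers = select_centers(rho, delta, config.n_clusters)
    return assign_and_aggregate(G, centers, rho, delta, config.representative)


def comparator_clusterings(G: np.ndarray, method: str, n_clusters: int,
                           seed: int = 0, dbscan_eps: float = 0.5,
                           dbscan_min_samples: int = 3,
                           representative: str = "mean") -> ClusterResult:
    """k-means / DBSCAN alternatives behind the same ClusterResult contract,
    for comparing compression schemes downstream."""
    from sklearn.cluster import DBSCAN, KMeans

    G = np.asarray(G, dtype=np.float64)
    L = G.shape[0]
    if method == "kmeans":
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(G)
        labels = km.labels_.astype(int)
    elif method == "dbscan":
        labels = DBSCAN(eps=dbscan_eps, min_samples=dbscan_min_samples).fit(G).labels_
        if (labels == -1).all():
            raise ConfigError(
                "DBSCAN marked every gene as noise; increase eps or decrease "
                "min_samples")
        # fold noise points into their nearest recovered cluster
        core = labels != -1
        if (~core).any():
            d = cdist(G[~core], G[core], metric="sqeuclidean")
            labels[~core] = labels[core][d.argmin(axis=1)]
    else:
        raise ConfigError(f"unknown comparator method {method!r}")

    # re-index clusters and pick the member closest to each centroid as the
    # nominal "center" so the ClusterResult contract holds
    uniq = np.unique(labels)
    remap = {int(u): r for r, u in enumerate(uniq)}
    assignment = np.array([remap[int(l)] for l in labels])
    centers = []
    for r, u in enumerate(uniq):
        members = np.flatnonzero(assignment == r)
        centroid = G[members].mean(axis=0)
        centers.append(int(members[np.argmin(((G[members] - centroid) ** 2).sum(axis=1))]))
    if representative == "mean":
        G_c = np.stack([G[assignment == r].mean(axis=0) for r in range(len(uniq))])
    else:
        G_c = G[centers].copy()
    return ClusterResult(density=np.zeros(L), separation=np.zeros(L),
                         centers=centers, assignment=assignment, G_c=G_c)


def within_cluster_ss(G: np.ndarray, result: ClusterResult) -> float:
    """Within-cluster sum of squared distances to cluster means (compression
    quality; decreases as |C| grows)."""
    G = np.asarray(G, dtype=np.float64)
    total = 0.0
    for r in range(len(result.centers)):
        members = G[result.assignment == r]
        total += ((members - members.mean(axis=0)) ** 2).sum()
    return float(total)


class CellLineProjector(nn.Module):
    """Three [linear -> layer-norm -> GELU] stages mapping each compressed
    cluster row from D_P to the shared fusion width."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 hidden: int | None = None):
        super().__init__()
        h = hidden or d_out
        self.stack = nn.MLPStack([d_in, h, h, d_out], rng)

    def forward(self, x):
        return self.stack(x)
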