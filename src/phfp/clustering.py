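"""Hierarchical and spectral clustering of compound similarity matrices.

Similarity matrices (Tanimoto / Rogot-Goldberg / Spearman) are converted
to distances d = 1 - s with a forced zero diagonal. Two families of
algorithms partition the compounds:

* **Agglomerative hierarchical clustering** with Ward, complete, average
  or single linkage (scipy merge trees cut at K clusters).
* **Spectral clustering** on a similarity graph: either a union-symmetrized
  k-nearest-neighbor graph weighted by similarity, or a fully connected
  graph with Gaussian weights W_ij = exp(-gamma * d_ij^2). With the graph
  Laplacian L = D - W, the first K generalized eigenvectors of
  L u = lambda D u (equivalently, eigenvectors of the random-walk
  Laplacian L_rw = D^-1 L) embed each compound as a row in R^K, and a
  seeded k-means on the rows extracts the partition.

Partitions are validated internally by the silhouette score and externally
against reference class labels by the adjusted Rand index (ARI) and
normalized mutual information (NMI), with leave-one-out averaging and
K-sweeps mirroring the benchmarking protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.linalg import eigh
from scipy.spatial.distance import squareform
from sklearn import metrics as skm
from sklearn.cluster import KMeans

from .similarity import SimilarityMatrix

__all__ = [
    "DistanceMatrix",
    "GraphSpec",
    "ClusterResult",
    "ValidationReport",
    "to_distance",
    "hierarchical",
    "build_affinity",
    "spectral",
    "silhouette_score",
    "ari",
    "nmi",
    "evaluate",
    "loo_evaluate",
    "k_sweep",
    "choose_k_by_silhouette",
]

LINKAGES = ("ward", "complete", "average", "single")


@dataclass(frozen=True)
class DistanceMatrix:
    values: np.ndarray
    ids: tuple[str, ...]
    metric: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(arr, arr.T) or np.any(np.diag(arr) != 0) or arr.min() < 0:
            raise ValueError("need symmetric non-negative matrix with zero diagonal")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class GraphSpec:
    """Similarity-graph construction parameters for spectral clustering."""

    mode: str = "rbf"  # "rbf" (fully connected Gaussian) or "knn"
    n_neighbors: int = 7
    gamma: float = 1.0  # gamma = 1 / (2 sigma^2) of the Gaussian width
    eigen_tol: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("rbf", "knn"):
            raise ValueError(f"unknown graph mode {self.mode!r}")


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray
    k: int
    algorithm: str
    params: dict = field(default_factory=dict, compare=False)
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))


@dataclass(frozen=True)
class ValidationReport:
    ari: float
    nmi: float
    silhouette: float
    label_set: str = ""


def to_distance(sim: SimilarityMatrix) -> DistanceMatrix:
    """d = 1 - s (range [0,2] for Spearman); diagonal forced to zero.

    The diagonal is forced even where the metric's self-similarity is below
    1 (an all-zero fingerprint has Rogot-Goldberg self-similarity 0.5):
    linkage and silhouette require d_ii = 0, while off-diagonal entries
    keep the metric's semantics.
    """
    d = 1.0 - sim.values
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return DistanceMatrix(values=d, ids=sim.ids, metric=sim.metric)


def hierarchical(dist: DistanceMatrix, linkage: str, k: int) -> ClusterResult:
    """Agglomerative clustering cut at K clusters."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if not 1 <= k <= dist.n:
        raise ValueError(f"K={k} outside [1, {dist.n}]")
    Z = hierarchy.linkage(squareform(dist.values, checks=False), method=linkage)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
    return ClusterResult(labels=labels, k=k, algorithm="hierarchical",
                         params={"linkage": linkage})


def build_affinity(sim: SimilarityMatrix, spec: GraphSpec) -> np.ndarray:
    """Affinity matrix W of the similarity graph.

    knn mode: edge (i, j) present iff j is among i's k most similar
    neighbors *or* vice versa (union symmetrization), weighted by s_ij.
    rbf mode: fully connected, W_ij = exp(-gamma * (1 - s_ij)^2).
    """
    s = sim.values
    n = s.shape[0]
    if spec.mode == "rbf":
        d = 1.0 - s
        np.fill_diagonal(d, 0.0)
        return np.exp(-spec.gamma * d**2)
    k = spec.n_neighbors
    if not 1 <= k < n:
        raise ValueError(f"n_neighbors={k} outside [1, {n - 1}]")
    mask = np.zeros((n, n), dtype=bool)
    s_off = s.copy()
    np.fill_diagonal(s_off, -np.inf)
    for i in range(n):
        nn = np.argsort(-s_off[i], kind="stable")[:k]
        mask[i, nn] = True
    mask |= mask.T  # union symmetrization
    W = np.where(mask, s, 0.0)
    np.fill_diagonal(W, 0.0)
    return np.maximum(W, 0.0)


def spectral(
    affinity: np.ndarray,
    k: int,
    eigen_tol: float = 0.0,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterResult:
    """Random-walk-Laplacian spectral clustering.

    Solves the generalized eigenproblem L u = lambda D u exactly (dense
    symmetric solver; ``eigen_tol`` is recorded for provenance — the exact
    solver has no iteration tolerance), embeds each vertex by the first K
    eigenvectors, and runs seeded k-means with ``n_init`` restarts.
    """
    W = np.asarray(affinity, dtype=float)
    n = W.shape[0]
    if W.ndim != 2 or W.shape[1] != n:
        raise ValueError("affinity must be square")
    if not np.allclose(W, W.T) or W.min() < 0:
        raise ValueError("affinity must be symmetric and non-negative")
    if k < 2:
        raise ValueError("K must be at least 2")
    deg = W.sum(axis=1)
    dead = np.flatnonzero(deg <= 0)
    if dead.size:
        raise ValueError(f"zero-degree vertices: {dead.tolist()}")
    L = np.diag(deg) - W
    vals, vecs = eigh(L, np.diag(deg))
    embedding = vecs[:, :k]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(embedding)
    return ClusterResult(
        labels=labels, k=k, algorithm="spectral",
        params={"eigen_tol": eigen_tol, "eigenvalues": vals[:k].tolist()},
        seed=seed,
    )


def silhouette_score(dist: DistanceMatrix, labels: Sequence[int]) -> float:
    """Mean silhouette (b - a)/max(a, b) over points, on precomputed distances."""
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    if not 2 <= k < dist.n:
        raise ValueError("silhouette needs 2 <= K < n")
    return float(skm.silhouette_score(dist.values, labels, metric="precomputed"))


def ari(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Adjusted Rand index (pair-counting, chance-corrected; 1 = identical)."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.size != b.size:
        raise ValueError("label vectors must have equal length")
    return float(skm.adjusted_rand_score(a, b))


def nmi(
    labels_a: Sequence[int], labels_b: Sequence[int], average: str = "arithmetic"
) -> float:
    """Normalized mutual information in [0, 1].

    Normalization uses the arithmetic mean of the two entropies by default;
    ``average="geometric"`` selects the geometric-mean variant.
    """
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.size != b.size:
        raise ValueError("label vectors must have equal length")
    return float(skm.normalized_mutual_info_score(a, b, average_method=average))


@dataclass(frozen=True)
class ClusterConfig:
    """Which algorithm to run and with what hyperparameters."""

    algorithm: str = "hierarchical"  # or "spectral"
    linkage: str = "ward"
    graph: GraphSpec = field(default_factory=GraphSpec)
    seed: int = 0


def _run(sim: SimilarityMatrix, dist: DistanceMatrix, cfg: ClusterConfig, k: int
         ) -> ClusterResult:
    if cfg.algorithm == "hierarchical":
        return hierarchical(dist, cfg.linkage, k)
    if cfg.algorithm == "spectral":
        W = build_affinity(sim, cfg.graph)
        return spectral(W, k, eigen_tol=cfg.graph.eigen_tol, seed=cfg.seed)
    raise ValueError(f"unknown algorithm {cfg.algorithm!r}")


def evaluate(
    sim: SimilarityMatrix,
    cfg: ClusterConfig,
    k: int,
    external_labels: Sequence,
    label_set: str = "",
) -> ValidationReport:
    """Cluster once and score against external labels."""
    dist = to_distance(sim)
    res = _run(sim, dist, cfg, k)
    ext = np.asarray(external_labels)
    return ValidationReport(
        ari=ari(res.labels, ext),
        nmi=nmi(res.labels, ext),
        silhouette=silhouette_score(dist, res.labels),
        label_set=label_set,
    )


def loo_evaluate(
    sim: SimilarityMatrix,
    cfg: ClusterConfig,
    k: int,
    external_labels: Sequence,
    label_set: str = "",
) -> ValidationReport:
    """Leave-one-out averaging: n runs, each with one compound removed.

    Each run clusters the (n-1) x (n-1) submatrix and scores the retained
    compounds against the matching external labels; the arithmetic means of
    the n reports are returned.
    """
    n = sim.n
    if n < k + 1:
        raise ValueError("need n >= K + 1 for leave-one-out")
    ext = np.asarray(external_labels)
    reports = []
    for drop in range(n):
        keep = np.r_[0:drop, drop + 1:n]
        sub = SimilarityMatrix(
            values=sim.values[np.ix_(keep, keep)],
            ids=tuple(sim.ids[i] for i in keep),
            metric=sim.metric,
        )
        reports.append(evaluate(sub, cfg, k, ext[keep], label_set))
    return ValidationReport(
        ari=float(np.mean([r.ari for r in reports])),
        nmi=float(np.mean([r.nmi for r in reports])),
        silhouette=float(np.mean([r.silhouette for r in reports])),
        label_set=label_set,
    )


def k_sweep(
    sim: SimilarityMatrix,
    cfg: ClusterConfig,
    k_range: Sequence[int],
    external_labels: Sequence,
) -> list[dict]:
    """One (K, ari, nmi, silhouette) row per K, same seed across K."""
    dist = to_distance(sim)
    ext = np.asarray(external_labels)
    rows = []
    for k in k_range:
        res = _run(sim, dist, cfg, k)
        rows.append(
            {
                "k": int(k),
                "ari": ari(res.labels, ext),
                "nmi": nmi(res.labels, ext),
                "silhouette": silhouette_score(dist, res.labels),
            }
        )
    return rows


def choose_k_by_silhouette(
    dist: DistanceMatrix, linkage: str, k_range: Sequence[int]
) -> int:
    """K maximizing the silhouette of the hierarchical cut; ties -> smallest K."""
    best_k, best_s = None, -np.inf
    for k in sorted(k_range):
        res = hierarchical(dist, linkage, k)
        s = silhouette_score(dist, res.labels)
        if s > best_s + 1e-12:
            best_k, best_s = int(k), s
    return best_k
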