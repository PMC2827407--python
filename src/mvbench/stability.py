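"""Gene clustering and cluster-stability indices.

The distance between two expression profiles is the masked normalized
Euclidean distance

    d*(v, w) = sqrt( n/(n-m) * sum_observed (v_i - w_i)^2 )

where m counts the coordinates missing in v and/or w, so profiles with
gaps remain comparable to complete ones. Agreement between a reference
clustering (RC, computed on the complete matrix) and a generated
clustering (GC, after masking + imputation) is quantified by:

* CPP  — per-RC-cluster best-match overlap, as a percentage of genes;
* CPP_f — CPP relaxed to the best-matching GC cluster plus its f-1
  nearest neighbouring clusters (centroid proximity);
* CAR  — percentage of gene pairs concordant between RC and GC
  (co-clustered in both or separated in both): the Rand index x 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from ._nanops import pairwise_sq_dists
from .core import ExpressionMatrix, ValidationError

__all__ = [
    "Partition",
    "DistanceMatrix",
    "LINKAGES",
    "masked_euclidean_distance",
    "distance_matrix",
    "hierarchical_cluster",
    "kmeans_cluster",
    "cpp",
    "cpp_f",
    "car",
    "within_cluster_dispersion",
]

logger = logging.getLogger(__name__)

#: the seven agglomerative linkages, mapped to scipy method names
LINKAGES = {
    "single": "single",
    "complete": "complete",
    "average": "average",
    "mcquitty": "weighted",
    "median": "median",
    "centroid": "centroid",
    "ward": "ward",
}


@dataclass
class Partition:
    """Assignment of each gene to exactly one cluster (labels 0..K-1)."""

    labels: np.ndarray = field(repr=False)
    K: int
    source: str = "GC"
    algorithm: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) == 0:
            raise ValidationError("labels must be a non-empty 1-D array")
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        if self.labels.min() < 0 or self.labels.max() >= self.K:
            raise ValidationError("labels out of range 0..K-1")

    @property
    def n_genes(self) -> int:
        return len(self.labels)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative gene-gene distances with a zero diagonal."""

    values: np.ndarray = field(repr=False)
    n_undefined: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max() > 1e-12:
            raise ValidationError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValidationError("distances must be nonnegative")


def masked_euclidean_distance(v: np.ndarray, w: np.ndarray) -> float:
    """d* between two profiles; NaN when they share no observed coordinate."""
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValidationError("profiles must be 1-D and of equal length")
    n = len(v)
    both = np.isfinite(v) & np.isfinite(w)
    n_obs = int(both.sum())
    if n_obs == 0:
        return float("nan")
    diff = v[both] - w[both]
    return float(np.sqrt(n / n_obs * np.sum(diff * diff)))


def distance_matrix(m: ExpressionMatrix) -> DistanceMatrix:
    """All-pairs d*. Pairs with no shared observed coordinate get the
    matrix-wide maximum finite distance; their count is logged and
    recorded in ``n_undefined``."""
    n = m.n_conditions
    ssd, count = pairwise_sq_dists(m.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(n / count * ssd)
    undefined = count == 0
    np.fill_diagonal(undefined, False)
    n_undefined = int(undefined.sum()) // 2
    if n_undefined:
        finite_max = float(np.nanmax(np.where(undefined, np.nan, d)))
        d[undefined] = finite_max
        logger.warning(
            "%d gene pairs share no observed coordinate; substituted the "
            "maximum finite distance %.4g", n_undefined, finite_max,
        )
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # exact symmetry against round-off
    return DistanceMatrix(d, n_undefined=n_undefined)


def hierarchical_cluster(
    d: DistanceMatrix | np.ndarray,
    linkage: str,
    K: int,
    source: str = "GC",
) -> Partition:
    """Agglomerate with the named linkage and cut the tree to K clusters.

    Centroid/median linkages update on squared distances and Ward on the
    minimum-variance criterion (Lance-Williams recurrences).
    """
    if linkage not in LINKAGES:
        raise ValidationError(
            f"unknown linkage {linkage!r}; choose from {sorted(LINKAGES)}"
        )
    values = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, float)
    g = values.shape[0]
    if not 1 <= K <= g:
        raise ValidationError("K must be in 1..G")
    z = scipy_linkage(squareform(values, checks=False), method=LINKAGES[linkage])
    labels = fcluster(z, t=K, criterion="maxclust") - 1
    # compact labels in case maxclust returns fewer clusters than asked
    _, labels = np.unique(labels, return_inverse=True)
    return Partition(labels, K=int(labels.max()) + 1, source=source,
                     algorithm=linkage)


def kmeans_cluster(
    m: ExpressionMatrix,
    K: int,
    restarts: int = 10,
    seed: int = 0,
    source: str = "GC",
) -> Partition:
    """Euclidean k-means with seeded restarts; best inertia kept."""
    if not m.is_complete:
        raise ValidationError("k-means requires a complete matrix")
    if not 1 <= K <= m.n_genes:
        raise ValidationError("K must be in 1..G")
    km = KMeans(n_clusters=K, n_init=restarts, random_state=seed)
    labels = km.fit_predict(m.values)
    _, labels = np.unique(labels, return_inverse=True)
    return Partition(labels, K=int(labels.max()) + 1, source=source,
                     algorithm="kmeans")


# ----------------------------------------------------------------------
def _contingency(rc: Partition, gc: Partition) -> np.ndarray:
    if rc.n_genes != gc.n_genes:
        raise ValidationError("partitions cover different gene universes")
    table = np.zeros((rc.K, gc.K), dtype=np.int64)
    np.add.at(table, (rc.labels, gc.labels), 1)
    return table


def cpp(rc: Partition, gc: Partition) -> float:
    """Conserved Pairs Proportion: for each RC cluster, the genes in its
    best-matching GC cluster, summed and expressed as % of all genes."""
    table = _contingency(rc, gc)
    return float(100.0 * table.max(axis=1).sum() / rc.n_genes)


def cpp_f(
    rc: Partition, gc: Partition, m: ExpressionMatrix, f: int = 5
) -> float:
    """CPP relaxed to the union of the best-matching GC cluster and the
    f-1 GC clusters with the nearest centroids (mean profiles in ``m``)."""
    if f < 1:
        raise ValidationError("f must be >= 1")
    if not m.is_complete:
        raise ValidationError("cpp_f needs a complete (post-imputation) matrix")
    if m.n_genes != rc.n_genes:
        raise ValidationError("matrix and partitions cover different genes")
    table = _contingency(rc, gc)
    centroids = np.vstack([
        m.values[gc.labels == c].mean(axis=0) if (gc.labels == c).any()
        else np.full(m.n_conditions, np.inf)
        for c in range(gc.K)
    ])
    conserved = 0
    for c in range(rc.K):
        best = int(np.argmax(table[c]))  # ties -> smallest GC label
        dist = np.linalg.norm(centroids - centroids[best], axis=1)
        dist[best] = -np.inf  # best always first in the ranking
        ranking = np.lexsort((np.arange(gc.K), dist))
        union = set(int(c2) for c2 in ranking[:f])
        in_union = np.isin(gc.labels, list(union))
        conserved += int(((rc.labels == c) & in_union).sum())
    return float(100.0 * conserved / rc.n_genes)


def car(rc: Partition, gc: Partition) -> float:
    """Clustering Agreement Ratio: % of gene pairs co-clustered in both
    partitions or separated in both (Rand index x 100), by pair counting
    on the contingency table."""
    if rc.n_genes < 2:
        raise ValidationError("CAR needs at least 2 genes")
    table = _contingency(rc, gc)
    g = rc.n_genes
    total_pairs = g * (g - 1) // 2

    def pairs(x: np.ndarray) -> float:
        x = x.astype(np.int64)
        return float((x * (x - 1) // 2).sum())

    both_same = pairs(table.ravel())
    rc_same = pairs(table.sum(axis=1))
    gc_same = pairs(table.sum(axis=0))
    agreements = total_pairs + 2 * both_same - rc_same - gc_same
    return float(100.0 * agreements / total_pairs)


def within_cluster_dispersion(p: Partition, m: ExpressionMatrix) -> float:
    """Mean over clusters of the average squared distance of members to
    their centroid; used to match comparable K across algorithms."""
    if not m.is_complete:
        raise ValidationError("dispersion needs a complete matrix")
    if m.n_genes != p.n_genes:
        raise ValidationError("matrix and partition cover different genes")
    per_cluster = []
    for c in range(p.K):
        members = m.values[p.labels == c]
        if len(members) == 0:
            logger.warning("cluster %d is empty; excluded from dispersion", c)
            continue
        centroid = members.mean(axis=0)
        per_cluster.append(float(np.mean(np.sum((members - centroid) ** 2, axis=1))))
    return float(np.mean(per_cluster))
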