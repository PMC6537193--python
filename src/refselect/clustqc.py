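"""Internal clustering-quality indices for choosing the number of groups.

Three classical indices are computed on the same MDS embedding that the
k-means strategy clusters, so a single metric (correlation distance)
governs both the partition and its assessment:

* Dunn index — min inter-cluster point distance / max intra-cluster
  diameter; larger is better.
* Mean silhouette width — mean of (b - a) / max(a, b) per point; in
  [-1, 1], larger is better; points in singleton clusters score 0.
* Davies–Bouldin index — mean over clusters of the worst
  (scatter_i + scatter_j) / centroid-distance ratio; smaller is better.

``sweep_k`` runs k-means for each candidate k on a shared embedding and
recommends the k preferred by at least two of the three indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .depthio import DepthMatrix
from .selection import (
    MDSEmbedding,
    correlation_matrix,
    kmeans_labels,
    mds_embed,
)

__all__ = [
    "ClusteringQuality",
    "dunn_index",
    "silhouette_mean",
    "davies_bouldin",
    "sweep_k",
]


class ClusterIndexError(ValueError):
    pass


@dataclass(frozen=True)
class ClusteringQuality:
    k: int
    dunn: float
    silhouette_mean: float
    davies_bouldin: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.silhouette_mean <= 1.0 + 1e-9:
            raise ClusterIndexError("mean silhouette outside [-1, 1]")
        if self.dunn < 0 or self.davies_bouldin < 0:
            raise ClusterIndexError("Dunn and Davies-Bouldin must be non-negative")


def _check_labels(points: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1 and points.shape[1] > 1 and len(labels) == points.shape[1]:
        points = points.T
    labels = np.asarray(labels)
    if len(labels) != points.shape[0]:
        raise ClusterIndexError("labels length != number of points")
    groups = [np.nonzero(labels == lab)[0] for lab in np.unique(labels)]
    if len(groups) < 2:
        raise ClusterIndexError("need at least 2 clusters")
    return [points[g] for g in groups]


def dunn_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Min inter-cluster distance over max intra-cluster diameter.

    Singleton clusters contribute diameter 0; if every cluster is a
    singleton the index is undefined.
    """
    clusters = _check_labels(points, labels)
    diam = max(
        (pdist(c).max() if len(c) > 1 else 0.0) for c in clusters
    )
    if diam == 0.0:
        raise ClusterIndexError("Dunn undefined: all intra-cluster diameters are 0")
    inter = min(
        cdist(clusters[i], clusters[j]).min()
        for i in range(len(clusters))
        for j in range(i + 1, len(clusters))
    )
    return float(inter / diam)


def silhouette_mean(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width s(i) = (b - a) / max(a, b).

    a(i): mean distance to the other members of i's cluster (s = 0 for a
    singleton cluster); b(i): smallest mean distance to any other cluster.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 1 and pts.shape[1] > 1 and len(labels) == pts.shape[1]:
        pts = pts.T
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ClusterIndexError("silhouette needs at least 2 clusters")
    D = squareform(pdist(pts))
    scores = np.empty(pts.shape[0])
    for i in range(pts.shape[0]):
        own = np.nonzero(labels == labels[i])[0]
        if len(own) == 1:
            scores[i] = 0.0
            continue
        a = D[i, own[own != i]].mean()
        b = min(
            D[i, labels == lab].mean() for lab in uniq if lab != labels[i]
        )
        scores[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(scores.mean())


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters of the worst (σi + σj) / d(ci, cj) ratio.

    σ is the mean distance of a cluster's members to its centroid.
    Coincident centroids make the ratio undefined and raise an error.
    """
    clusters = _check_labels(points, labels)
    cents = np.array([c.mean(axis=0) for c in clusters])
    sig = np.array(
        [np.linalg.norm(c - ct, axis=1).mean() for c, ct in zip(clusters, cents)]
    )
    dcent = cdist(cents, cents)
    n = len(clusters)
    worst = np.empty(n)
    for i in range(n):
        ratios = []
        for j in range(n):
            if j == i:
                continue
            if dcent[i, j] == 0.0:
                raise ClusterIndexError(
                    f"DB undefined: clusters {i} and {j} have coincident centroids"
                )
            ratios.append((sig[i] + sig[j]) / dcent[i, j])
        worst[i] = max(ratios)
    return float(worst.mean())


def sweep_k(
    matrix: DepthMatrix,
    k_values: list[int],
    seed: int = 0,
    m: int | None = None,
    embedding: MDSEmbedding | None = None,
) -> tuple[list[ClusteringQuality], int]:
    """Score k-means partitions for each k and recommend one.

    All k values share a single MDS embedding and the same seed.  The
    recommendation is a 2-of-3 vote: the k maximising Dunn, the k
    maximising mean silhouette and the k minimising Davies–Bouldin each
    cast one vote (per-index ties go to the smallest k); a k with at
    least two votes wins, otherwise the smallest voted k is returned.
    """
    if not k_values:
        raise ClusterIndexError("empty list of k values")
    S = matrix.n_samples
    for k in k_values:
        if not 2 <= k <= S - 1:
            raise ClusterIndexError(f"k={k} outside [2, {S - 1}]")
    if embedding is None:
        corr = correlation_matrix(matrix)
        embedding = mds_embed(corr, m=min(m or 10, S - 1))
    pts = embedding.coordinates
    results: list[ClusteringQuality] = []
    for k in sorted(set(k_values)):
        labels = kmeans_labels(embedding, k, seed)
        try:
            dunn = dunn_index(pts, labels)
        except ClusterIndexError:
            dunn = 0.0
        results.append(
            ClusteringQuality(
                k=k,
                dunn=dunn,
                silhouette_mean=silhouette_mean(pts, labels),
                davies_bouldin=davies_bouldin(pts, labels),
            )
        )
    votes = [
        min(results, key=lambda q: (-q.dunn, q.k)).k,
        min(results, key=lambda q: (-q.silhouette_mean, q.k)).k,
        min(results, key=lambda q: (q.davies_bouldin, q.k)).k,
    ]
    for k in votes:
        if votes.count(k) >= 2:
            return results, k
    return results, min(votes)
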