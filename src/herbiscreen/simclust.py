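"""Similarity, hierarchical clustering and cluster-validation indices.

Structural similarity between fingerprints is the Tanimoto coefficient
TC = |A ∩ B| / |A ∪ B|; the corresponding dissimilarity is the Jaccard
distance 1 - TC. Compounds are grouped by variance-minimising (Ward)
agglomeration on the Jaccard distance matrix, and partitions are assessed
with the Dunn, Dunn2 and average-silhouette internal indices plus the
adjusted Rand index against reference labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.special import comb

from .errors import ValidationError


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray
    metric: str = "jaccard"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape must match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if (self.values < 0).any() or not np.allclose(np.diag(self.values), 0):
            raise ValidationError("distances must be non-negative with zero diagonal")
        if self.metric == "jaccard" and (self.values > 1 + 1e-12).any():
            raise ValidationError("jaccard distances must be <= 1")


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |A ∩ B| / |A ∪ B| between binary key vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("fingerprints must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValidationError("Tanimoto undefined for two empty fingerprints")
    return float(np.logical_and(a, b).sum() / union)


def jaccard_distance_matrix(bits: np.ndarray, ids: list[str] | None = None) -> DistanceMatrix:
    """All-pairs Jaccard distance (1 - TC) on a binary fingerprint matrix."""
    bits = np.asarray(bits, dtype=bool)
    if bits.ndim != 2 or bits.shape[0] == 0:
        raise ValidationError("need a non-empty 2-D bit matrix")
    if (bits.sum(axis=1) == 0).any():
        raise ValidationError("all-zero fingerprint row; Jaccard undefined")
    dist = squareform(pdist(bits, metric="jaccard"))
    ids = ids if ids is not None else [str(i) for i in range(bits.shape[0])]
    return DistanceMatrix(ids=ids, values=dist, metric="jaccard")


def min_jaccard_distance(query_bits: np.ndarray, training_bits: np.ndarray) -> float:
    """Minimum Jaccard distance from a query fingerprint to a training set."""
    training_bits = np.atleast_2d(np.asarray(training_bits, dtype=bool))
    if training_bits.shape[0] == 0:
        raise ValidationError("empty training set")
    query = np.asarray(query_bits, dtype=bool)
    if query.shape[-1] != training_bits.shape[1]:
        raise ValidationError("fingerprint length mismatch")
    dists = cdist(query.reshape(1, -1), training_bits, metric="jaccard")
    return float(dists.min())


def min_euclidean_distance(query: np.ndarray, training: np.ndarray) -> float:
    """Minimum Euclidean distance from a scaled query row to training rows."""
    training = np.atleast_2d(np.asarray(training, dtype=float))
    if training.shape[0] == 0:
        raise ValidationError("empty training set")
    query = np.asarray(query, dtype=float).reshape(1, -1)
    if query.shape[1] != training.shape[1]:
        raise ValidationError("descriptor dimension mismatch")
    return float(cdist(query, training, metric="euclidean").min())


def hierarchical_clusters(dist: DistanceMatrix, k: int) -> np.ndarray:
    """Partition into ``k`` clusters by Ward (squared-update) agglomeration.

    The Ward linkage is applied directly to the supplied dissimilarities
    (the ward.D2 convention for precomputed distance input). Labels are
    integers 1..k, deterministic for a given matrix.
    """
    n = len(dist.ids)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in 1..{n}, got {k}")
    if n == 1:
        return np.array([1])
    Z = linkage(squareform(dist.values, checks=False), method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def cluster_validation(dist: DistanceMatrix, labels) -> dict[str, float]:
    """Dunn, Dunn2 and average silhouette width for a partition.

    * Dunn: minimum between-cluster separation / maximum cluster diameter.
    * Dunn2: minimum average between-cluster dissimilarity / maximum average
      within-cluster dissimilarity.
    * silhouette: mean over points of (b - a) / max(a, b); members of
      singleton clusters score 0.
    """
    labels = np.asarray(labels)
    D = dist.values
    if labels.shape[0] != D.shape[0]:
        raise ValidationError("labels length must match distance matrix")
    clusters = [np.nonzero(labels == c)[0] for c in np.unique(labels)]
    if len(clusters) < 2:
        raise ValidationError("cluster validation needs at least 2 clusters")

    # Dunn / Dunn2 numerators and denominators
    min_sep = np.inf
    min_avg_between = np.inf
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            block = D[np.ix_(clusters[i], clusters[j])]
            min_sep = min(min_sep, block.min())
            min_avg_between = min(min_avg_between, block.mean())
    max_diam = 0.0
    max_avg_within = 0.0
    for members in clusters:
        if len(members) > 1:
            block = D[np.ix_(members, members)]
            max_diam = max(max_diam, block.max())
            m = len(members)
            max_avg_within = max(max_avg_within, block.sum() / (m * (m - 1)))
    dunn = min_sep / max_diam if max_diam > 0 else np.inf
    dunn2 = min_avg_between / max_avg_within if max_avg_within > 0 else np.inf

    # silhouette widths
    sil = np.zeros(len(labels))
    for idx in range(len(labels)):
        own = labels[idx]
        own_members = np.nonzero(labels == own)[0]
        if len(own_members) == 1:
            sil[idx] = 0.0
            continue
        a = D[idx, own_members[own_members != idx]].mean()
        b = min(
            D[idx, members].mean()
            for members, c in zip(clusters, np.unique(labels))
            if c != own
        )
        sil[idx] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return {"dunn": float(dunn), "dunn2": float(dunn2),
            "avg_silhouette": float(sil.mean())}


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    ARI = (index - expected) / (max_index - expected) on the contingency
    table of the two labelings; 1 for identical partitions (up to renaming),
    ~0 for independent ones.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("label vectors must be 1-D of equal length")
    n = a.shape[0]
    if n == 0:
        raise ValidationError("empty label vectors")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)
    sum_comb = comb(contingency, 2).sum()
    sum_rows = comb(contingency.sum(axis=1), 2).sum()
    sum_cols = comb(contingency.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_rows * sum_cols / total if total else 0.0
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:  # both partitions trivial (all-one-cluster etc.)
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))
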