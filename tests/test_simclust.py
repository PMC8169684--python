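"""Similarity measures, Ward clustering and validation indices."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

import herbiscreen as hs
from herbiscreen.errors import ValidationError
from herbiscreen.simclust import DistanceMatrix


def _bits(*on, n=8):
    v = np.zeros(n, dtype=np.uint8)
    for k in on:
        v[k] = 1
    return v


def _dist_1d(points):
    points = np.asarray(points, dtype=float)
    values = np.abs(points[:, None] - points[None, :])
    return DistanceMatrix(ids=[str(i) for i in range(len(points))],
                          values=values, metric="euclidean")


class TestTanimoto:
    def test_identical(self):
        assert hs.tanimoto(_bits(0, 3), _bits(0, 3)) == 1.0

    def test_disjoint(self):
        assert hs.tanimoto(_bits(0, 1), _bits(2, 3)) == 0.0

    def test_partial_overlap(self):
        assert hs.tanimoto(_bits(1, 2, 3), _bits(2, 3, 4)) == 0.5

    def test_both_empty_is_an_error(self):
        with pytest.raises(ValidationError):
            hs.tanimoto(_bits(), _bits())

    def test_one_minus_tc_is_a_metric_on_6bit_vectors(self):
        # triangle inequality checked exhaustively over all non-empty
        # 6-bit vectors
        vectors = np.array(
            [v for v in itertools.product([0, 1], repeat=6) if any(v)],
            dtype=bool,
        )
        n = len(vectors)
        inter = (vectors[:, None, :] & vectors[None, :, :]).sum(-1)
        union = (vectors[:, None, :] | vectors[None, :, :]).sum(-1)
        D = 1 - inter / union
        slack = D[:, :, None] + D[None, :, :].transpose(1, 0, 2) - D[:, None, :]
        assert (slack.min() >= -1e-12)


class TestMinDistances:
    def test_identical_training_compound(self):
        train = np.vstack([_bits(0, 1), _bits(2, 3)])
        assert hs.min_jaccard_distance(_bits(0, 1), train) == 0.0

    def test_disjoint_from_all(self):
        train = np.vstack([_bits(0), _bits(1)])
        assert hs.min_jaccard_distance(_bits(5, 6), train) == 1.0

    def test_minimum_over_training(self):
        # TC 0.5 and 0.7 -> distances 0.5 and 0.3 -> min 0.3
        query = _bits(*range(7), n=20)
        a = _bits(*range(0, 14), n=20)               # inter 7 / union 14
        b = _bits(*range(0, 7), 7, 8, 9, n=20)       # inter 7 / union 10
        assert hs.min_jaccard_distance(query, np.vstack([a, b])) == pytest.approx(0.3)

    def test_euclidean_examples(self):
        assert hs.min_euclidean_distance([3.0], np.array([[0.0], [5.0]])) == 2.0
        assert hs.min_euclidean_distance([0.0, 0.0], np.array([[0.0, 0.0]])) == 0.0

    def test_adding_a_training_point_never_increases_minimum(self, rng):
        query = rng.normal(size=3)
        train = rng.normal(size=(5, 3))
        before = hs.min_euclidean_distance(query, train)
        extended = np.vstack([train, rng.normal(size=3)])
        assert hs.min_euclidean_distance(query, extended) <= before

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            hs.min_jaccard_distance(_bits(0), np.zeros((0, 8)))


class TestHierarchicalClusters:
    def test_recovers_two_well_separated_groups(self):
        # brute-force oracle: the best 2-partition by within-cluster distance
        # sum is {0,1,2} vs {3,4,5} for this matrix
        n = 6
        values = np.full((n, n), 0.9)
        for i in range(n):
            values[i, i] = 0.0
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i in grp:
                for j in grp:
                    if i != j:
                        values[i, j] = 0.05
        dist = DistanceMatrix(ids=[str(i) for i in range(n)], values=values)
        labels = hs.hierarchical_clusters(dist, k=2)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_k_extremes(self):
        dist = _dist_1d([0.0, 1.0, 10.0, 11.0])
        assert len(set(hs.hierarchical_clusters(dist, k=4))) == 4
        assert len(set(hs.hierarchical_clusters(dist, k=1))) == 1

    def test_k_out_of_range(self):
        dist = _dist_1d([0.0, 1.0])
        with pytest.raises(ValidationError):
            hs.hierarchical_clusters(dist, k=3)


class TestClusterValidation:
    def test_toy_dunn_and_silhouette(self):
        dist = _dist_1d([0.0, 1.0, 10.0, 11.0])
        labels = [1, 1, 2, 2]
        out = hs.cluster_validation(dist, labels)
        # separation 9, max diameter 1
        assert out["dunn"] == pytest.approx(9.0)
        # hand-evaluated a(i)/b(i): mean of (9.5/10.5) and (8.5/9.5)
        assert out["avg_silhouette"] == pytest.approx(0.899749, abs=1e-6)
        # independent library oracle agrees
        assert out["avg_silhouette"] == pytest.approx(
            silhouette_score(dist.values, labels, metric="precomputed")
        )

    def test_duplicate_points_reach_silhouette_one(self):
        dist = _dist_1d([0.0, 0.0, 100.0, 100.0])
        out = hs.cluster_validation(dist, [1, 1, 2, 2])
        assert out["avg_silhouette"] == pytest.approx(1.0)

    def test_indices_increase_with_separation(self):
        previous = None
        for gap in [5.0, 10.0, 20.0, 40.0]:
            dist = _dist_1d([0.0, 1.0, gap, gap + 1.0])
            out = hs.cluster_validation(dist, [1, 1, 2, 2])
            if previous is not None:
                assert out["dunn"] > previous["dunn"]
                assert out["dunn2"] > previous["dunn2"]
            previous = out

    def test_single_cluster_rejected(self):
        dist = _dist_1d([0.0, 1.0])
        with pytest.raises(ValidationError):
            hs.cluster_validation(dist, [1, 1])


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        assert hs.adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_label_permutation_invariance(self):
        assert hs.adjusted_rand_index([1, 1, 2, 2], [7, 7, 3, 3]) == 1.0

    def test_chance_level_case(self):
        # contingency counting gives index == expected index here
        assert hs.adjusted_rand_index([1, 1, 2, 2], [1, 1, 1, 2]) == pytest.approx(0.0)

    def test_agrees_with_library_oracle(self, rng):
        for _ in range(20):
            a = rng.integers(0, 4, size=30)
            b = rng.integers(0, 3, size=30)
            assert hs.adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b)
            )

    def test_symmetric(self, rng):
        a = rng.integers(0, 3, size=25)
        b = rng.integers(0, 3, size=25)
        assert hs.adjusted_rand_index(a, b) == pytest.approx(
            hs.adjusted_rand_index(b, a)
        )

    def test_random_relabelling_has_mean_near_zero(self):
        rng = np.random.default_rng(42)
        a = np.repeat(np.arange(5), 10)
        values = []
        for _ in range(1000):
            values.append(hs.adjusted_rand_index(a, rng.permutation(a)))
        assert abs(np.mean(values)) < 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            hs.adjusted_rand_index([1, 2], [1, 2, 3])
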