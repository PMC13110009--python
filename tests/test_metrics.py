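"""Comparator metrics: hand instances, oracle equivalence, invariances."""

import numpy as np
import pytest
from scipy.spatial.distance import squareform, pdist

from dcimsi import (
    MetricConfig,
    centroid_distance_correlation,
    knn_accuracy,
    mean_dunn_index,
    random_triplet_accuracy,
    spearman_pairwise,
)
from dcimsi.errors import DegenerateInputError, ValidationError

from oracles import knn_accuracy_naive, triplet_scores_all

EUCLID = MetricConfig(high_metric="euclidean", low_metric="euclidean")


def rand_points(rng, n, d=2):
    return rng.uniform(0.1, 2.0, size=(n, d))


class TestKnnAccuracy:
    def test_identical_spaces(self):
        rng = np.random.default_rng(0)
        X = rand_points(rng, 30)
        cfg = MetricConfig(knn_k=5, high_metric="euclidean", low_metric="euclidean")
        assert knn_accuracy(X, X, cfg) == 1.0

    def test_all_neighbours_trivial(self):
        rng = np.random.default_rng(1)
        X, Y = rand_points(rng, 8), rand_points(rng, 8)
        cfg = MetricConfig(knn_k=7, high_metric="euclidean", low_metric="euclidean")
        assert knn_accuracy(X, Y, cfg) == 1.0

    def test_line_flip_hand_case(self):
        # every point's single nearest neighbour flips between the spaces
        high = np.array([[0.0], [1.0], [10.0]])
        low = np.array([[0.0], [10.0], [1.0]])
        cfg = MetricConfig(knn_k=1, high_metric="euclidean", low_metric="euclidean")
        value = knn_accuracy(high, low, cfg)
        oracle = knn_accuracy_naive(squareform(pdist(high)), squareform(pdist(low)), 1)
        assert value == oracle == 0.0

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(1, n - 1))
            high, low = rand_points(rng, n, 3), rand_points(rng, n, 2)
            cfg = MetricConfig(knn_k=k, high_metric="euclidean", low_metric="euclidean")
            expect = knn_accuracy_naive(squareform(pdist(high)), squareform(pdist(low)), k)
            assert knn_accuracy(high, low, cfg) == pytest.approx(expect, abs=1e-12)

    def test_n_too_small(self):
        with pytest.raises(ValidationError):
            knn_accuracy(np.zeros((3, 2)), np.zeros((3, 2)), MetricConfig(knn_k=5))


class TestTripletAccuracy:
    def test_isometry_gives_one(self):
        rng = np.random.default_rng(3)
        X = rand_points(rng, 20)
        shifted = X + 7.0
        cfg = MetricConfig(high_metric="euclidean", low_metric="euclidean", triplet_seed=0)
        assert random_triplet_accuracy(X, shifted, cfg) == 1.0

    def test_all_ties_give_half(self):
        rng = np.random.default_rng(4)
        X = rand_points(rng, 10)
        low = np.zeros((10, 2))
        cfg = MetricConfig(high_metric="euclidean", low_metric="euclidean")
        assert random_triplet_accuracy(X, low, cfg) == 0.5

    def test_sampled_score_within_exhaustive_spread(self):
        # the seeded sample average must agree with exhaustive enumeration
        # once enough triplets are drawn (law of large numbers on a finite set)
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(4, 7))
            high, low = rand_points(rng, n), rand_points(rng, n)
            exhaustive = triplet_scores_all(squareform(pdist(high)), squareform(pdist(low)))
            cfg = MetricConfig(triplets_per_point=400, triplet_seed=1,
                               high_metric="euclidean", low_metric="euclidean")
            sampled = random_triplet_accuracy(high, low, cfg)
            assert sampled == pytest.approx(exhaustive, abs=0.08)

    def test_rank_reversed_construction(self):
        # 1-D instances with exactly opposite distance orderings score the
        # exhaustively-enumerated value
        high = np.array([[0.0], [1.0], [3.0]])
        low = np.array([[0.0], [3.0], [4.0]])
        exhaustive = triplet_scores_all(squareform(pdist(high)), squareform(pdist(low)))
        cfg = MetricConfig(triplets_per_point=500, triplet_seed=2,
                           high_metric="euclidean", low_metric="euclidean")
        assert random_triplet_accuracy(high, low, cfg) == pytest.approx(exhaustive, abs=0.05)

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            random_triplet_accuracy(np.zeros((2, 2)), np.zeros((2, 2)))


class TestSpearmanPairwise:
    def test_isometric_low_space(self):
        rng = np.random.default_rng(6)
        X = rand_points(rng, 15)
        assert spearman_pairwise(X, X * 2.0 + 1.0, EUCLID) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        # low distance vector is a strictly increasing transform of the
        # high one (identical ranks), so the rank correlation is exactly 1
        high = np.array([[0.0], [2.0], [10.0]])  # distances (2, 10, 8)
        low = np.array([[0.0], [1.0], [3.0]])  # distances (1, 3, 2): same ranks
        from scipy.stats import rankdata

        assert np.all(rankdata(pdist(high)) == rankdata(pdist(low)))
        assert spearman_pairwise(high, low, EUCLID) == pytest.approx(1.0)

    def test_rank_reversal(self):
        # high distances rank (1,3,2); low triangle with distances
        # (4, 1, 3.5) ranks (3,1,2) — exactly reversed -> rho = -1
        high = np.array([[0.0], [1.0], [3.0]])
        x = 0.59375  # from |AC|=1, |BC|=3.5, |AB|=4
        low = np.array([[0.0, 0.0], [4.0, 0.0], [x, np.sqrt(1 - x**2)]])
        dh, dl = pdist(high), pdist(low)
        from scipy.stats import rankdata

        assert np.all(rankdata(dh) + rankdata(dl) == 4.0)
        assert spearman_pairwise(high, low, EUCLID) == pytest.approx(-1.0)

    def test_constant_distances_rejected(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])  # equilateral
        rng = np.random.default_rng(8)
        with pytest.raises(DegenerateInputError):
            spearman_pairwise(X, rand_points(rng, 3), EUCLID)


class TestCentroidDistanceCorrelation:
    def test_rigid_rotation_of_centroids(self):
        rng = np.random.default_rng(9)
        labels = np.repeat(np.arange(4), 10)
        high = rand_points(rng, 40, 3) + 3.0 * labels[:, None]
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        low = high @ R.T
        cfg = MetricConfig(high_metric="euclidean", low_metric="euclidean")
        assert centroid_distance_correlation(high, low, labels, cfg) == pytest.approx(1.0)

    def test_hand_rank_instance(self):
        # centroid distances (1,2,3) vs (3,1,2) -> Spearman -0.5
        high = np.array([[0.0], [1.0], [-2.0]])
        low = np.array([[0.0], [3.0], [1.0]])
        labels = np.array([0, 1, 2])
        np.testing.assert_allclose(pdist(high), [1.0, 2.0, 3.0])
        np.testing.assert_allclose(pdist(low), [3.0, 1.0, 2.0])
        cfg = MetricConfig(high_metric="euclidean", low_metric="euclidean")
        assert centroid_distance_correlation(high, low, labels, cfg) == pytest.approx(-0.5)

    def test_needs_three_classes(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValidationError):
            centroid_distance_correlation(X, X, np.array([0, 0, 1, 1]))


class TestMeanDunn:
    def test_two_cluster_hand_instance(self):
        low = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        labels = np.array([0, 0, 1, 1])
        expected = (20 + 2 * np.sqrt(101)) / 4  # mean inter / intra mean (=1)
        assert mean_dunn_index(low, labels) == pytest.approx(expected)
        assert expected == pytest.approx(10.025, abs=5e-4)

    def test_coincident_points_rejected(self):
        low = np.zeros((4, 2))
        with pytest.raises(DegenerateInputError):
            mean_dunn_index(low, np.array([0, 0, 1, 1]))

    def test_singleton_class_rejected(self):
        low = np.arange(6.0).reshape(3, 2)
        with pytest.raises(DegenerateInputError, match="1"):
            mean_dunn_index(low, np.array([0, 0, 1]))

    def test_shuffled_labels_near_one(self):
        # permutation null on a symmetric two-blob dataset
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal([8, 0], 1, (100, 2))])
        ratios = []
        for _ in range(30):
            labels = rng.permutation(np.repeat([0, 1], 100))
            ratios.append(mean_dunn_index(X, labels))
        assert np.median(ratios) == pytest.approx(1.0, abs=0.05)

    def test_true_labels_separate(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal([8, 0], 1, (50, 2))])
        assert mean_dunn_index(X, np.repeat([0, 1], 50)) > 1.0


class TestInvariances:
    def test_scale_invariance_of_all_metrics(self):
        rng = np.random.default_rng(12)
        high, low = rand_points(rng, 24, 4), rand_points(rng, 24, 3)
        labels = np.repeat(np.arange(4), 6)
        cfg = MetricConfig(knn_k=4, triplet_seed=3)
        scaled = 10.0 * low
        assert knn_accuracy(high, low, cfg) == knn_accuracy(high, scaled, cfg)
        assert random_triplet_accuracy(high, low, cfg) == random_triplet_accuracy(high, scaled, cfg)
        assert spearman_pairwise(high, low, cfg) == pytest.approx(
            spearman_pairwise(high, scaled, cfg), abs=1e-12
        )
        assert centroid_distance_correlation(high, low, labels, cfg) == pytest.approx(
            centroid_distance_correlation(high, scaled, labels, cfg), abs=1e-12
        )
        assert mean_dunn_index(low, labels, cfg) == pytest.approx(
            mean_dunn_index(scaled, labels, cfg), rel=1e-12
        )

    def test_subsample_restricts_computation(self):
        rng = np.random.default_rng(13)
        high, low = rand_points(rng, 40, 4), rand_points(rng, 40, 3)
        idx = np.arange(0, 40, 2)
        cfg = MetricConfig(knn_k=3, subsample=idx,
                           high_metric="euclidean", low_metric="euclidean")
        direct = MetricConfig(knn_k=3, high_metric="euclidean", low_metric="euclidean")
        assert knn_accuracy(high, low, cfg) == knn_accuracy(high[idx], low[idx], direct)
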