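"""K-medoids: brute-force optimality oracle, silhouette, k-selection, profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import catchvuln as cv
from catchvuln.clustering import standardize
from catchvuln.registry import variable_names


def brute_force_pam(D, k):
    """Exhaustive search over all medoid subsets: the global optimum."""
    n = len(D)
    best = np.inf
    for subset in itertools.combinations(range(n), k):
        cost = D[:, subset].min(axis=1).sum()
        best = min(best, cost)
    return best


def blobs(rng, centers, n_per, spread=0.05):
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(rng.normal(loc=c, scale=spread, size=(n_per, len(c))))
        labels += [i] * n_per
    return np.vstack(pts), np.array(labels)


class TestPam:
    def test_k_equals_n(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        res = cv.pam_cluster(X, k=6)
        assert res.total_dissimilarity == 0.0
        assert sorted(res.medoid_indices) == list(range(6))

    def test_two_separated_blobs(self):
        rng = np.random.default_rng(1)
        X, truth = blobs(rng, [(0, 0), (10, 10)], 20)
        res = cv.pam_cluster(X, k=2)
        # labels partition exactly by blob (up to label permutation)
        groups = [set(np.where(res.labels == j)[0]) for j in range(2)]
        expected = [set(range(20)), set(range(20, 40))]
        assert groups in ([expected[0], expected[1]], [expected[1], expected[0]])

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_optimum_small(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 9))
        k = int(rng.integers(2, 4))
        X = rng.normal(size=(n, 2))
        D = squareform(pdist(X))
        res = cv.pam_cluster(None, k, precomputed=D)
        assert res.total_dissimilarity == pytest.approx(brute_force_pam(D, k))

    def test_k_out_of_range(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError):
            cv.pam_cluster(X, k=1)
        with pytest.raises(ValueError):
            cv.pam_cluster(X, k=6)

    def test_constant_column_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError):
            cv.pam_cluster(X, k=2)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 4))
        a = cv.pam_cluster(X, k=3)
        b = cv.pam_cluster(X, k=3)
        assert (a.labels == b.labels).all()
        assert a.total_dissimilarity == b.total_dissimilarity


class TestSilhouette:
    def test_two_tight_far_pairs_approach_one(self):
        X = np.array([[0.0], [0.01], [100.0], [100.01]])
        D = squareform(pdist(X))
        s = cv.average_silhouette(np.array([0, 0, 1, 1]), D)
        assert s > 0.999

    def test_hand_listed_distances(self):
        # 4 points, clusters {0,1} and {2,3}; hand-computed (b-a)/max(a,b)
        D = np.array(
            [
                [0.0, 2.0, 6.0, 8.0],
                [2.0, 0.0, 5.0, 7.0],
                [6.0, 5.0, 0.0, 3.0],
                [8.0, 7.0, 3.0, 0.0],
            ]
        )
        labels = np.array([0, 0, 1, 1])
        # point 0: a=2, b=(6+8)/2=7   -> 5/7
        # point 1: a=2, b=(5+7)/2=6   -> 4/6
        # point 2: a=3, b=(6+5)/2=5.5 -> 2.5/5.5
        # point 3: a=3, b=(8+7)/2=7.5 -> 4.5/7.5
        expected = np.mean([5 / 7, 4 / 6, 2.5 / 5.5, 4.5 / 7.5])
        assert cv.average_silhouette(labels, D) == pytest.approx(expected)

    def test_identical_points_give_zero(self):
        D = np.zeros((4, 4))
        assert cv.average_silhouette(np.array([0, 0, 1, 1]), D) == 0.0

    def test_single_cluster_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            cv.average_silhouette(np.array([0, 0, 0]), D)

    def test_matches_sklearn(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 3))
        res = cv.pam_cluster(X, k=3)
        D = squareform(pdist(standardize(X)))
        assert cv.average_silhouette(res.labels, D) == pytest.approx(
            silhouette_score(D, res.labels, metric="precomputed")
        )

    def test_bounds(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            X = rng.normal(size=(20, 2))
            res = cv.pam_cluster(X, k=int(rng.integers(2, 6)))
            assert -1.0 <= res.avg_silhouette <= 1.0


class TestSelectK:
    def test_three_planted_blobs(self):
        rng = np.random.default_rng(9)
        X, truth = blobs(rng, [(0, 0), (10, 0), (0, 10)], 15)
        k, res = cv.select_k(X, range(2, 7))
        assert k == 3
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_singleton_range(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(12, 2))
        k, res = cv.select_k(X, [2])
        assert k == 2 and res.k == 2

    def test_argmax_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(25, 3))
        sils = {k: cv.pam_cluster(X, k).avg_silhouette for k in range(2, 7)}
        k_star, _ = cv.select_k(X, range(2, 7))
        best = max(sils.values())
        assert sils[k_star] == pytest.approx(best)
        assert k_star == min(k for k, s in sils.items() if s >= best - 1e-12)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            cv.select_k(np.random.default_rng(0).normal(size=(10, 2)), [])


class TestProfiles:
    def test_single_cluster_equals_global_means(self, catchment_table):
        names = [v for v in variable_names() if not v.endswith("_proximity")]
        X = catchment_table[names].to_numpy(dtype=float)
        res = cv.pam_cluster(X, k=2)
        one = cv.ClusterResult(1, res.medoid_indices[:1],
                               np.zeros(len(X), dtype=int), 0.0, 0.0)
        prof = cv.cluster_profiles(one, catchment_table)
        for name in names:
            assert prof.loc[0, name] == pytest.approx(catchment_table[name].mean())

    def test_size_weighted_profiles_recompose_global_means(self, catchment_table):
        names = [v for v in variable_names() if not v.endswith("_proximity")]
        X = catchment_table[names].to_numpy(dtype=float)
        res = cv.pam_cluster(X, k=4)
        prof = cv.cluster_profiles(res, catchment_table)
        assert (prof["n"] >= 1).all()
        total = prof["n"].sum()
        for name in names:
            recomposed = (prof[name] * prof["n"]).sum() / total
            assert recomposed == pytest.approx(catchment_table[name].mean())

    def test_label_table_mismatch(self, catchment_table):
        res = cv.ClusterResult(2, np.array([0, 1]), np.array([0, 1]), 0.0, 0.0)
        with pytest.raises(ValueError):
            cv.cluster_profiles(res, catchment_table)
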