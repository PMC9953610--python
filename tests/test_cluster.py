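"""Lloyd k-means, WCSS/SSB, silhouette and the k/D selection rules."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import silhouette_samples

from phenopet.cluster import (
    ScanCurve,
    elbow_scan,
    kmeans,
    select_D,
    select_k,
    silhouette,
    smallest_within_margin,
    ssb,
    wcss,
)

FOUR_POINTS = np.array([0.0, 1.0, 10.0, 11.0])


def three_blob_data(seed=0, n_per=40, sep=8.0):
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [sep, 0], [0, sep]], dtype=float)
    X = np.vstack([c + rng.normal(0, 1.0, size=(n_per, 2)) for c in centers])
    labels = np.repeat([0, 1, 2], n_per)
    return X, labels


class TestKmeans:
    def test_two_pairs_in_one_dimension(self):
        res = kmeans(FOUR_POINTS, 2, seed=0)
        assert sorted(res.centroids.ravel()) == [0.5, 10.5]
        assert res.wcss == pytest.approx(1.0)
        assert res.labels[0] == res.labels[1] != res.labels[2] == res.labels[3]

    def test_k_equals_n_gives_zero_wcss(self):
        res = kmeans(FOUR_POINTS, 4, seed=0, compute_silhouette=False)
        assert res.wcss == pytest.approx(0.0)

    def test_k_one_centroid_is_global_mean(self):
        res = kmeans(FOUR_POINTS, 1, seed=0)
        assert res.centroids.ravel()[0] == pytest.approx(5.5)
        assert res.wcss == pytest.approx(np.sum((FOUR_POINTS - 5.5) ** 2))
        assert res.ssb == pytest.approx(0.0)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans(FOUR_POINTS, 5)

    def test_determinism_and_size_canonical_labels(self):
        X, _ = three_blob_data(3, n_per=30)
        r1 = kmeans(X, 3, seed=42)
        r2 = kmeans(X, 3, seed=42)
        assert np.array_equal(r1.labels, r2.labels)
        sizes = np.bincount(r1.labels)
        assert np.all(np.diff(sizes) <= 0)  # descending cluster size

    def test_centroids_are_cluster_means(self):
        X, _ = three_blob_data(5)
        res = kmeans(X, 3, seed=1)
        for c in range(3):
            assert np.allclose(res.centroids[c], X[res.labels == c].mean(axis=0))

    def test_best_of_restarts_attains_enumeration_optimum_small_n(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            X = rng.random((8, 2))
            k = 3
            best = min(
                wcss(X, np.array(assign), _centroids(X, assign, k))
                for assign in itertools.product(range(k), repeat=len(X))
                if len(set(assign)) == k
            )
            res = kmeans(X, k, n_init=50, seed=trial, compute_silhouette=False)
            assert res.wcss == pytest.approx(best, abs=1e-9)

    def test_kmeanspp_init_also_converges(self):
        X, truth = three_blob_data(11)
        res = kmeans(X, 3, seed=2, init="k-means++")
        assert res.wcss <= wcss(X, truth, _centroids(X, truth, 3)) * 1.01


def _centroids(X, assign, k):
    assign = np.asarray(assign)
    return np.vstack([
        X[assign == c].mean(axis=0) if np.any(assign == c) else np.zeros(X.shape[1])
        for c in range(k)
    ])


class TestMetrics:
    def test_wcss_hand_value(self):
        labels = np.array([0, 0, 1, 1])
        cents = np.array([[0.5], [10.5]])
        assert wcss(FOUR_POINTS[:, None], labels, cents) == pytest.approx(1.0)

    def test_wcss_zero_when_points_equal_centroids(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert wcss(X, np.array([0, 1]), X) == 0.0

    def test_wcss_matches_double_loop(self):
        rng = np.random.default_rng(12)
        X = rng.random((20, 3))
        labels = rng.integers(0, 3, 20)
        cents = _centroids(X, labels, 3)
        slow = sum(
            float(np.sum((X[i] - cents[labels[i]]) ** 2)) for i in range(20)
        )
        assert wcss(X, labels, cents) == pytest.approx(slow, rel=1e-12)

    def test_ssb_hand_values_and_decomposition(self):
        # centroids 0.5, 10.5; global mean 5.5
        cents = np.array([[0.5], [10.5]])
        ga = np.array([5.5])
        assert ssb(cents, ga) == pytest.approx(50.0)
        assert ssb(cents, ga, [2, 2], weighted=True) == pytest.approx(100.0)
        total_ss = float(np.sum((FOUR_POINTS - 5.5) ** 2))
        assert 1.0 + 100.0 == pytest.approx(total_ss)  # WCSS + SSB_w = total SS

    def test_variance_decomposition_on_random_clusterings(self):
        rng = np.random.default_rng(13)
        for k in (2, 3, 5):
            X = rng.normal(size=(40, 4))
            res = kmeans(X, k, seed=int(k), compute_silhouette=False)
            total_ss = float(np.sum((X - X.mean(axis=0)) ** 2))
            assert res.wcss + res.ssb_weighted == pytest.approx(total_ss, abs=1e-9)


class TestSilhouette:
    def test_hand_computed_four_points(self):
        labels = np.array([0, 0, 1, 1])
        per_point, mean = silhouette(FOUR_POINTS[:, None], labels)
        # s(0): a = 1, b = (10 + 11)/2 = 10.5 -> (10.5 - 1)/10.5
        # s(1): a = 1, b = (9 + 10)/2 = 9.5  -> (9.5 - 1)/9.5
        s0, s1 = (10.5 - 1) / 10.5, (9.5 - 1) / 9.5
        assert per_point[0] == pytest.approx(s0)
        assert per_point[1] == pytest.approx(s1)
        assert mean == pytest.approx((s0 + s1) / 2)  # outer/inner pairs symmetric

    def test_coincident_clusters_score_non_positive(self):
        # two clusters occupying identical positions: no separation at all
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        X = np.vstack([pts, pts])
        labels = np.repeat([0, 1], 3)
        _, mean = silhouette(X, labels)
        assert mean <= 0.0

    def test_bounds_and_sklearn_agreement(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(50, 3))
        labels = rng.integers(0, 4, 50)
        per_point, _ = silhouette(X, labels)
        assert np.all(per_point >= -1) and np.all(per_point <= 1)
        assert np.allclose(per_point, silhouette_samples(X, labels), atol=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(FOUR_POINTS[:, None], np.zeros(4, dtype=int))


class TestScans:
    def test_elbow_on_three_blobs(self):
        X, _ = three_blob_data(21)
        curve = elbow_scan(X, range(1, 9), seed=5)
        assert curve.wcss[0] == pytest.approx(np.sum((X - X.mean(0)) ** 2))
        assert np.all(np.diff(curve.wcss) <= 1e-9)
        assert select_k(curve) == 3

    def test_scan_determinism(self):
        X, _ = three_blob_data(22)
        c1 = elbow_scan(X, range(1, 7), seed=9)
        c2 = elbow_scan(X, range(1, 7), seed=9)
        assert np.array_equal(c1.wcss, c2.wcss)

    def test_select_k_piecewise_linear_breakpoint(self):
        ks = np.arange(1, 8)
        w = np.where(ks <= 3, 100.0 - 30 * (ks - 1), 40.0 - 2.0 * (ks - 3))
        curve = ScanCurve(ks, w, np.zeros(7), np.full(7, np.nan))
        assert select_k(curve) == 3

    def test_select_k_flat_curve_falls_back_to_silhouette(self):
        ks = np.arange(1, 7)
        w = 100.0 - 10.0 * (ks - 1)  # strictly linear: zero curvature
        sil = np.array([np.nan, 0.2, 0.5, 0.4, 0.3, 0.2])
        curve = ScanCurve(ks, w, np.zeros(6), sil)
        with pytest.warns(RuntimeWarning, match="flat"):
            assert select_k(curve) == 3


class TestSelectD:
    def test_published_silhouette_pair_selects_two_dimensions(self):
        # decision fixture: silhouettes 0.563 (D=2) vs 0.3217 (D=3)
        assert smallest_within_margin({2: 0.563, 3: 0.3217}) == 2

    def test_equal_scores_prefer_smaller_dimension(self):
        assert smallest_within_margin({2: 0.5, 3: 0.5}) == 2

    def test_single_candidate_returned(self):
        assert smallest_within_margin({4: 0.1}) == 4

    def test_select_d_runs_pipeline_embeddings(self):
        X, _ = three_blob_data(30, n_per=25)

        def embed_fn(X_, D_):  # deterministic stand-in embedding: PCA-like
            Xc = X_ - X_.mean(0)
            _, _, vt = np.linalg.svd(Xc, full_matrices=False)
            return Xc @ vt[:D_].T

        D, scores = select_D(X, embed_fn, [1, 2], 3, seed=0)
        assert set(scores) == {1, 2}
        assert D == min(d for d, s in scores.items() if s >= max(scores.values()) - 1e-12)


class TestDecompositionProperty:
    """WCSS + weighted SSB = total SS for arbitrary data and any k."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @staticmethod
    @given(
        seed=st.integers(0, 2**16),
        n=st.integers(6, 25),
        dim=st.integers(1, 4),
        k=st.integers(1, 4),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_holds_for_random_instances(seed, n, dim, k):
        rng = np.random.default_rng(seed)
        X = rng.normal(scale=rng.uniform(0.1, 10), size=(n, dim))
        res = kmeans(X, min(k, n), seed=seed, compute_silhouette=False)
        total_ss = float(np.sum((X - X.mean(axis=0)) ** 2))
        assert res.wcss + res.ssb_weighted == pytest.approx(
            total_ss, abs=1e-9 * max(total_ss, 1.0)
        )
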