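"""t-SNE (affinities + descent), ISOMAP (Floyd-Warshall + MDS), UMAP contract."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from phenopet.cluster import silhouette
from phenopet.manifold import (
    classical_mds,
    floyd_warshall,
    isomap_embed,
    kl_divergence,
    knn_graph,
    min_connected_neighbors,
    tsne_affinities,
    tsne_embed,
    umap_embed,
)


def brute_force_affinities(X, perplexity):
    """Independent loop-based evaluation: bisect sigma per point, symmetrise."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    P_cond = np.zeros((n, n))
    for i in range(n):
        d2 = np.array([np.sum((X[i] - X[j]) ** 2) for j in range(n) if j != i])

        def entropy_bits(sigma):
            w = np.exp(-d2 / (2 * sigma**2))
            p = w / w.sum()
            nz = p[p > 0]
            return -np.sum(nz * np.log2(nz))

        lo, hi = 1e-12, 1e12
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if entropy_bits(mid) > np.log2(perplexity):
                hi = mid
            else:
                lo = mid
        sigma = np.sqrt(lo * hi)
        w = np.exp(-d2 / (2 * sigma**2))
        p = w / w.sum()
        P_cond[i, [j for j in range(n) if j != i]] = p
    return (P_cond + P_cond.T) / (2 * n)


def two_blob_data(seed=0, n_per=10, dim=20, sep=25.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, dim))
    b = rng.normal(0, 1, size=(n_per, dim))
    b[:, 0] += sep
    return np.vstack([a, b]), np.repeat([0, 1], n_per)


class TestAffinities:
    @pytest.mark.parametrize("perplexity", [1.5, 2.0, 2.9])
    def test_equilateral_points_give_uniform_affinities(self, perplexity):
        # simplex vertices: all squared distances exactly 2 in floating point
        X = np.eye(3)
        aff = tsne_affinities(X, perplexity=perplexity)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(aff.P[off], 1 / 6, atol=1e-9)

    def test_collinear_points_match_brute_force(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        aff = tsne_affinities(X, perplexity=2.0)
        expected = brute_force_affinities(X, 2.0)
        assert np.allclose(aff.P, expected, atol=1e-9)

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(4)
        for n, perp in [(7, 3.0), (10, 5.0)]:
            X = rng.normal(size=(n, 4))
            aff = tsne_affinities(X, perplexity=perp)
            assert np.allclose(aff.P, brute_force_affinities(X, perp), atol=1e-9)

    def test_normalisation_and_achieved_perplexity(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 6))
        aff = tsne_affinities(X, perplexity=8.0)
        assert aff.P.sum() == pytest.approx(1.0, abs=1e-9)
        # per-point achieved perplexity from the conditional distributions
        n = len(X)
        D2 = squareform(pdist(X, "sqeuclidean"))
        for i in range(n):
            beta = 1.0 / (2 * aff.sigmas[i] ** 2)
            w = np.exp(-np.delete(D2[i], i) * beta)
            p = w / w.sum()
            achieved = 2 ** (-np.sum(p * np.log2(p)))
            assert achieved == pytest.approx(8.0, abs=1e-3)

    def test_preconditions(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="perplexity"):
            tsne_affinities(np.random.default_rng(0).normal(size=(5, 2)), perplexity=5)
        with pytest.warns(RuntimeWarning, match="duplicate"):
            tsne_affinities(X, perplexity=2)


class TestTsneEmbed:
    def test_zero_iterations_returns_initialisation(self):
        X = np.random.default_rng(6).normal(size=(12, 5))
        emb = tsne_embed(X, D=2, n_iter=0, perplexity=5.0, seed=3)
        ref = np.random.default_rng(3).normal(0, 1e-4, size=(12, 2))
        assert np.array_equal(emb.Y, ref)
        assert emb.objective == emb.params["initial_kl"]

    def test_final_kl_not_above_initial(self):
        X, _ = two_blob_data(7)
        emb = tsne_embed(X, D=2, n_iter=400, perplexity=8.0, seed=1)
        assert emb.objective <= emb.params["initial_kl"]
        assert emb.objective >= 0  # Gibbs' inequality

    def test_separated_blobs_stay_separable(self):
        X, labels = two_blob_data(8)
        emb = tsne_embed(X, D=2, perplexity=8.0, seed=2)
        _, sil = silhouette(emb.Y, labels)
        assert sil > 0.5

    def test_seeded_determinism(self):
        X, _ = two_blob_data(9)
        e1 = tsne_embed(X, D=2, n_iter=300, perplexity=8.0, seed=11)
        e2 = tsne_embed(X, D=2, n_iter=300, perplexity=8.0, seed=11)
        assert np.array_equal(e1.Y, e2.Y)

    def test_translation_invariance(self):
        # affinities depend on pairwise distances only, so a global shift of
        # the input leaves P (to FP round-off) and hence the map unchanged;
        # the gradient-descent check uses a short horizon because round-off
        # differences grow along the trajectory
        X, _ = two_blob_data(10, n_per=8)
        a1 = tsne_affinities(X, perplexity=5.0)
        a2 = tsne_affinities(X + 113.0, perplexity=5.0)
        assert np.allclose(a1.P, a2.P, atol=1e-8)
        e1 = tsne_embed(X, D=2, n_iter=10, perplexity=5.0, seed=4)
        e2 = tsne_embed(X + 113.0, D=2, n_iter=10, perplexity=5.0, seed=4)
        assert np.allclose(e1.Y, e2.Y, atol=1e-6)

    def test_isomap_translation_invariance_up_to_rigid_motion(self):
        X, _ = two_blob_data(12, n_per=8, dim=4)
        e1 = isomap_embed(X, D=2, n_neighbors="auto")
        e2 = isomap_embed(X + 50.0, D=2, n_neighbors="auto")
        d1 = squareform(pdist(e1.Y))
        d2 = squareform(pdist(e2.Y))
        assert np.allclose(d1, d2, atol=1e-7)


class TestFloydWarshall:
    def test_path_graph_geodesics(self):
        n = 4
        G = np.full((n, n), np.inf)
        np.fill_diagonal(G, 0.0)
        for i in range(n - 1):
            G[i, i + 1] = G[i + 1, i] = 1.0
        geo = floyd_warshall(G)
        expected = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        assert np.array_equal(geo, expected)

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(15)
        n = 6
        G = np.full((n, n), np.inf)
        np.fill_diagonal(G, 0.0)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.6:
                    G[i, j] = G[j, i] = rng.uniform(0.1, 2.0)
        geo = floyd_warshall(G)

        def shortest_by_enumeration(a, b):
            best = G[a, b]
            others = [v for v in range(n) if v not in (a, b)]
            for r in range(1, len(others) + 1):
                for mids in itertools.permutations(others, r):
                    path = (a, *mids, b)
                    length = sum(G[path[i], path[i + 1]] for i in range(len(path) - 1))
                    best = min(best, length)
            return best

        for a in range(n):
            for b in range(n):
                if a == b:
                    continue
                expected = shortest_by_enumeration(a, b)
                if np.isinf(expected):
                    assert np.isinf(geo[a, b])
                else:
                    assert geo[a, b] == pytest.approx(expected, abs=1e-12)


class TestClassicalMds:
    def test_unit_square_recovered_up_to_rigid_motion(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        D = squareform(pdist(pts))
        Y = classical_mds(D, 2)
        assert np.allclose(squareform(pdist(Y)), D, atol=1e-9)

    def test_collinear_points_in_one_dimension(self):
        x = np.array([0.0, 1.0, 2.5, 7.0])
        D = np.abs(np.subtract.outer(x, x))
        Y = classical_mds(D, 1).ravel()
        # recovered up to sign and shift
        d = np.abs(np.subtract.outer(Y, Y))
        assert np.allclose(d, D, atol=1e-9)

    def test_random_euclidean_configuration_exact(self):
        rng = np.random.default_rng(16)
        pts = rng.normal(size=(6, 3))
        D = squareform(pdist(pts))
        Y = classical_mds(D, 3)
        assert np.allclose(squareform(pdist(Y)), D, atol=1e-9)

    def test_asymmetric_input_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            classical_mds(D, 1)

    def test_non_euclidean_truncation_warns(self):
        # violates the triangle inequality strongly -> a negative eigenvalue
        # enters the requested components and is truncated
        D = np.array(
            [[0, 10, 1, 1], [10, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]], dtype=float
        )
        with pytest.warns(RuntimeWarning, match="negative"):
            Y = classical_mds(D, 4)
        assert np.all(np.isfinite(Y))


class TestIsomap:
    def test_flat_data_distances_preserved(self):
        # points on a 2-D affine subspace of 10-D space
        rng = np.random.default_rng(17)
        basis = np.linalg.qr(rng.normal(size=(10, 2)))[0]
        coords = rng.normal(size=(30, 2)) * 3
        X = coords @ basis.T + 5.0
        emb = isomap_embed(X, D=2, n_neighbors=29)  # dense graph: geodesic = Euclidean
        orig = squareform(pdist(X))
        assert np.allclose(squareform(pdist(emb.Y)), orig, atol=1e-6)

    def test_disconnected_graph_reports_component_sizes(self):
        X = np.vstack([np.zeros((4, 2)), np.full((5, 2), 100.0)])
        X += np.random.default_rng(18).normal(0, 0.01, X.shape)
        with pytest.raises(ValueError, match=r"\[5, 4\]"):
            isomap_embed(X, D=2, n_neighbors=2)

    def test_auto_neighbors_connects_clustered_data(self):
        X, labels = two_blob_data(19, n_per=12, dim=5)
        k = min_connected_neighbors(X)
        G = knn_graph(X, k)
        assert np.all(np.isfinite(floyd_warshall(G)))
        emb = isomap_embed(X, D=2, n_neighbors="auto")
        _, sil = silhouette(emb.Y, labels)
        assert sil > 0.5


class TestUmap:
    def test_blob_separability_and_determinism(self):
        X, labels = two_blob_data(20, n_per=15)
        e1 = umap_embed(X, D=2, n_neighbors=8, seed=7)
        _, sil = silhouette(e1.Y, labels)
        assert sil > 0.5
        e2 = umap_embed(X, D=2, n_neighbors=8, seed=7)
        assert np.array_equal(e1.Y, e2.Y)

    def test_neighbor_count_precondition(self):
        X = np.random.default_rng(21).normal(size=(10, 3))
        with pytest.raises(ValueError, match="n_neighbors"):
            umap_embed(X, D=2, n_neighbors=10)
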