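"""Manifold embeddings of the SUVR feature matrix.

Three nonlinear dimensionality reductions are crossed into the phenotyping
pipelines:

* **t-SNE** — implemented here from first principles: Gaussian conditional
  affinities with per-point bandwidths found by bisection on the perplexity
  (2^entropy of the neighbour distribution), symmetrised and normalised;
  Student-t low-dimensional similarities; KL(P||Q) minimised by gradient
  descent with momentum, adaptive gains and early exaggeration.
* **ISOMAP** — Euclidean k-NN graph, all-pairs geodesics by the Floyd-Warshall
  algorithm, then classical MDS (double centring + top-D eigenpairs).
* **UMAP** — delegated to the ``umap-learn`` reference implementation behind
  the same embedding contract (seeded, deterministic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AffinityMatrix",
    "Embedding",
    "tsne_affinities",
    "tsne_embed",
    "isomap_embed",
    "umap_embed",
    "floyd_warshall",
    "knn_graph",
    "classical_mds",
    "kl_divergence",
    "embed",
]

MACHINE_EPS = np.finfo(float).eps


@dataclass
class AffinityMatrix:
    """Symmetric t-SNE input affinities with their per-point bandwidths."""

    P: np.ndarray
    sigmas: np.ndarray
    perplexity: float

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if np.any(P < 0) or np.any(np.diag(P) != 0):
            raise ValueError("affinities must be non-negative with zero diagonal")
        if abs(P.sum() - 1.0) > 1e-9:
            raise ValueError(f"affinities must sum to 1, got {P.sum()}")
        self.P = P


@dataclass
class Embedding:
    """Low-dimensional coordinates with full provenance."""

    Y: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    objective: float = float("nan")  # final KL for t-SNE, residual for ISOMAP
    seed: int | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("embedding coordinates must be finite")


# ---------------------------------------------------------------------------
# t-SNE
# ---------------------------------------------------------------------------

def _conditional_probs(d2_row: np.ndarray, beta: float) -> tuple[np.ndarray, float]:
    """p_{j|i} for precision beta = 1/(2 sigma_i^2); returns (probs, entropy in bits).

    Distances are shifted by their minimum before exponentiation — invariant
    for the normalised distribution, and it keeps equidistant neighbours
    exactly uniform at any beta instead of underflowing.
    """
    p = np.exp(-(d2_row - d2_row.min()) * beta)
    p /= p.sum()
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    return p, entropy


def _bisect_beta(
    d2_row: np.ndarray, target_log_perp: float, tol: float, max_iter: int = 200
) -> tuple[np.ndarray, float]:
    beta, lo, hi = 1.0, 0.0, np.inf
    p, entropy = _conditional_probs(d2_row, beta)
    for _ in range(max_iter):
        if abs(entropy - target_log_perp) <= tol:
            break
        if entropy > target_log_perp:  # too many neighbours -> sharpen
            lo = beta
            beta = beta * 2.0 if np.isinf(hi) else (beta + hi) / 2.0
        else:
            hi = beta
            beta = beta / 2.0 if lo == 0.0 else (beta + lo) / 2.0
        p, entropy = _conditional_probs(d2_row, beta)
    return p, beta


def tsne_affinities(
    X: np.ndarray, perplexity: float = 30.0, tol: float = 1e-10
) -> AffinityMatrix:
    """Symmetrised Gaussian affinities with perplexity-calibrated bandwidths.

    For each point i the bandwidth sigma_i is found by bisection so that the
    conditional distribution p_{.|i} has 2^entropy equal to ``perplexity``.
    The symmetrised matrix is p_ij = (p_{j|i} + p_{i|j}) / 2n, which sums to 1
    over all ordered pairs.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n < 3:
        raise ValueError("t-SNE affinities need at least 3 points")
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be below n={n}")
    if perplexity <= 1:
        raise ValueError("perplexity must exceed 1")

    D2 = squareform(pdist(X, metric="sqeuclidean"))
    # exact duplicates make the neighbour distribution independent of sigma
    off = D2 + np.diag(np.full(n, np.inf))
    if np.any(off.min(axis=1) == 0):
        warnings.warn(
            "duplicate points detected; perplexity calibration may not converge — "
            "consider jittering the input",
            RuntimeWarning,
            stacklevel=2,
        )
    target = float(np.log2(perplexity))
    P_cond = np.zeros((n, n))
    betas = np.empty(n)
    for i in range(n):
        d2_row = np.delete(D2[i], i)
        p_row, betas[i] = _bisect_beta(d2_row, target, tol)
        P_cond[i, np.arange(n) != i] = p_row
    P = (P_cond + P_cond.T) / (2.0 * n)
    sigmas = np.sqrt(1.0 / (2.0 * betas))
    return AffinityMatrix(P=P, sigmas=sigmas, perplexity=perplexity)


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """KL(P || Q) over the off-diagonal entries (both sum to 1)."""
    mask = (P > 0) & ~np.eye(len(P), dtype=bool)
    return float(np.sum(P[mask] * np.log(P[mask] / np.maximum(Q[mask], MACHINE_EPS))))


def _student_q(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Student-t similarities q_ij and the unnormalised kernel matrix."""
    d2 = squareform(pdist(Y, metric="sqeuclidean"))
    num = 1.0 / (1.0 + d2)
    np.fill_diagonal(num, 0.0)
    Q = num / num.sum()
    return Q, num


def tsne_embed(
    X: np.ndarray,
    D: int = 2,
    perplexity: float = 30.0,
    learning_rate: float = 200.0,
    n_iter: int = 1000,
    seed: int | None = None,
    early_exaggeration: float = 12.0,
    exaggeration_iters: int = 250,
    momentum: tuple[float, float] = (0.5, 0.8),
    init_sd: float = 1e-4,
) -> Embedding:
    """Embed ``X`` in D dimensions by minimising KL(P || Q) by gradient descent.

    The map is initialised from a seeded Gaussian of standard deviation
    ``init_sd``; affinities are exaggerated by ``early_exaggeration`` for the
    first ``exaggeration_iters`` iterations; momentum switches from the first
    to the second value when exaggeration ends; per-coordinate adaptive gains
    follow the original descent scheme. With ``n_iter = 0`` the initial map is
    returned untouched.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if D < 1:
        raise ValueError("target dimension must be >= 1")
    aff = tsne_affinities(X, perplexity=perplexity)
    P = aff.P

    rng = np.random.default_rng(seed)
    Y = rng.normal(0.0, init_sd, size=(n, D))
    Q, _ = _student_q(Y)
    initial_kl = kl_divergence(P, Q)
    if n_iter == 0:
        return Embedding(
            Y=Y,
            method="tsne",
            params={
                "perplexity": perplexity,
                "learning_rate": learning_rate,
                "n_iter": 0,
                "initial_kl": initial_kl,
            },
            objective=initial_kl,
            seed=seed,
        )

    velocity = np.zeros_like(Y)
    gains = np.ones_like(Y)
    P_run = P * early_exaggeration
    mom = momentum[0]
    for it in range(1, n_iter + 1):
        if it == exaggeration_iters + 1:
            P_run = P
            mom = momentum[1]
        Q, num = _student_q(Y)
        PQd = (P_run - Q) * num
        if not np.all(np.isfinite(PQd)):
            raise FloatingPointError(
                f"non-finite t-SNE gradient at iteration {it} "
                f"(lr={learning_rate}, perplexity={perplexity})"
            )
        grad = 4.0 * (np.diag(PQd.sum(axis=1)) - PQd) @ Y
        gains = np.where(np.sign(grad) != np.sign(velocity), gains + 0.2, gains * 0.8)
        np.clip(gains, 0.01, None, out=gains)
        velocity = mom * velocity - learning_rate * gains * grad
        Y = Y + velocity
        Y -= Y.mean(axis=0)
    Q, _ = _student_q(Y)
    final_kl = kl_divergence(P, Q)
    return Embedding(
        Y=Y,
        method="tsne",
        params={
            "perplexity": perplexity,
            "learning_rate": learning_rate,
            "n_iter": n_iter,
            "early_exaggeration": early_exaggeration,
            "exaggeration_iters": exaggeration_iters,
            "initial_kl": initial_kl,
        },
        objective=final_kl,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ISOMAP
# ---------------------------------------------------------------------------

def knn_graph(X: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Symmetric Euclidean k-NN graph as a dense matrix (np.inf = no edge)."""
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(X, dtype=float)
    n = len(X)
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors {n_neighbors} must be below n={n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    G = np.full((n, n), np.inf)
    rows = np.repeat(np.arange(n), n_neighbors + 1)
    G[rows, idx.ravel()] = dist.ravel()
    np.fill_diagonal(G, 0.0)  # clear FP dust in self-distances
    return np.minimum(G, G.T)  # undirected


def floyd_warshall(G: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths of a dense non-negative graph (inf = no edge)."""
    D = np.array(G, dtype=float)
    n = len(D)
    if D.shape != (n, n):
        raise ValueError("graph matrix must be square")
    for k in range(n):
        np.minimum(D, D[:, k, None] + D[None, k, :], out=D)
    return D


def classical_mds(distance_matrix: np.ndarray, D: int) -> np.ndarray:
    """Classical (Torgerson) MDS of a symmetric distance matrix.

    Double-centres the squared distances, B = -1/2 J D^2 J, and returns the
    top-D eigenvector embedding scaled by sqrt(eigenvalue). Negative
    eigenvalues among the selected components (non-Euclidean input) are
    truncated at zero with a warning.
    """
    Dm = np.asarray(distance_matrix, dtype=float)
    n = len(Dm)
    if Dm.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(Dm, Dm.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(Dm), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dm**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:D]
    top_vals = eigvals[order]
    if np.any(top_vals < -1e-10 * max(abs(eigvals).max(), 1.0)):
        warnings.warn(
            "negative eigenvalues truncated at 0 (non-Euclidean distances)",
            RuntimeWarning,
            stacklevel=2,
        )
    top_vals = np.clip(top_vals, 0.0, None)
    return eigvecs[:, order] * np.sqrt(top_vals)[None, :]


def min_connected_neighbors(X: np.ndarray, start: int = 10) -> int:
    """Smallest k for which the symmetric k-NN graph of ``X`` is connected.

    Doubles k until the graph connects, then binary-searches the minimum.
    Strongly clustered data needs k on the order of the smallest cluster, so
    no small universal default can serve every cohort.
    """
    n = len(X)

    def connected(k: int) -> bool:
        return len(_component_sizes(np.isfinite(knn_graph(X, k)))) == 1

    hi = min(start, n - 1)
    while not connected(hi):
        if hi == n - 1:
            raise ValueError("graph is disconnected even at n_neighbors = n - 1")
        hi = min(2 * hi, n - 1)
    lo = max(1, hi // 2)
    while lo < hi:
        mid = (lo + hi) // 2
        if connected(mid):
            hi = mid
        else:
            lo = mid + 1
    return hi


def isomap_embed(X: np.ndarray, D: int = 2, n_neighbors: int | str = 10) -> Embedding:
    """ISOMAP: k-NN graph geodesics (Floyd-Warshall) + classical MDS.

    The k-NN graph must be connected; otherwise the component sizes are
    reported in the error. ``n_neighbors="auto"`` uses the smallest
    neighbourhood size that connects the graph. The residual objective is the
    RMS mismatch between geodesic and embedded distances.
    """
    X = np.asarray(X, dtype=float)
    if n_neighbors == "auto":
        n_neighbors = min_connected_neighbors(X)
    G = knn_graph(X, n_neighbors)
    geo = floyd_warshall(G)
    if np.any(np.isinf(geo)):
        finite = np.isfinite(geo)
        comp = _component_sizes(finite)
        raise ValueError(
            f"k-NN graph is disconnected (component sizes {comp}); "
            f"increase n_neighbors from {n_neighbors}"
        )
    Y = classical_mds(geo, D)
    emb_d = squareform(pdist(Y))
    residual = float(np.sqrt(np.mean((emb_d - geo) ** 2)))
    return Embedding(
        Y=Y, method="isomap", params={"n_neighbors": n_neighbors}, objective=residual
    )


def _component_sizes(adjacency: np.ndarray) -> list[int]:
    n = len(adjacency)
    seen = np.zeros(n, dtype=bool)
    sizes = []
    for start in range(n):
        if seen[start]:
            continue
        stack, size = [start], 0
        seen[start] = True
        while stack:
            u = stack.pop()
            size += 1
            for v in np.flatnonzero(adjacency[u] & ~seen):
                seen[v] = True
                stack.append(v)
        sizes.append(size)
    return sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# UMAP (delegated)
# ---------------------------------------------------------------------------

def umap_embed(
    X: np.ndarray,
    D: int = 2,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int | None = 0,
) -> Embedding:
    """UMAP embedding via the reference implementation, seeded for determinism."""
    X = np.asarray(X, dtype=float)
    if n_neighbors >= len(X):
        raise ValueError(f"n_neighbors {n_neighbors} must be below n={len(X)}")
    import umap  # deferred: numba compilation is slow at import

    reducer = umap.UMAP(
        n_components=D,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed if seed is not None else 0,
    )
    with warnings.catch_warnings():
        # umap-learn warns that a fixed random_state disables parallelism
        warnings.filterwarnings("ignore", category=UserWarning, module="umap")
        Y = reducer.fit_transform(X)
    return Embedding(
        Y=np.asarray(Y, dtype=float),
        method="umap",
        params={"n_neighbors": n_neighbors, "min_dist": min_dist},
        seed=seed,
    )


def embed(X: np.ndarray, method: str, D: int = 2, seed: int | None = 0, **kwargs) -> Embedding:
    """Dispatch to one of the three embedding methods by name."""
    method = method.lower()
    if method == "tsne":
        return tsne_embed(X, D=D, seed=seed, **kwargs)
    if method == "isomap":
        return isomap_embed(X, D=D, **kwargs)
    if method == "umap":
        return umap_embed(X, D=D, seed=seed, **kwargs)
    raise ValueError(f"unknown embedding method {method!r}")
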