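"""Lloyd k-means and cluster-quality diagnostics.

The phenotyping pipelines cluster low-dimensional embeddings with plain Lloyd
k-means (best of ``n_init`` seeded restarts) and score candidate clusterings
with three quantities:

* **WCSS** — within-cluster sum of squares, sum_i sum_{x in S_i} ||x - mu_i||^2
  (intra-cluster cohesion; lower is tighter);
* **SSB** — between-cluster separation. Two conventions are computed: the
  plain centroid form sum_i ||mu_i - ga||^2 used for reporting and ranking,
  and the size-weighted textbook form sum_i |S_i| ||mu_i - ga||^2 which obeys
  the variance decomposition WCSS + SSB_weighted = total sum of squares;
* **silhouette** — per-point (b - a)/max(a, b) in [-1, 1].

The number of clusters k is chosen from a 1..20 scan by the elbow rule
(maximal discrete curvature of WCSS(k), silhouette as tie-break) and the
embedding dimension D by the smallest candidate whose k-means silhouette is
within a margin of the best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ClusterResult",
    "ScanCurve",
    "kmeans",
    "wcss",
    "ssb",
    "silhouette",
    "elbow_scan",
    "select_k",
    "select_D",
    "smallest_within_margin",
]

DEFAULT_N_INIT = 10
DEFAULT_MAX_ITER = 200
DEFAULT_TOL = 1e-4
DEFAULT_K_RANGE = range(1, 21)


@dataclass
class ClusterResult:
    """A converged k-means clustering with its quality metrics.

    Labels are 0-based and canonicalised by descending cluster size. Both SSB
    conventions are carried; ``ssb`` (the plain centroid form) is the one used
    in pipeline ranking.
    """

    labels: np.ndarray
    centroids: np.ndarray
    k: int
    wcss: float
    ssb: float
    ssb_weighted: float
    ga: np.ndarray
    silhouette_per_point: np.ndarray | None
    silhouette_mean: float
    n_init: int
    converged_iterations: int
    seed: int | None = None


@dataclass
class ScanCurve:
    """Quality metrics as a function of k over a scan range."""

    k_values: np.ndarray
    wcss: np.ndarray
    ssb: np.ndarray
    silhouette_mean: np.ndarray  # NaN at k = 1

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values)
        self.wcss = np.asarray(self.wcss, dtype=float)
        self.ssb = np.asarray(self.ssb, dtype=float)
        self.silhouette_mean = np.asarray(self.silhouette_mean, dtype=float)


def wcss(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Within-cluster sum of squares."""
    X = np.asarray(X, dtype=float)
    return float(np.sum((X - np.asarray(centroids)[labels]) ** 2))


def ssb(
    centroids: np.ndarray,
    ga: np.ndarray,
    cluster_sizes: Sequence[int] | None = None,
    weighted: bool = False,
) -> float:
    """Between-cluster separation from centroids to the global mean ``ga``.

    Unweighted (default, the reported form): sum_i ||mu_i - ga||^2.
    Weighted: sum_i |S_i| ||mu_i - ga||^2, completing WCSS to the total SS.
    """
    centroids = np.asarray(centroids, dtype=float)
    d2 = np.sum((centroids - np.asarray(ga, dtype=float)) ** 2, axis=1)
    if weighted:
        if cluster_sizes is None:
            raise ValueError("weighted SSB requires cluster sizes")
        return float(np.sum(np.asarray(cluster_sizes) * d2))
    return float(np.sum(d2))


def silhouette(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-point and mean silhouette scores, s = (b - a) / max(a, b).

    ``a`` is the mean distance to the point's own cluster (excluding itself),
    ``b`` the smallest mean distance to any other cluster. Points in singleton
    clusters score 0 by convention.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("silhouette requires at least two clusters")
    n = len(X)
    D = cdist(X, X)
    sizes = np.bincount(inv, minlength=k)
    # mean distance from each point to each cluster
    sums = np.zeros((n, k))
    for c in range(k):
        sums[:, c] = D[:, inv == c].sum(axis=1)
    mean_other = sums / sizes[None, :]
    own = inv
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(
            sizes[own] > 1, sums[np.arange(n), own] / np.maximum(sizes[own] - 1, 1), 0.0
        )
    mean_other[np.arange(n), own] = np.inf
    b = mean_other.min(axis=1)
    s = np.where(sizes[own] > 1, (b - a) / np.maximum(a, b), 0.0)
    return s, float(s.mean())


def _init_centroids(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random distinct data points (the default 'random' scheme)."""
    idx = rng.choice(len(X), size=k, replace=False)
    return X[idx].copy()


def _init_plusplus(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [X[rng.integers(len(X))]]
    for _ in range(1, k):
        d2 = np.min(cdist(X, np.asarray(centers)) ** 2, axis=1)
        total = d2.sum()
        if total == 0:
            centers.append(X[rng.integers(len(X))])
            continue
        centers.append(X[rng.choice(len(X), p=d2 / total)])
    return np.asarray(centers)


def _lloyd(
    X: np.ndarray,
    centroids: np.ndarray,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """One Lloyd run. Returns (labels, centroids, wcss, iterations)."""
    prev_inertia = np.inf
    labels = None
    for it in range(1, max_iter + 1):
        d2 = cdist(X, centroids, metric="sqeuclidean")
        labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(len(X)), labels].sum())
        # Lloyd monotonicity: assignment+update can only lower the objective
        assert inertia <= prev_inertia + 1e-9 * max(1.0, prev_inertia), (
            "Lloyd objective increased"
        )
        prev_inertia = inertia
        new_centroids = centroids.copy()
        for c in range(len(centroids)):
            members = labels == c
            if members.any():
                new_centroids[c] = X[members].mean(axis=0)
            else:
                # empty-cluster repair: reseed at the farthest point
                far = d2[np.arange(len(X)), labels].argmax()
                new_centroids[c] = X[far]
        shift = np.linalg.norm(new_centroids - centroids)
        denom = max(np.linalg.norm(centroids), np.finfo(float).tiny)
        centroids = new_centroids
        if shift / denom <= tol:
            break
    d2 = cdist(X, centroids, metric="sqeuclidean")
    labels = d2.argmin(axis=1)
    # final means so the centroid-is-mean invariant holds exactly
    for c in range(len(centroids)):
        members = labels == c
        if members.any():
            centroids[c] = X[members].mean(axis=0)
    return labels, centroids, wcss(X, labels, centroids), it


def _canonicalise(labels: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters by descending size (ties: lexicographic centroid)."""
    k = len(centroids)
    sizes = np.bincount(labels, minlength=k)
    order = sorted(range(k), key=lambda c: (-sizes[c], tuple(centroids[c])))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    return remap[labels], centroids[order]


def kmeans(
    X: np.ndarray,
    k: int,
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int | None = None,
    init: str = "random",
    compute_silhouette: bool = True,
) -> ClusterResult:
    """Best-of-``n_init`` Lloyd k-means.

    Convergence: relative Frobenius norm of the centroid shift <= ``tol``.
    The restart with the lowest WCSS wins; everything is deterministic under a
    fixed ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    init_fn = {"random": _init_centroids, "k-means++": _init_plusplus}[init]

    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_init):
        rng = np.random.default_rng(child)
        labels, centroids, inertia, iters = _lloyd(
            X, init_fn(X, k, rng), max_iter, tol, rng
        )
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia, iters)
    labels, centroids, inertia, iters = best
    labels, centroids = _canonicalise(labels, centroids)
    ga = X.mean(axis=0)
    sizes = np.bincount(labels, minlength=k)
    if k >= 2 and compute_silhouette:
        sil, sil_mean = silhouette(X, labels)
    else:
        sil, sil_mean = None, float("nan")
    return ClusterResult(
        labels=labels,
        centroids=centroids,
        k=k,
        wcss=inertia,
        ssb=ssb(centroids, ga),
        ssb_weighted=ssb(centroids, ga, sizes, weighted=True),
        ga=ga,
        silhouette_per_point=sil,
        silhouette_mean=sil_mean,
        n_init=n_init,
        converged_iterations=iters,
        seed=seed,
    )


def elbow_scan(
    X: np.ndarray,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    seed: int | None = None,
    n_init: int = DEFAULT_N_INIT,
) -> ScanCurve:
    """k-means quality metrics over a range of k (same data and seed per k)."""
    X = np.asarray(X, dtype=float)
    ks = np.asarray(sorted(k_range))
    if ks.max() > len(X):
        raise ValueError("largest k in scan exceeds number of points")
    w, s, sil = [], [], []
    for k in ks:
        res = kmeans(X, int(k), n_init=n_init, seed=seed, compute_silhouette=k >= 2)
        w.append(res.wcss)
        s.append(res.ssb)
        sil.append(res.silhouette_mean)
    w = np.asarray(w)
    if np.any(np.diff(w) > 1e-9 * max(w.max(), 1.0)):
        warnings.warn(
            "WCSS not monotone over the scan (restart noise)", RuntimeWarning, stacklevel=2
        )
    return ScanCurve(k_values=ks, wcss=w, ssb=np.asarray(s), silhouette_mean=np.asarray(sil))


def select_k(curve: ScanCurve, flat_tol: float = 1e-12) -> int:
    """Elbow rule: k with the greatest discrete curvature of the WCSS curve.

    Curvature is the second difference of log WCSS(k) at interior scan
    points; the log makes the rule invariant to the overall scale of the
    embedding, so a gigantic k=1 -> 2 drop (typical when an embedding places
    clusters very far apart) does not swamp the true elbow. Ties break toward
    higher mean silhouette. A flat curve (all curvatures below ``flat_tol``)
    falls back to the silhouette maximiser with a warning. If any WCSS value
    is non-positive (k close to n), the raw-scale second difference is used.
    """
    ks, w = curve.k_values, curve.wcss
    if len(ks) < 4:
        raise ValueError("elbow selection needs at least 4 scan points")
    if np.any(np.diff(ks) != 1):
        raise ValueError("elbow selection expects consecutive k values")
    if np.all(w > 0):
        lw = np.log(w)
        curv = lw[:-2] - 2 * lw[1:-1] + lw[2:]
        scale = max(abs(lw[0]), 1.0)
    else:
        curv = w[:-2] - 2 * w[1:-1] + w[2:]
        scale = max(abs(w[0]), 1.0)
    interior = ks[1:-1]
    if np.all(curv < flat_tol * scale):
        warnings.warn(
            "flat WCSS curve: falling back to silhouette maximiser",
            RuntimeWarning,
            stacklevel=2,
        )
        valid = ~np.isnan(curve.silhouette_mean)
        return int(curve.k_values[valid][np.argmax(curve.silhouette_mean[valid])])
    best_curv = curv.max()
    tied = interior[curv >= best_curv * (1 - 1e-12)]
    if len(tied) == 1:
        return int(tied[0])
    sil = {int(k): curve.silhouette_mean[list(ks).index(k)] for k in tied}
    return int(max(tied, key=lambda k: (sil[int(k)], -k)))


def smallest_within_margin(scores: dict, margin: float = 0.0) -> int:
    """Smallest key whose score is within ``margin`` of the maximum score."""
    best = max(scores.values())
    eligible = [d for d, s in scores.items() if s >= best - margin - 1e-12]
    return min(eligible)


def select_D(
    X: np.ndarray,
    embed: Callable[[np.ndarray, int], np.ndarray],
    candidate_Ds: Sequence[int],
    k: int,
    margin: float = 0.0,
    seed: int | None = None,
) -> tuple[int, dict]:
    """Choose the embedding dimension D for a pipeline.

    For each candidate D, embed ``X`` with ``embed(X, D)``, cluster with
    k-means, and record the mean silhouette; return the smallest D whose score
    is within ``margin`` of the maximum (minimality is the point: D should be
    as low as the data allow). All scores are returned for logging.
    """
    if len(candidate_Ds) == 0:
        raise ValueError("candidate_Ds must be non-empty")
    scores: dict[int, float] = {}
    for D in sorted(candidate_Ds):
        Y = embed(X, int(D))
        res = kmeans(Y, k, seed=seed)
        scores[int(D)] = res.silhouette_mean
    return smallest_within_margin(scores, margin), scores
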