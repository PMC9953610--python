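"""Phenotyping pipelines: the PVC x manifold grid, evaluation and ranking.

A phenotyping pipeline (PPi) pairs one partial-volume-correction strategy with
one manifold embedding; the nine combinations are fixed by name:

====  =======  ========
id    PVC      manifold
====  =======  ========
PP1   pvc2c    umap
PP2   rsf      umap
PP3   none     umap
PP4   pvc2c    tsne
PP5   rsf      tsne
PP6   none     tsne
PP7   pvc2c    isomap
PP8   rsf      isomap
PP9   none     isomap
====  =======  ========

Each pipeline embeds its SUVR matrix to D dimensions, clusters the embedding
with k-means, and is scored by the per-cluster MMSE mean +/- sd, the three
pairwise one-way ANOVA p-values between cluster MMSE distributions, and the
WCSS / SSB of the clustering. Pipelines are ranked lexicographically by mean
pairwise p-value (ascending), then WCSS (ascending), then SSB (descending).

``PhenotypingModel`` wraps the grid in a statsmodels-style fit interface:
build it from the per-PVC SUVR matrices and the cohort table, call ``fit`` and
inspect the returned ``PhenotypingResults`` (summary table, best pipeline,
phenotype labels).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterResult, kmeans
from .manifold import Embedding, embed
from .suvr import SUVRMatrix

__all__ = [
    "PipelineSpec",
    "PipelineEvaluation",
    "PIPELINE_GRID",
    "pipeline_grid",
    "run_pipeline",
    "pairwise_anova",
    "evaluate_pipeline",
    "rank_pipelines",
    "label_phenotypes",
    "PhenotypingModel",
    "PhenotypingResults",
    "derive_seed",
]

PVC_METHODS = ("pvc2c", "rsf", "none")
MANIFOLD_METHODS = ("umap", "tsne", "isomap")

SEVERITY_NAMES = ("phen_least_impaired", "phen_intermediate", "phen_most_impaired")


def derive_seed(master: int | None, *tags) -> int:
    """Deterministically derive a sub-2^31 child seed from a master seed + tags.

    Tags are hashed with CRC32 (stable across processes, unlike ``hash``).
    """
    if master is None:
        master = 0
    h = np.random.SeedSequence(
        [int(master) % 2**31, *(zlib.crc32(repr(t).encode()) % 2**31 for t in tags)]
    )
    return int(h.generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class PipelineSpec:
    """One PVC x manifold combination with its hyperparameters."""

    id: str
    pvc_method: str
    manifold_method: str
    D: int = 2
    k: int = 3
    seed: int | None = 0
    manifold_params: dict = field(default_factory=dict)
    kmeans_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pvc_method not in PVC_METHODS:
            raise ValueError(f"unknown PVC method {self.pvc_method!r}")
        if self.manifold_method not in MANIFOLD_METHODS:
            raise ValueError(f"unknown manifold method {self.manifold_method!r}")


#: The canonical nine-pipeline grid (D = 2, k = 3 defaults).
PIPELINE_GRID: tuple[PipelineSpec, ...] = tuple(
    PipelineSpec(id=f"PP{i + 1}", pvc_method=pvc, manifold_method=man)
    for i, (man, pvc) in enumerate(
        (man, pvc) for man in MANIFOLD_METHODS for pvc in PVC_METHODS
    )
)


def pipeline_grid(D: int = 2, k: int = 3, seed: int | None = 0, **overrides):
    """The nine named pipelines with shared D, k and a master seed.

    Per-pipeline seeds are derived from the master seed and the pipeline id so
    stochastic stages are independent but reproducible.
    """
    return [
        replace(p, D=D, k=k, seed=derive_seed(seed, p.id), **overrides)
        for p in PIPELINE_GRID
    ]


@dataclass
class PipelineEvaluation:
    """Scores of one pipeline's clustering against the cognitive outcome."""

    pipeline_id: str
    mmse_mean: np.ndarray  # per cluster
    mmse_sd: np.ndarray
    cluster_sizes: np.ndarray
    wcss: float
    ssb: float
    p_values: dict  # {"1v2": p, "1v3": p, "2v3": p}
    n_missing_mmse: int = 0

    @property
    def mean_p(self) -> float:
        return float(np.mean(list(self.p_values.values())))

    def to_row(self) -> dict:
        row = {"pipeline": self.pipeline_id}
        for c in range(len(self.mmse_mean)):
            row[f"mmse_cluster{c + 1}"] = f"{self.mmse_mean[c]:.2f} ± {self.mmse_sd[c]:.2f}"
        row["wcss"] = self.wcss
        row["ssb"] = self.ssb
        for pair, p in self.p_values.items():
            row[f"p_cluster{pair}"] = p
        row["mean_p"] = self.mean_p
        return row


def run_pipeline(
    spec: PipelineSpec,
    suvr_matrices: dict,
    cohort: pd.DataFrame | None = None,
) -> tuple[Embedding, ClusterResult]:
    """Run one pipeline: select the PVC matrix, embed, cluster.

    ``suvr_matrices`` maps PVC method name -> SUVRMatrix. If a cohort table is
    supplied its subject ids must match the matrix rows exactly (order
    included); a mismatch is reported with the differing ids.
    """
    if spec.pvc_method not in suvr_matrices:
        raise KeyError(f"no SUVR matrix for PVC method {spec.pvc_method!r}")
    matrix: SUVRMatrix = suvr_matrices[spec.pvc_method]
    if cohort is not None:
        mat_ids = list(matrix.subject_ids)
        coh_ids = list(cohort["subject_id"])
        if mat_ids != coh_ids:
            extra = sorted(set(mat_ids) ^ set(coh_ids))
            raise ValueError(
                f"subject ids of matrix and cohort differ (symmetric diff: {extra[:10]}"
                + ("...)" if len(extra) > 10 else ")")
            )
    X = matrix.values
    params = dict(spec.manifold_params)
    if spec.manifold_method == "isomap":
        # cluster-structured cohorts disconnect small k-NN graphs
        params.setdefault("n_neighbors", "auto")
    embedding = embed(X, spec.manifold_method, D=spec.D, seed=spec.seed, **params)
    clustering = kmeans(
        embedding.Y, spec.k, seed=derive_seed(spec.seed, "kmeans"), **spec.kmeans_params
    )
    return embedding, clustering


def pairwise_anova(values_a, values_b) -> float:
    """One-way ANOVA p-value between two groups (F-test, F = t^2).

    Degenerate cases: both groups constant with equal means -> p = 1 (no
    evidence of difference); both constant with different means -> p = 0.
    Groups smaller than 2 are rejected.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    n = len(a) + len(b)
    grand = (a.sum() + b.sum()) / n
    ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_within = float(np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
    if ss_within == 0.0:
        return 1.0 if ss_between == 0.0 else 0.0
    F = ss_between / (ss_within / (n - 2))
    return float(stats.f.sf(F, 1, n - 2))


def evaluate_pipeline(
    cluster_result: ClusterResult,
    embedding: Embedding,
    mmse_by_subject: np.ndarray,
    pipeline_id: str = "",
    bonferroni: bool = False,
) -> PipelineEvaluation:
    """Score a clustering: per-cluster MMSE, pairwise ANOVA, WCSS and SSB.

    Missing MMSE values are excluded per cluster (count reported). WCSS/SSB
    are computed on the embedding coordinates, where the clustering lives.
    ``bonferroni`` multiplies each pairwise p by the number of pairs (capped
    at 1); off by default — the reference tables report uncorrected values.
    """
    labels = cluster_result.labels
    mmse = np.asarray(mmse_by_subject, dtype=float)
    if len(mmse) != len(labels):
        raise ValueError("one MMSE value (or NaN) per clustered subject required")
    k = cluster_result.k
    groups = [mmse[labels == c] for c in range(k)]
    groups = [g[~np.isnan(g)] for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every cluster needs at least one subject with MMSE")
    n_missing = int(np.isnan(mmse).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} subject(s) without MMSE excluded from evaluation",
            RuntimeWarning,
            stacklevel=2,
        )
    means = np.array([g.mean() for g in groups])
    sds = np.array([g.std(ddof=1) if len(g) > 1 else 0.0 for g in groups])
    p_values = {}
    for i in range(k):
        for j in range(i + 1, k):
            if len(groups[i]) < 2 or len(groups[j]) < 2:
                # a (near-)singleton cluster carries no separation evidence;
                # score the pair as unseparated so the pipeline ranks last
                warnings.warn(
                    f"cluster pair {i + 1}v{j + 1} has a group with < 2 MMSE "
                    "values; p set to 1",
                    RuntimeWarning,
                    stacklevel=2,
                )
                p_values[f"{i + 1}v{j + 1}"] = 1.0
            else:
                p_values[f"{i + 1}v{j + 1}"] = pairwise_anova(groups[i], groups[j])
    if bonferroni:
        m = len(p_values)
        p_values = {pair: min(1.0, p * m) for pair, p in p_values.items()}
    return PipelineEvaluation(
        pipeline_id=pipeline_id,
        mmse_mean=means,
        mmse_sd=sds,
        cluster_sizes=np.bincount(labels, minlength=k),
        wcss=cluster_result.wcss,
        ssb=cluster_result.ssb,
        p_values=p_values,
        n_missing_mmse=n_missing,
    )


RANKING_RULE = "lexicographic: mean pairwise p (asc), WCSS (asc), SSB (desc)"


def rank_pipelines(evaluations) -> tuple[list, str]:
    """Order pipeline evaluations best-first; returns (ordered list, best id).

    Primary key: mean of the pairwise p-values (smaller = cleaner cognitive
    separation); ties break on lower WCSS, then higher SSB. The rule string is
    ``RANKING_RULE`` and is recorded in every report.
    """
    evaluations = list(evaluations)
    if len(evaluations) < 2:
        raise ValueError("ranking needs at least two evaluations")
    ordered = sorted(evaluations, key=lambda e: (e.mean_p, e.wcss, -e.ssb))
    return ordered, ordered[0].pipeline_id


def label_phenotypes(
    cluster_result: ClusterResult, mmse_by_subject: np.ndarray
) -> dict:
    """Map cluster indices to severity-ordered phenotype names.

    Clusters are ordered by descending mean MMSE: the highest-MMSE cluster is
    the least impaired. Ties are broken by descending cluster size with a
    warning. The returned dict maps cluster index -> dict with the severity
    name and a ``phen<N>`` alias (phen1 = least impaired).
    """
    labels = cluster_result.labels
    k = cluster_result.k
    if k != len(SEVERITY_NAMES):
        raise ValueError(f"phenotype naming expects k={len(SEVERITY_NAMES)}, got {k}")
    mmse = np.asarray(mmse_by_subject, dtype=float)
    means, sizes = [], []
    for c in range(k):
        g = mmse[labels == c]
        g = g[~np.isnan(g)]
        means.append(g.mean() if len(g) else -np.inf)
        sizes.append(int((labels == c).sum()))
    means = np.asarray(means)
    if len(np.unique(np.round(means, 12))) < k:
        warnings.warn(
            "mean MMSE ties across clusters; breaking by cluster size",
            RuntimeWarning,
            stacklevel=2,
        )
    order = sorted(range(k), key=lambda c: (-means[c], -sizes[c], c))
    return {
        cluster: {
            "name": SEVERITY_NAMES[rank],
            "alias": f"phen{rank + 1}",
            "mean_mmse": float(means[cluster]),
            "size": sizes[cluster],
        }
        for rank, cluster in enumerate(order)
    }


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class PhenotypingModel:
    """The nine-pipeline phenotyping analysis as a fittable model.

    Parameters
    ----------
    suvr_matrices : dict or SUVRMatrix
        Mapping PVC method -> SUVRMatrix. A single matrix is broadcast to all
        three methods (useful when the features were generated directly).
    cohort : pandas.DataFrame
        Covariate table with ``subject_id`` and ``mmse`` columns, rows aligned
        with the matrices.
    D, k : int
        Embedding dimension and cluster count shared by all pipelines.
    pipelines : sequence of PipelineSpec, optional
        Override the canonical grid.
    """

    def __init__(self, suvr_matrices, cohort: pd.DataFrame, D: int = 2, k: int = 3,
                 pipelines=None):
        if isinstance(suvr_matrices, SUVRMatrix):
            suvr_matrices = {m: suvr_matrices for m in PVC_METHODS}
        self.suvr_matrices = suvr_matrices
        self.cohort = cohort.reset_index(drop=True)
        if "subject_id" not in self.cohort or "mmse" not in self.cohort:
            raise ValueError("cohort table needs subject_id and mmse columns")
        self.D = D
        self.k = k
        self._pipelines = pipelines

    @classmethod
    def from_dataframe(cls, features: pd.DataFrame, cohort: pd.DataFrame, **kwargs):
        """Build from a plain subjects x ROIs feature frame (single PVC path)."""
        matrix = SUVRMatrix(data=features, provenance={"source": "dataframe"})
        return cls(matrix, cohort, **kwargs)

    def fit(self, seed: int | None = 0) -> "PhenotypingResults":
        """Run every pipeline, evaluate and rank. Deterministic under ``seed``."""
        specs = self._pipelines or pipeline_grid(D=self.D, k=self.k, seed=seed)
        mmse = self.cohort["mmse"].to_numpy(dtype=float)
        runs, evaluations = {}, []
        for spec in specs:
            embedding, clustering = run_pipeline(spec, self.suvr_matrices, self.cohort)
            ev = evaluate_pipeline(clustering, embedding, mmse, pipeline_id=spec.id)
            runs[spec.id] = (spec, embedding, clustering)
            evaluations.append(ev)
        ordered, best_id = rank_pipelines(evaluations)
        return PhenotypingResults(
            model=self, seed=seed, runs=runs, evaluations=evaluations,
            ranking=[e.pipeline_id for e in ordered], best_id=best_id,
        )


class PhenotypingResults:
    """Fitted phenotyping grid: evaluations, ranking and phenotype labels."""

    def __init__(self, model, seed, runs, evaluations, ranking, best_id):
        self.model = model
        self.seed = seed
        self.runs = runs
        self.evaluations = {e.pipeline_id: e for e in evaluations}
        self.ranking = ranking
        self.best_id = best_id
        self.ranking_rule = RANKING_RULE

    @property
    def best_run(self):
        return self.runs[self.best_id]

    def evaluation_table(self) -> pd.DataFrame:
        """Table of per-pipeline scores, one row per pipeline, grid order."""
        rows = [self.evaluations[pid].to_row() for pid in sorted(self.evaluations)]
        return pd.DataFrame(rows).set_index("pipeline")

    def phenotypes(self, pipeline_id: str | None = None) -> dict:
        """Severity-ordered phenotype names for a pipeline (default: best)."""
        pid = pipeline_id or self.best_id
        _, _, clustering = self.runs[pid]
        return label_phenotypes(clustering, self.model.cohort["mmse"].to_numpy(float))

    def phenotype_assignments(self, pipeline_id: str | None = None) -> pd.Series:
        """Per-subject phenotype alias (phen1..phen3) for a pipeline."""
        pid = pipeline_id or self.best_id
        _, _, clustering = self.runs[pid]
        mapping = self.phenotypes(pid)
        return pd.Series(
            [mapping[c]["alias"] for c in clustering.labels],
            index=self.model.cohort["subject_id"],
            name="phenotype",
        )

    def summary(self) -> str:
        """Human-readable report of the fitted grid."""
        lines = [
            "Phenotyping pipeline grid (PVC x manifold)",
            "=" * 58,
            f"subjects: {len(self.model.cohort)}   D={self.model.D}   k={self.model.k}   "
            f"seed={self.seed}",
            f"ranking rule: {self.ranking_rule}",
            "",
            self.evaluation_table().to_string(float_format=lambda v: f"{v:.3f}"),
            "",
            f"best pipeline: {self.best_id} "
            f"(mean pairwise p = {self.evaluations[self.best_id].mean_p:.4f})",
        ]
        phen = self.phenotypes()
        for cluster, info in sorted(phen.items(), key=lambda kv: kv[1]["alias"]):
            lines.append(
                f"  {info['alias']} ({info['name']}): cluster {cluster}, "
                f"n={info['size']}, mean MMSE {info['mean_mmse']:.2f}"
            )
        return "\n".join(lines)

    def plot_embeddings(self, path=None):
        """3x3 scatter grid of the embeddings coloured by cluster."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(3, 3, figsize=(12, 12))
        for ax, pid in zip(axes.ravel(), sorted(self.runs)):
            spec, embedding, clustering = self.runs[pid]
            ax.scatter(
                embedding.Y[:, 0], embedding.Y[:, 1], c=clustering.labels, s=8,
                cmap="viridis",
            )
            ax.set_title(f"{pid}: {spec.pvc_method}+{spec.manifold_method}")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
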