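"""Readers, writers, run configuration and the end-to-end orchestrator.

File conventions: NIfTI (.nii/.nii.gz) for volumes, comma-separated UTF-8 CSV
with a mandatory header for tables, YAML/JSON for configuration and
provenance. All randomness flows from a single master seed in the config,
split deterministically per stage. Every run writes its resolved
configuration and the SHA-256 checksum of each artifact, so a re-run with the
same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import manifold as _manifold
from .epigenetics import stratify, violin_data
from .pipeline import PhenotypingModel, derive_seed
from .suvr import SUVRMatrix
from .synthcohort import CohortSpec, make_cohort

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "read_cohort",
    "write_cohort",
    "RunConfig",
    "orchestrate",
]

MMSE_RANGE = (0.0, 30.0)

CATEGORICAL_LEVELS = {
    "gender": {"female", "male"},
    "apoe_risk": {"low", "medium", "high"},
    "tobac": {"yes", "no"},
    "depothr": {"yes", "no"},
    "alcohol": {"yes", "no"},
}


@dataclass
class Volume:
    """A 3-D voxel grid with its voxel size (mm) and affine."""

    data: np.ndarray
    voxel_size_mm: tuple
    affine: np.ndarray


def read_volume(path, kind: str = "activity") -> Volume:
    """Load a 3-D NIfTI volume; ``kind='labels'`` validates integer labels."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if kind == "labels":
        if not np.allclose(data, np.round(data)) or np.any(data < 0):
            raise ValueError("label volume must contain non-negative integers")
        data = np.round(data).astype(np.int32)
    elif kind == "activity":
        data = data.astype(float)
    else:
        raise ValueError(f"unknown volume kind {kind!r}")
    return Volume(data=data, voxel_size_mm=voxel_size, affine=np.asarray(img.affine))


def write_volume(path, data: np.ndarray, voxel_size_mm=1.0) -> None:
    """Write a 3-D array as NIfTI with a diagonal affine from the voxel size."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    zooms = np.broadcast_to(np.atleast_1d(voxel_size_mm), (3,)).astype(float)
    affine = np.diag([*zooms, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_cohort(path) -> pd.DataFrame:
    """Load and validate a cohort covariate table.

    ``subject_id`` must be unique. MMSE values outside [0, 30] are treated as
    missing with a warning; known categorical variables are checked against
    their level sets (unexpected levels warn). Missing cells stay missing.
    """
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("cohort CSV needs a subject_id column")
    dupes = df["subject_id"][df["subject_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate subject_id(s): {list(dupes)[:5]}")
    if "mmse" in df.columns:
        mmse = pd.to_numeric(df["mmse"], errors="coerce")
        bad = mmse.notna() & ((mmse < MMSE_RANGE[0]) | (mmse > MMSE_RANGE[1]))
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} MMSE value(s) outside {MMSE_RANGE} treated as missing",
                RuntimeWarning,
                stacklevel=2,
            )
            mmse[bad] = np.nan
        df["mmse"] = mmse
    for var, levels in CATEGORICAL_LEVELS.items():
        if var in df.columns:
            seen = set(df[var].dropna().unique())
            unknown = seen - levels
            if unknown:
                warnings.warn(
                    f"unexpected {var} level(s): {sorted(unknown)}",
                    RuntimeWarning,
                    stacklevel=2,
                )
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_embedding(embedding, subject_ids, path) -> None:
    """CSV of coordinates plus a JSON sidecar with method, params and seed."""
    path = Path(path)
    D = embedding.Y.shape[1]
    pd.DataFrame(
        embedding.Y,
        index=pd.Index(subject_ids, name="subject_id"),
        columns=[f"dim_{i + 1}" for i in range(D)],
    ).to_csv(path)
    meta = {
        "method": embedding.method,
        "params": embedding.params,
        "seed": embedding.seed,
        "objective": embedding.objective,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, default=str)
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

STRATIFY_VARIABLES = [
    "education_years", "tobac", "depothr", "apoe_risk", "alcohol",
]
CLINICAL_VARIABLES = ["gender", "age", "mmse"]
VIOLIN_VARIABLES = ["mmse", "smoking_years", "education_years", "age"]


@dataclass
class RunConfig:
    """Validated configuration of a full phenotyping run."""

    output_dir: str
    seed: int = 0
    D: int | None = 2
    k: int | None = 3
    synthetic: dict | None = None  # CohortSpec overrides
    suvr_csv: dict | str | None = None  # path or {pvc_method: path}
    cohort_csv: str | None = None
    select_hyperparameters: bool = False
    k_range: tuple = (1, 20)
    candidate_Ds: tuple = (2, 3)
    manifold_params: dict = field(default_factory=dict)
    stratify_variables: list = field(default_factory=lambda: list(STRATIFY_VARIABLES))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.synthetic is None and (self.suvr_csv is None or self.cohort_csv is None):
            raise ValueError(
                "config needs either a 'synthetic' block or both suvr_csv and cohort_csv"
            )
        if not self.select_hyperparameters and (self.D is None or self.k is None):
            raise ValueError("D and k required unless select_hyperparameters is set")
        if self.select_hyperparameters:
            lo, hi = self.k_range
            if hi - lo < 3:
                raise ValueError("k_range must span at least 4 values for the elbow rule")
            if not self.candidate_Ds:
                raise ValueError("candidate_Ds must be non-empty")

    def resolved(self) -> dict:
        from dataclasses import asdict

        out = asdict(self)
        out["k_range"] = list(self.k_range)
        out["candidate_Ds"] = list(self.candidate_Ds)
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def orchestrate(config: RunConfig) -> dict:
    """Run the full method: inputs -> (selection) -> grid -> report.

    Stage order: acquire features, optional D/k selection, fit the pipeline
    grid, stratify covariates by the best pipeline's phenotypes, write the
    artifact tree. Returns a manifest with stage timings and artifact
    checksums; any stage failure aborts naming the stage.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "artifacts": {}, "versions": _versions()}
    log: list[str] = []

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            dt = time.perf_counter() - t0
            manifest["stages"][name] = round(dt, 3)
            log.append(f"completed stage {name}")
            return result

        return wrap

    # -- acquire ------------------------------------------------------------
    def _acquire():
        if config.synthetic is not None:
            spec = CohortSpec(seed=derive_seed(config.seed, "cohort"))
            n = config.synthetic.get("n_subjects")
            if n:
                spec = spec.with_sizes(int(n))
            for key in ("n_rois", "cluster_sd", "separation", "k_true"):
                if key in config.synthetic:
                    from dataclasses import replace

                    spec = replace(spec, **{key: config.synthetic[key]})
            if "n_rois" in config.synthetic or "k_true" in config.synthetic:
                spec.validate()
            matrix, cohort, true_labels = make_cohort(spec)
            matrices = {m: matrix for m in ("pvc2c", "rsf", "none")}
            cohort.to_csv(out / "cohort.csv", index=False)
            matrix.to_csv(out / "suvr_synthetic.csv")
            return matrices, cohort, true_labels
        paths = config.suvr_csv
        if isinstance(paths, str):
            matrix = SUVRMatrix.from_csv(paths)
            matrices = {m: matrix for m in ("pvc2c", "rsf", "none")}
        else:
            matrices = {m: SUVRMatrix.from_csv(p) for m, p in paths.items()}
        cohort = read_cohort(config.cohort_csv)
        return matrices, cohort, None

    matrices, cohort, true_labels = stage("acquire")(_acquire)

    # -- hyperparameter selection -------------------------------------------
    D, k = config.D, config.k
    if config.select_hyperparameters:
        def _select():
            ref = matrices["rsf"].values
            emb_seed = derive_seed(config.seed, "select")

            def embed_fn(X, dim):
                return _manifold.tsne_embed(X, D=dim, seed=emb_seed).Y

            Y2 = embed_fn(ref, 2)
            lo, hi = config.k_range
            curve = _cluster.elbow_scan(Y2, range(lo, hi + 1), seed=emb_seed)
            k_sel = _cluster.select_k(curve)
            D_sel, scores = _cluster.select_D(
                ref, embed_fn, config.candidate_Ds, k_sel, seed=emb_seed
            )
            pd.DataFrame(
                {
                    "k": curve.k_values,
                    "wcss": curve.wcss,
                    "ssb": curve.ssb,
                    "silhouette": curve.silhouette_mean,
                }
            ).to_csv(out / "elbow_scan.csv", index=False)
            log.append(f"selected k={k_sel} (elbow), D={D_sel} (silhouette {scores})")
            return D_sel, k_sel

        D, k = stage("select_hyperparameters")(_select)

    # -- pipeline grid ------------------------------------------------------
    def _fit():
        model = PhenotypingModel(matrices, cohort, D=D, k=k)
        return model.fit(seed=derive_seed(config.seed, "grid"))

    results = stage("fit_grid")(_fit)

    # -- stratification -----------------------------------------------------
    def _stratify():
        phen = results.phenotype_assignments()
        labels = phen.to_numpy()
        available = [v for v in config.stratify_variables if v in cohort.columns]
        tables = stratify(cohort, labels, available)
        for t in tables:
            t.to_frame().to_csv(out / f"stratified_{t.variable}.csv")
        clin = [v for v in CLINICAL_VARIABLES if v in cohort.columns]
        clin_tables = stratify(cohort, labels, clin)
        pd.concat([t.to_frame() for t in clin_tables], keys=[t.variable for t in clin_tables]).to_csv(
            out / "best_pipeline_clinical.csv"
        )
        for var in VIOLIN_VARIABLES:
            if var not in cohort.columns:
                continue
            vd = violin_data(cohort, labels, var)
            tidy = pd.concat(
                [
                    pd.DataFrame({"phenotype": p, "value": d["values"]})
                    for p, d in vd.items()
                ]
            )
            tidy.to_csv(out / f"violin_{var}_values.csv", index=False)
            dens = pd.concat(
                [
                    pd.DataFrame(
                        {"phenotype": p, "grid": d["grid"], "density": d["density"]}
                    )
                    for p, d in vd.items()
                ]
            )
            dens.to_csv(out / f"violin_{var}_density.csv", index=False)
        return phen

    phen = stage("stratify")(_stratify)

    # -- report -------------------------------------------------------------
    def _report():
        results.evaluation_table().to_csv(out / "pipeline_evaluation.csv")
        phen.to_frame().to_csv(out / "phenotype_assignments.csv")
        for pid, (spec, embedding, clustering) in results.runs.items():
            write_embedding(embedding, cohort["subject_id"], out / f"embedding_{pid}.csv")
        (out / "summary.txt").write_text(results.summary() + "\n")
        if true_labels is not None:
            from sklearn.metrics import adjusted_rand_score

            _, _, best_clust = results.best_run
            ari = adjusted_rand_score(true_labels, best_clust.labels)
            manifest["best_pipeline_ari_vs_truth"] = float(ari)
        manifest["best_pipeline"] = results.best_id
        manifest["D"], manifest["k"] = D, k

    stage("report")(_report)

    (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.resolved()))
    (out / "run.log").write_text("\n".join(log) + "\n")
    # timings live in provenance.json only, so artifact checksums are
    # reproducible run-to-run under the same config and seed
    for artifact in sorted(out.iterdir()):
        if artifact.name in ("provenance.json", "run.log"):
            continue
        if artifact.is_file():
            manifest["artifacts"][artifact.name] = _sha256(artifact)
    (out / "provenance.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _versions() -> dict:
    import sklearn

    import phenopet

    return {
        "phenopet": phenopet.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
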