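"""Synthetic phantoms and cohorts.

The study data this package targets (amyloid PET + clinical covariates from a
large access-controlled repository) cannot ship with the code, so this module
generates inputs with the statistical structure the analysis assumes:

* **Phantoms** — piecewise-constant regional activity on a labelled voxel
  grid, blurred by a Gaussian PSF with optional additive noise. Because the
  true regional activities are known by construction, they are the oracle for
  every partial-volume-correction test.
* **Cohorts** — n subjects whose SUVR feature vectors are drawn from k latent
  phenotype clusters (diagonal Gaussians), with MMSE and clinical covariates
  distributed per phenotype. The default covariate parameters reproduce the
  published marginals of a 518-subject amyloid cohort split into three
  phenotypes (sizes 194/118/206; MMSE 28.97±0.81, 28.28±1.40, 29.31±0.59).

Everything is driven by an explicit integer seed: identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._gaussian import gaussian_blur
from .pvc import PSFModel
from .suvr import SUVRMatrix

__all__ = [
    "Sphere",
    "Box",
    "Shell",
    "PhantomSpec",
    "Numeric",
    "Categorical",
    "CohortSpec",
    "make_phantom",
    "simulate_pet",
    "make_cohort",
    "default_phantom_spec",
    "default_cluster_means",
]

COHORT_COLUMNS = [
    "subject_id",
    "mmse",
    "age",
    "gender",
    "apoe_risk",
    "education_years",
    "tobac",
    "depothr",
    "alcohol",
    "smoking_years",
    "true_phenotype",
]


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sphere:
    center: tuple
    radius: float

    def mask(self, grid_shape) -> np.ndarray:
        coords = np.indices(grid_shape, dtype=float)
        d2 = sum((coords[a] - self.center[a]) ** 2 for a in range(len(grid_shape)))
        return d2 <= self.radius**2

    def inside(self, grid_shape) -> bool:
        return all(
            self.center[a] - self.radius >= 0
            and self.center[a] + self.radius <= grid_shape[a] - 1
            for a in range(len(grid_shape))
        )


@dataclass(frozen=True)
class Box:
    lo: tuple  # inclusive voxel corner
    hi: tuple  # exclusive voxel corner

    def mask(self, grid_shape) -> np.ndarray:
        m = np.ones(grid_shape, dtype=bool)
        coords = np.indices(grid_shape)
        for a in range(len(grid_shape)):
            m &= (coords[a] >= self.lo[a]) & (coords[a] < self.hi[a])
        return m

    def inside(self, grid_shape) -> bool:
        return all(
            0 <= self.lo[a] < self.hi[a] <= grid_shape[a] for a in range(len(grid_shape))
        )


@dataclass(frozen=True)
class Shell:
    """Spherical shell: voxels with r_inner < distance <= r_outer."""

    center: tuple
    r_inner: float
    r_outer: float

    def mask(self, grid_shape) -> np.ndarray:
        coords = np.indices(grid_shape, dtype=float)
        d2 = sum((coords[a] - self.center[a]) ** 2 for a in range(len(grid_shape)))
        return (d2 > self.r_inner**2) & (d2 <= self.r_outer**2)

    def inside(self, grid_shape) -> bool:
        return Sphere(self.center, self.r_outer).inside(grid_shape)


@dataclass(frozen=True)
class PhantomSpec:
    """Piecewise-constant activity phantom on a labelled grid.

    ``regions`` is a list of ``(label_id, geometry, true_activity)``; label 0
    is the background with ``background_activity``. At least one label must be
    named in ``reference_labels`` (the SUVR denominator downstream).
    """

    grid_shape: tuple
    voxel_size_mm: float
    regions: tuple
    background_activity: float = 0.0
    reference_labels: tuple = ()

    def validate(self) -> None:
        ids = [r[0] for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate label ids in phantom spec: {ids}")
        if any(i <= 0 for i in ids):
            raise ValueError("label ids must be positive integers")
        if any(r[2] < 0 for r in self.regions) or self.background_activity < 0:
            raise ValueError("activities must be non-negative")
        if not self.reference_labels:
            raise ValueError("at least one region must be designated as reference")
        if not set(self.reference_labels) <= set(ids):
            raise ValueError("reference_labels must name declared regions")
        for label, geom, _ in self.regions:
            if not geom.inside(self.grid_shape):
                raise ValueError(f"geometry of label {label} extends outside the grid")


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise a phantom spec into (label volume, activity volume).

    Overlapping region geometries are rejected: each voxel belongs to exactly
    one region or the background, so the activity image is piecewise constant
    with exactly the specified values.
    """
    spec.validate()
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    activity = np.full(spec.grid_shape, float(spec.background_activity))
    claimed = np.zeros(spec.grid_shape, dtype=bool)
    for label, geom, act in spec.regions:
        m = geom.mask(spec.grid_shape)
        if not m.any():
            raise ValueError(f"region {label} rasterises to zero voxels")
        if np.any(m & claimed):
            raise ValueError(f"region {label} overlaps a previously placed region")
        claimed |= m
        labels[m] = label
        activity[m] = act
    return labels, activity


def simulate_pet(
    activity: np.ndarray,
    psf: PSFModel,
    noise_sd: float = 0.0,
    seed: int | None = None,
    noise_model: str = "gaussian",
) -> np.ndarray:
    """Simulate a PET acquisition: PSF blur plus voxelwise noise.

    The blur is the same discrete operator the PVC module corrects with, so
    noiseless simulations are exactly invertible by GTM. ``noise_model`` is
    additive ``"gaussian"`` (default; ``noise_sd`` in activity units) or
    ``"poisson"`` (``noise_sd`` acts as 1/sqrt(scale); counts scaled so that
    the noise level is comparable). ``noise_sd = 0`` is deterministic.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    blurred = psf.blur(activity)
    if noise_sd == 0:
        return blurred
    rng = np.random.default_rng(seed)
    if noise_model == "gaussian":
        return blurred + rng.normal(0.0, noise_sd, size=blurred.shape)
    if noise_model == "poisson":
        scale = 1.0 / noise_sd**2  # variance ~ mean/scale ~ noise_sd^2 at unit activity
        return rng.poisson(np.clip(blurred, 0, None) * scale) / scale
    raise ValueError(f"unknown noise model {noise_model!r}")


def default_phantom_spec(
    grid: int = 48, voxel_size_mm: float = 2.0, n_spheres: int = 6
) -> PhantomSpec:
    """A compact test phantom: disjoint spheres + a nested shell + reference.

    Activities span the SUVR-like range 0.4-2.4; the large outer shell (label
    ``n_spheres + 1``) plays the cerebellar reference role.
    """
    c = (grid - 1) / 2.0
    rng = np.random.default_rng(20230119)  # geometry is part of the spec, fixed
    regions = []
    # ring of disjoint spheres around the centre
    ring_r = grid * 0.30
    for i in range(n_spheres):
        theta = 2 * np.pi * i / n_spheres
        center = (c + ring_r * np.cos(theta), c + ring_r * np.sin(theta), c)
        radius = grid * 0.08
        act = float(0.4 + 2.0 * rng.random())
        regions.append((i + 1, Sphere(center, radius), act))
    # nested core: shell around an inner sphere
    regions.append((n_spheres + 1, Shell((c, c, c), grid * 0.06, grid * 0.12), 1.0))
    regions.append((n_spheres + 2, Sphere((c, c, c), grid * 0.06), 2.4))
    return PhantomSpec(
        grid_shape=(grid, grid, grid),
        voxel_size_mm=voxel_size_mm,
        regions=tuple(regions),
        background_activity=0.1,
        reference_labels=(n_spheres + 1,),
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Numeric:
    """Per-phenotype numeric covariate: truncated normal, with missingness."""

    mean: float
    sd: float
    lo: float | None = None
    hi: float | None = None
    missing: float = 0.0


@dataclass(frozen=True)
class Categorical:
    """Per-phenotype categorical covariate: levels with probabilities."""

    levels: tuple
    probs: tuple
    missing: float = 0.0

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.probs):
            raise ValueError("levels and probs must align")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {sum(self.probs)}")


def _cat(levels, counts, total):
    """Categorical from observed counts; the remainder of ``total`` is missing."""
    known = sum(counts)
    return Categorical(
        levels=tuple(levels),
        probs=tuple(c / known for c in counts),
        missing=1.0 - known / total,
    )


def _default_covariates() -> dict:
    """Three-phenotype covariate distributions from the published cohort tables."""
    sizes = (194, 118, 206)
    return {
        "mmse": [
            Numeric(28.97, 0.81, lo=0, hi=30),
            Numeric(28.28, 1.40, lo=0, hi=30),
            Numeric(29.31, 0.59, lo=0, hi=30),
        ],
        "age": [
            Numeric(67.30, 8.40, lo=42, hi=95),
            Numeric(73.52, 5.83, lo=42, hi=95),
            Numeric(62.12, 8.90, lo=42, hi=95),
        ],
        "gender": [
            _cat(("female", "male"), (96, 98), sizes[0]),
            _cat(("female", "male"), (70, 48), sizes[1]),
            _cat(("female", "male"), (136, 70), sizes[2]),
        ],
        "apoe_risk": [
            _cat(("low", "medium", "high"), (134, 48, 5), sizes[0]),
            _cat(("low", "medium", "high"), (60, 47, 11), sizes[1]),
            _cat(("low", "medium", "high"), (122, 71, 5), sizes[2]),
        ],
        "education_years": [
            Numeric(16.010, 2.400, lo=0),
            Numeric(15.898, 2.553, lo=0),
            Numeric(16.247, 1.589, lo=0),
        ],
        "tobac": [
            _cat(("yes", "no"), (73, 88), sizes[0]),
            _cat(("yes", "no"), (58, 38), sizes[1]),
            _cat(("yes", "no"), (73, 107), sizes[2]),
        ],
        "depothr": [
            _cat(("yes", "no"), (24, 103), sizes[0]),
            _cat(("yes", "no"), (19, 67), sizes[1]),
            _cat(("yes", "no"), (5, 178), sizes[2]),
        ],
        "alcohol": [
            _cat(("yes", "no"), (3, 58), sizes[0]),
            _cat(("yes", "no"), (7, 62), sizes[1]),
            _cat(("yes", "no"), (4, 80), sizes[2]),
        ],
        # numeric smoking burden: an extension beyond the binary TOBAC flag,
        # ordered like the published violin plots (middle phenotype heaviest)
        "smoking_years": [
            Numeric(18.0, 12.0, lo=0),
            Numeric(24.0, 13.0, lo=0),
            Numeric(12.0, 10.0, lo=0),
        ],
    }


def default_cluster_means(
    n_rois: int = 166,
    k: int = 3,
    separation: float = 4.0,
    cluster_sd: float = 0.1,
    recipe_seed: int = 20230119,
) -> np.ndarray:
    """Deterministic per-cluster SUVR mean vectors with a set separation.

    A shared baseline profile (uniform on [0.9, 1.6], fixed recipe seed) is
    offset along k orthonormal directions so that every pair of cluster means
    is ``separation * cluster_sd * sqrt(n_rois)`` apart — i.e. ``separation``
    times the typical within-cluster radius. Offsets are shrunk toward zero
    mean so cluster means stay in a plausible SUVR range.
    """
    rng = np.random.default_rng(recipe_seed)
    baseline = rng.uniform(0.9, 1.6, size=n_rois)
    raw = rng.normal(size=(n_rois, k))
    q, _ = np.linalg.qr(raw)  # orthonormal columns
    radius = separation * cluster_sd * np.sqrt(n_rois) / np.sqrt(2.0)
    means = baseline[None, :] + radius * q.T
    return means


@dataclass(frozen=True)
class CohortSpec:
    """Latent-phenotype cohort: SUVR clusters plus per-phenotype covariates."""

    n_subjects: int = 518
    n_rois: int = 166
    k_true: int = 3
    cluster_sizes: tuple = (194, 118, 206)
    cluster_means: np.ndarray | None = None  # (k_true, n_rois); default recipe
    cluster_sd: float = 0.1
    separation: float = 4.0
    covariate_params: dict = field(default_factory=_default_covariates)
    seed: int = 0

    def validate(self) -> None:
        if sum(self.cluster_sizes) != self.n_subjects:
            raise ValueError(
                f"cluster sizes {self.cluster_sizes} must sum to n_subjects {self.n_subjects}"
            )
        if len(self.cluster_sizes) != self.k_true:
            raise ValueError("need one cluster size per latent phenotype")
        if self.cluster_means is not None:
            shape = np.asarray(self.cluster_means).shape
            if shape != (self.k_true, self.n_rois):
                raise ValueError(
                    f"cluster_means shape {shape} != ({self.k_true}, {self.n_rois})"
                )
        for name, per_phen in self.covariate_params.items():
            if len(per_phen) != self.k_true:
                raise ValueError(f"covariate {name!r} needs {self.k_true} phenotype entries")

    def with_sizes(self, n_subjects: int) -> "CohortSpec":
        """Rescale the default 194/118/206 split to a new total."""
        props = np.asarray(self.cluster_sizes, dtype=float)
        props /= props.sum()
        sizes = np.floor(props * n_subjects).astype(int)
        sizes[0] += n_subjects - sizes.sum()
        return replace(self, n_subjects=n_subjects, cluster_sizes=tuple(int(s) for s in sizes))

    def resolved_means(self) -> np.ndarray:
        if self.cluster_means is not None:
            return np.asarray(self.cluster_means, dtype=float)
        return default_cluster_means(
            self.n_rois, self.k_true, self.separation, self.cluster_sd
        )


def _draw_numeric(rng: np.random.Generator, p: Numeric, n: int) -> np.ndarray:
    # out-of-range draws are clipped to the bounds: bounded clinical scales
    # (MMSE tops out at 30) show exactly this ceiling/floor effect, and the
    # clip perturbs the group mean far less than resampling would
    vals = rng.normal(p.mean, p.sd, size=n)
    lo = -np.inf if p.lo is None else p.lo
    hi = np.inf if p.hi is None else p.hi
    vals = np.clip(vals, lo, hi)
    if p.missing > 0:
        vals[rng.random(n) < p.missing] = np.nan
    return vals


def _draw_categorical(rng: np.random.Generator, p: Categorical, n: int) -> np.ndarray:
    vals = rng.choice(np.asarray(p.levels, dtype=object), size=n, p=p.probs)
    if p.missing > 0:
        vals[rng.random(n) < p.missing] = None
    return vals


def make_cohort(spec: CohortSpec) -> tuple[SUVRMatrix, pd.DataFrame, np.ndarray]:
    """Draw a cohort: (SUVR matrix, covariate table, true phenotype labels).

    Row i of the SUVR matrix ~ Normal(cluster_means[c(i)], diag(cluster_sd^2));
    covariates are drawn independently within phenotype from
    ``spec.covariate_params``. Same spec + seed gives identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    means = spec.resolved_means()

    true_labels = np.repeat(np.arange(1, spec.k_true + 1), spec.cluster_sizes)
    X = means[true_labels - 1] + rng.normal(
        0.0, spec.cluster_sd, size=(spec.n_subjects, spec.n_rois)
    )
    subject_ids = [f"sub-{i:04d}" for i in range(1, spec.n_subjects + 1)]
    matrix = SUVRMatrix(
        data=pd.DataFrame(
            X,
            index=pd.Index(subject_ids, name="subject_id"),
            columns=[f"ROI_{i}" for i in range(1, spec.n_rois + 1)],
        ),
        provenance={"source": "synthetic", "seed": spec.seed, "cluster_sd": spec.cluster_sd},
    )

    table = {"subject_id": subject_ids}
    for name, per_phen in spec.covariate_params.items():
        col = np.empty(spec.n_subjects, dtype=object)
        start = 0
        for phen_idx, size in enumerate(spec.cluster_sizes):
            p = per_phen[phen_idx]
            if isinstance(p, Numeric):
                col[start : start + size] = _draw_numeric(rng, p, size)
            else:
                col[start : start + size] = _draw_categorical(rng, p, size)
            start += size
        table[name] = col
    cohort = pd.DataFrame(table)
    for name, per_phen in spec.covariate_params.items():
        if isinstance(per_phen[0], Numeric):
            cohort[name] = pd.to_numeric(cohort[name])
    cohort["true_phenotype"] = true_labels
    return matrix, cohort, true_labels
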