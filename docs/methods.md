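# Methods

`phenopet` implements an unsupervised phenotyping method for amyloid-PET
cohorts: regional tracer quantification after partial volume correction,
nonlinear dimensionality reduction of the regional feature vectors, k-means
clustering of the embedding, and a quantitative comparison of candidate
processing pipelines. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data generator does and
does not emulate.

## The point-spread model and partial volume correction

PET resolution is modelled as an isotropic Gaussian point spread function
(PSF) parameterised by its full width at half maximum (FWHM, mm), with
`sigma = FWHM / (2 sqrt(2 ln 2))` converted to voxel units per axis (so
anisotropic voxels are supported). The discrete operator is a separable,
truncated, discretely normalised Gaussian kernel. Two numerical choices
matter:

* **Truncation at 6 sigma.** The discarded tail mass is ~2e-9, which keeps
  two properties the correction oracles rely on at the 1e-9 level: blurring
  to a target resolution in two steps equals one step (Gaussian semigroup),
  and total activity is conserved for sources away from the volume boundary.
* **Edge renormalisation.** At the boundary the kernel is renormalised over
  its in-bounds support (equivalently: the blurred image is divided by the
  blurred ones-image). The operator therefore preserves constant images
  exactly, which makes the two-component correction an exact algebraic
  inverse for uniform in-mask activity.

Scanner harmonisation blurs every study to a common 8 mm FWHM using the
semigroup increment `sqrt(target^2 - native^2)`; sharpening is refused.

Three corrections are implemented behind one interface:

* `none` — the identity (the amyloid literature is genuinely split on
  whether PVC helps quantitative analysis, so "no correction" is a real arm);
* `pvc2c` — two-component (brain / non-brain) correction: divide by the
  blurred binary brain mask where it exceeds a threshold (default 0.2,
  configurable; below threshold the output is zeroed to stay finite);
* `rsf` / GTM — the regional spread function method: blur each atlas
  region's indicator, form the matrix `W[i, j]` = mean over region i of the
  blurred indicator of region j, and solve `W t = b` for the true regional
  means `t` given observed regional means `b`. The region-mean (not sum)
  convention makes `W` dimensionless and the recovery equation exact for
  regional means. With the regions tiling the grid (the
  `include_background` option models label 0 as a region) the rows of `W`
  sum to exactly 1 and recovery of a noiseless phantom is exact to solver
  tolerance — the package's central internal oracle. A condition number
  above 1e8 (configurable) triggers a least-squares fallback with a warning;
  a numerically singular matrix raises an error naming the degenerate
  regions. The GTM path returns regional measurements, not a corrected
  voxel image.

## SUVR features

The standard uptake value ratio of a region is its mean activity divided by
the pooled reference-region mean; pooling is voxel-count-weighted, i.e. the
plain mean over all reference voxels. The reference region is an explicit
configuration input recorded in provenance — conventionally cerebellar in
amyloid work, but the package does not hard-code an atlas label. SUVR is
invariant to global rescaling of the image. A cohort's vectors are assembled
subjects-as-rows with `ROI_<id>` columns (a ROIs-as-rows CSV is transposed on
load); the default feature dimension is 166 regions.

## Manifold embeddings

Three reductions are crossed into the pipelines. The embedding dimension `D`
is deliberately small; the study design asks for the smallest `D` that keeps
the clusters separable.

**t-SNE** is implemented from first principles. Per-point Gaussian bandwidths
are found by bisection so that each conditional neighbour distribution has
`2^entropy` equal to the perplexity (default 30; tolerance 1e-10 bits, which
makes the affinities match an independent brute-force evaluation to 1e-9).
Squared distances are shifted by their row minimum before exponentiation —
invariant after normalisation, and exactly uniform for equidistant
neighbours. Conditional probabilities are symmetrised, `p_ij = (p_{j|i} +
p_{i|j}) / 2n`, summing to 1 over ordered pairs. The map minimises
KL(P || Q) with Student-t similarities Q by gradient descent: seeded Gaussian
initialisation (sd 1e-4), learning rate 200, 1000 iterations, early
exaggeration x12 for 250 iterations, momentum 0.5 then 0.8, per-coordinate
adaptive gains. All defaults are configurable and logged; duplicate input
points trigger a warning (their perplexity cannot be calibrated).

**ISOMAP** builds the symmetric Euclidean k-NN graph, computes all-pairs
geodesics with the Floyd-Warshall algorithm (O(n^3), kept as the default
deliberately — exact and simple at cohort scale), and embeds with classical
MDS: double-centre the squared geodesics, take the top-D eigenpairs, scale by
sqrt(eigenvalue), truncating negative eigenvalues at zero with a warning. A
disconnected graph is rejected with the component sizes. Because strongly
clustered cohorts disconnect any small fixed neighbourhood, the pipeline grid
uses `n_neighbors="auto"`: the smallest k whose graph is connected (found by
doubling plus binary search). On data lying in a flat 2-D subspace the
embedding reproduces Euclidean distances to 1e-6.

**UMAP** is delegated to the reference `umap-learn` implementation behind the
same contract (seeded and deterministic; `n_neighbors` 15, `min_dist` 0.1).

## Clustering and pipeline selection

Lloyd k-means with the study's run parameters: best of 10 restarts, at most
200 iterations, convergence when the relative Frobenius norm of the centroid
shift is below 1e-4. Initial centroids are uniform random distinct points per
seeded restart (k-means++ available behind a flag); an emptied cluster is
re-seeded at the farthest point; the objective is asserted non-increasing at
every iteration. Labels are canonicalised by descending cluster size.

Cluster quality is scored by WCSS (within-cluster sum of squares), SSB
(between-cluster separation) and the mean silhouette. SSB is computed in two
conventions: the plain centroid form `sum_i ||mu_i - ga||^2` (reported and
used in ranking) and the size-weighted form, which satisfies the exact
decomposition `WCSS + SSB_weighted = total SS` — asserted to 1e-9 on every
clustering as a standing invariant.

`k` is chosen from a 1–20 scan by the elbow rule, formalised as the maximum
second difference of **log** WCSS(k). The log makes the rule invariant to the
overall scale of the embedding: nonlinear embeddings can place clusters so
far apart that the raw k=1→2 drop dwarfs the true elbow (observed in
practice), while the log-curvature picks the same elbow a human reads off
the curve. Ties break toward higher silhouette; a flat curve falls back to
the silhouette maximiser with a warning. `D` is the smallest candidate whose
k-means silhouette is within a configurable margin (default 0) of the best —
minimality is the point, since the embedding exists to make the cohort
manageable.

The nine pipelines cross {two-component, RSF, none} with {UMAP, t-SNE,
ISOMAP} under fixed ids (PP1 = pvc2c+umap … PP9 = none+isomap). Each
pipeline's clustering is evaluated against cognition: per-cluster MMSE
mean ± sd and the three pairwise one-way ANOVA p-values (two-group F-test,
F = t²; no multiple-testing correction by default, Bonferroni behind a flag;
a pair involving a cluster with fewer than two MMSE values scores p = 1, so
degenerate pipelines rank last instead of aborting the grid). Ranking is
lexicographic — mean pairwise p ascending, then WCSS ascending, then SSB
descending — and the rule string is recorded with every report so
alternative rules can be audited. Clusters are named by severity (descending
mean MMSE = least impaired first), with `phen1..phen3` aliases attached in
that order; ties break by cluster size with a warning.

The stratification step summarises clinical/epigenetic covariates per
phenotype: mean ± sd for numeric variables, level counts for categorical
ones, missing values excluded per variable and never imputed (counts +
missing always equal the phenotype size). Violin exports provide raw values
plus a Gaussian kernel density (Silverman bandwidth
`0.9 min(sd, IQR/1.34) n^(-1/5)`, recorded in the output) on a shared grid.

## The synthetic generator

Real amyloid cohorts are access-controlled, so the generator produces inputs
with the statistical structure the method assumes.

*Phantoms* are piecewise-constant labelled volumes (spheres, boxes, nested
shells; overlap rejected) blurred by the same discrete PSF the corrections
invert, with optional additive Gaussian noise (Poisson behind a flag; the
physics of scatter, attenuation and randoms is out of scope). The default
test phantom is 8 regions in a 48³ grid at 2 mm voxels with a shell-shaped
reference region.

*Cohorts* draw each subject's SUVR vector from one of k latent phenotypes
(diagonal Gaussian, per-ROI sd 0.1 by default). Cluster means are a fixed
baseline profile (uniform 0.9–1.6) offset along orthonormal directions so
every pair of means is `separation x sd x sqrt(n_rois)` apart — `separation`
(default 4) is therefore the ratio of between-cluster distance to the
typical within-cluster radius. Covariates are drawn independently within
phenotype from published three-phenotype marginals of a 518-subject amyloid
cohort: sizes 194/118/206; MMSE 28.97 ± 0.81 / 28.28 ± 1.40 / 29.31 ± 0.59
(clipped to the 0–30 scale, reproducing the ceiling effect of the real
instrument); ages 67.3 / 73.5 / 62.1; APOE risk, smoking, depression and
alcohol frequencies with per-variable missingness matching the published
known-value counts. A numeric `smoking_years` field extends the binary
smoking flag to support violin plots. Other totals rescale the size split
proportionally.

What passing tests on this generator show: the corrections invert the
forward model exactly; the optimisers find their optima; the selection rules
recover the generating k and a minimal D; the full grid recovers the latent
phenotypes and their cognitive separation at realistic effect sizes. What
they cannot show: behaviour under real scanner physics, registration error,
atlas mis-segmentation, non-Gaussian biological covariance between regions,
or covariate dependence within phenotype (the generator treats covariates as
independent given the phenotype, because only marginals are published).

## Problem sizes and reproducibility

The standing test suite exercises cohorts of 100–500 subjects with 20–166
ROIs and phantoms up to 64³ voxels; the recovery and selection studies use
50 independent cohorts of 500 subjects, which keeps every property estimate
comfortably away from its threshold while the whole suite runs in minutes on
a single core. All randomness flows from explicit integer seeds; per-stage
seeds are derived from one master seed with a CRC-based splitter, so a full
nine-pipeline run reproduces every artifact checksum under the same
configuration. Stochastic embeddings are bit-reproducible for a fixed seed
on a fixed platform.

## Known limitations

* GTM exactness holds for the package's own discrete PSF; on real data the
  true scanner PSF is neither Gaussian nor spatially invariant.
* The two-component correction recovers uniform activity only; non-uniform
  activity within the mask keeps a residual bias by construction.
* Floyd-Warshall is cubic in cohort size; fine at n ≈ 500, wrong tool at
  n ≈ 10⁵ (a sparse shortest-path algorithm would slot in behind the flag).
* The ranking mixes three criteria lexicographically; when mean p-values tie
  at numerical zero (strongly separated synthetic cohorts), WCSS decides,
  which favours the most compact embedding.
* Severity naming relies on MMSE alone; cohorts whose clusters do not differ
  in MMSE get a warned size-based tie-break.
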