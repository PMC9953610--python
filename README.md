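# phenopet

Data-driven phenotyping of Alzheimer's disease cohorts from amyloid-PET
imaging features. `phenopet` is for neuroimaging researchers who want to ask:
*given regional amyloid burden and cognitive scores, do subjects fall into
distinct phenotypes — and which processing pipeline separates them best?*

The method, end to end:

1. **Partial volume correction (PVC).** PET resolution (Gaussian PSF,
   quantified as FWHM) mixes each voxel's signal with its neighbourhood.
   Three strategies are compared: no correction; two-component (Meltzer)
   correction, `corrected = pet / (psf * brain_mask)` above a denominator
   threshold; and the regional spread function / geometric transfer matrix
   (Rousset) method, which solves `W t = b` for true regional activities,
   where `W[i,j]` is the fraction of region *j*'s activity observed in
   region *i*. All studies are harmonised to 8 mm FWHM first.
2. **SUVR features.** Each study becomes a vector of regional standard
   uptake value ratios (regional mean / pooled reference-region mean), 166
   regions by default; a cohort is a subjects x ROIs matrix.
3. **Manifold embedding.** The matrix is reduced to D dimensions by t-SNE
   (implemented from the affinity definitions up: perplexity-calibrated
   Gaussian affinities, Student-t low-dimensional kernel, KL minimised by
   gradient descent), ISOMAP (k-NN graph, Floyd–Warshall geodesics,
   classical MDS), or UMAP (delegated to `umap-learn`).
4. **Clustering and pipeline ranking.** Lloyd k-means (best of 10 seeded
   restarts) clusters each embedding; k comes from an elbow scan
   (log-WCSS curvature) and D from silhouette minimality. The nine
   PVC x manifold pipelines (PP1–PP9) are scored by per-cluster MMSE
   mean ± sd, pairwise one-way ANOVA p-values, WCSS and SSB, and ranked
   (mean p, then WCSS, then SSB). Clusters become severity-ordered
   phenotypes; clinical and epigenetic covariates (education, smoking,
   depression, APOE risk, alcohol) are stratified per phenotype.

Because the cohorts such methods target are access-controlled, the package
ships a first-class synthetic generator — phantoms whose true regional
activities are known by construction, and cohorts drawn from latent
phenotypes with published covariate marginals — so every stage is testable
offline against exact oracles.

## Worked example

```python
from phenopet import PhenotypingModel
from phenopet.synthcohort import CohortSpec, make_cohort

# a 500-subject cohort from 3 latent phenotypes (sizes scaled from 194/118/206)
matrix, cohort, truth = make_cohort(CohortSpec(seed=11).with_sizes(500))

model = PhenotypingModel(matrix, cohort, D=2, k=3)
results = model.fit(seed=42)
print(results.summary())
```

```
Phenotyping pipeline grid (PVC x manifold)
==========================================================
subjects: 500   D=2   k=3   seed=42
ranking rule: lexicographic: mean pairwise p (asc), WCSS (asc), SSB (desc)

         mmse_cluster1 mmse_cluster2 mmse_cluster3     wcss      ssb  p_cluster1v2  p_cluster1v3  p_cluster2v3  mean_p
pipeline
PP1       29.15 ± 0.51  28.80 ± 0.67  28.16 ± 1.05  290.541  292.562         0.000         0.000         0.000   0.000
...
PP5       29.15 ± 0.51  28.80 ± 0.67  28.16 ± 1.05 3635.404 1525.344         0.000         0.000         0.000   0.000
...

best pipeline: PP1 (mean pairwise p = 0.0000)
  phen1 (phen_least_impaired): cluster 0, n=198, mean MMSE 29.15
  phen2 (phen_intermediate): cluster 1, n=189, mean MMSE 28.80
  phen3 (phen_most_impaired): cluster 2, n=113, mean MMSE 28.16
```

Reading the output: every pipeline recovers the three latent phenotypes
(cluster MMSE means straddle the generating 29.31/28.97/28.28), all pairwise
p-values are below printed precision, so the tie-break falls to WCSS and the
most compact embedding ranks first. `results.phenotype_assignments()` gives
the per-subject phenotype, `results.phenotypes()` the severity mapping, and
`phenopet.epigenetics.stratify` / `violin_data` the covariate tables.

The same run is available from the shell:

```bash
phenopet synth cohort --n 500 --seed 11 --out data/
phenopet phenotype run --config config.yaml --out results/
phenopet synth phantom --grid 48 --fwhm 8 --out phantom/
phenopet pvc run --method rsf --pet phantom/pet.nii.gz \
    --labels phantom/labels.nii.gz --fwhm 8 --out corrected/
```

(`phenopet phenotype run` takes a YAML config; see `RunConfig` in
`phenopet.io` — a `synthetic:` block generates its inputs, otherwise point
`suvr_csv`/`cohort_csv` at your own files.)

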