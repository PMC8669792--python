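# lesioncov

Lesion covariance network analysis for cohorts of binary brain lesion
masks.

Gliomas do not appear uniformly across the brain: their locations cluster
around the ventricular horns, plausibly reflecting a subventricular origin
followed by migration along neural pathways. `lesioncov` turns that
hypothesis into a reproducible pipeline for any lesion cohort in a common
voxel space:

1. **Lesion covariance networks (LCNs).** Masks are folded to one
   hemisphere, stacked into a subjects × voxels matrix, and decomposed by
   spatial ICA (voxels as samples, subjects as observations) into `k`
   component z-maps with one score per subject. A Gaussian–Gamma mixture
   fitted to each z-map yields a probabilistic network map, thresholded at
   activation posterior > 0.5.
2. **Clinical associations.** Subjects are grouped by their
   highest-scoring component; groups are related to tumour grade and
   molecular subtype by chi-square tests with adjusted standardized
   residuals (Bonferroni post-hoc), and to overall survival by
   Kaplan–Meier curves and Cox proportional-hazards models (Breslow ties).
3. **Connectivity correspondence.** Each LCN is correlated with structural
   (Spearman, on voxels above a streamline-density threshold) and
   functional (Pearson) connectivity maps. Significance comes from a
   one-sided non-parametric test against variogram-matched surrogate maps
   that preserve the LCN's spatial autocorrelation:
   `p = (1 + #{r_null ≥ r_obs}) / (1 + N)`.
4. **Seed-based functional connectivity.** For every subcortical voxel, a
   cortical connectivity map is reconstructed from low-rank dense-connectome
   loadings, Fisher z-transformed, smoothed (5 mm FWHM) and correlated with
   each LCN; seed-level p-values are corrected by permutation-style
   cluster-level family-wise-error control on the surrogate null.

A synthetic-data module generates lesion cohorts, clinical tables,
connectivity maps and connectomes with planted ground truth, so every stage
is verifiable offline.

## Worked example

Generate a demo cohort, decompose it, and run the full pipeline:

```sh
lesioncov synth --out demo --n 60 --seed 3
lesioncov run-all --data demo --out results --seed 3
```

which reports every stage green:

```json
{
  "fold_stack": "ok",
  "decompose": "ok",
  "mixture": "ok",
  "assign": "ok",
  "clinical": "ok",
  "surrogates": "ok",
  "correspond": "ok",
  "sbfc": "ok"
}
```

`results/` then contains the LCN z-maps and posterior maps (NIfTI), subject
scores and group labels (TSV), clinical statistics (JSON), Kaplan–Meier
curves, correspondence tests and the cluster table. Running the stages
individually shows the planted structure being recovered — each LCN finds
its paired functional network and its paired subcortical cluster:

```sh
lesioncov decompose --masks demo/masks --out dec --seed 3
lesioncov correspond --data demo --zmaps dec --out corr --seed 3
lesioncov sbfc --data demo --zmaps dec --out sb --seed 3
```

`corr/correspondence.tsv` (excerpt — LCN 2 matches its planted network,
r = 0.56, Bonferroni-adjusted p = 0.045 with 199 surrogates):

```
lcn  network       method   r       p      p_adj
1    functional_1  pearson  0.017   0.380  1.0
2    functional_1  pearson  0.563   0.005  0.045
3    functional_1  pearson  -0.099  0.910  1.0
```

`sb/clusters.tsv` — one surviving subcortical cluster per LCN at
cluster-level FWE p < 0.05:

```
lcn  cluster  extent  peak_r  fwe_p
1    1        174     0.632   0.005
2    1        127     0.746   0.010
3    1        142     0.689   0.005
```

The library API mirrors the CLI (`lesioncov.decompose`,
`lesioncov.fit_mixture`, `lesioncov.make_surrogates`,
`lesioncov.surrogate_test`, `lesioncov.seed_scan`, `lesioncov.cluster_fwe`,
`lesioncov.cox_fit`, ...); see `docs/methods.md` for the model details and
parameter defaults.

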