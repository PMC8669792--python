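# Methods

`lesioncov` implements a lesion covariance network (LCN) analysis: a cohort
of binary lesion masks in a common voxel space is decomposed into a small
number of spatially independent components, component membership is related
to clinical and survival variables, and the components' spatial
correspondence with connectivity maps is tested against
autocorrelation-preserving surrogate nulls, including a subcortical
seed-based functional-connectivity scan with cluster-level family-wise-error
control. This note records the model choices, parameter defaults, and the
numerical decisions that were genuinely open, and states what the synthetic
validation does and does not demonstrate.

## Hemisphere folding

Diffuse gliomas are analysed irrespective of laterality, so every lesion is
folded onto one hemisphere before stacking. The midline of a synthetic grid
is the centre plane of the designated axis (voxel `i` mirrors to
`shape - 1 - i`); grids read from NIfTI carry their affine, for which the
`x = 0` plane is the natural midline. A right-majority lesion is mirrored
whole; any voxels remaining contralateral after the flip (bilateral
"butterfly" lesions) are mirrored onto the majority side and united by
voxelwise maximum, which preserves binarity. An exact left/right tie breaks
toward no flip and is logged. Paired left/right tract-density maps are
instead aligned and *averaged*, matching how such maps are normally
combined.

## Spatial ICA and z-maps

The stack (subjects x voxels, binary) is mean-centred per voxel and reduced
to `k` principal dimensions, treating voxels as samples and subjects as
observations — the orientation a subject-concatenated 4D volume gets in
probabilistic ICA. A symmetric fixed-point rotation with the log-cosh
contrast (scikit-learn's FastICA on the pre-whitened sources, `whiten=False`)
maximizes spatial non-Gaussianity. `k` defaults to 3 by the study design
(one component per ventricular horn hypothesis); automatic selection of `k`
is out of scope.

Source maps are scaled to z-maps by dividing the data-unit source estimate
by a single global residual-noise standard deviation — the square root of
the mean eigenvalue outside the retained `k`-dimensional subspace. This
preserves voxel ranking and the mixture fit's behaviour; the absolute scale
of a full variance-normalized probabilistic-ICA z-statistic is not
reproduced. Each map is sign-flipped so its skewness is nonnegative
(lesion load is positive), and subject scores are the corresponding mixing
columns rescaled to unit variance. The decomposition is deterministic for a
fixed seed; on non-convergence it restarts (at most 10 times) with derived
seeds and otherwise returns a flagged result.

Subjects are assigned to the component with their highest score; the
reported ambiguity margin (difference between the top two scores, in
score-sd units) operationalizes the check that no subject loads strongly on
several components at once. Components of two decompositions are matched by
Hungarian assignment on absolute spatial correlation, with one-sided
surrogate p-values per matched pair.

## Mixture-model thresholding

A component's z-values are modelled as Gaussian background plus a positive
Gamma activation class (optionally a mirrored negative-tail Gamma). EM uses
the weighted maximum-likelihood Gamma update (Newton on the shape), so the
log-likelihood is non-decreasing; initialization takes the Gaussian from
the trimmed central 90% and the Gamma from method-of-moments on the top
decile. Convergence tolerance 1e-6, at most 500 iterations. A degenerate
Gamma class (e.g. no positive mass) triggers a two-Gaussian fallback with a
warning. The network support keeps voxels whose activation posterior
strictly exceeds 0.5 — voxels more likely to be background noise are
excluded.

On desk-scale synthetic cohorts the posterior support of the
lowest-variance component can absorb the shared lesion halo, so supports of
distinct components may overlap even when the planted sources are disjoint;
the thresholding machinery itself produces near-disjoint supports when fed
maps with disjoint planted activations (tested), and spatial recovery of
the sources is asserted on the continuous z-maps, not the supports.

## Variogram-matched surrogate maps

Correlating two smooth brain maps against a naive permutation null grossly
overstates significance. The null implemented here matches the target map's
variogram (semivariance vs. distance): permute the map's values; smooth the
permutation with a truncated distance kernel over the `knn = 100` nearest
neighbours at each candidate bandwidth (`{0.1, ..., 0.9}` of the variogram
max lag, which is the 25th percentile of pairwise distances); fit
`target ≈ alpha * variogram(smoothed) + beta` by nonnegative least squares
over 25 distance bins; keep the best bandwidth; and return
`sqrt(alpha) * smoothed + sqrt(beta) * white noise`, rank-resampled against
the source map's values so every order statistic is preserved exactly.

Two numerical choices depart from the obvious defaults, both for measurable
reasons. First, the least-squares fit is weighted by the inverse target
semivariance (a relative-units fit): short-lag bins of a smooth map have
tiny semivariances that an unweighted fit ignores, leaving surrogates far
too rough at adjacent-voxel lags. Second, the default kernel is a truncated
Gaussian rather than a truncated exponential: exponential-kernel fields are
non-differentiable and their short-lag semivariance cannot be brought
within ~15% of a smooth target by any (alpha, beta); the exponential kernel
remains available (`kernel="exp"`). With these defaults the mean surrogate
variogram of a smooth map (white noise at 8 mm FWHM on the 4 mm synthetic
cortex) tracks the target within 15% per bin, and surrogate variogram SSE
beats permutation-only surrogates in ≥ 95% of draws.

The one-sided test is `p = (1 + #{null_r >= r_obs}) / (1 + N)`; ensembles
are generated once per LCN and reused across every comparison of that LCN.
The production default is N = 999 (the study-scale figure of 10 000 is
supported but unnecessary at desk scale); N = 199 is used for calibration
experiments. Multiple comparisons across a network family are corrected by
Bonferroni (default, matching the tabulated results style) or
Benjamini–Hochberg. Structural comparisons use Spearman correlation on
voxels exceeding a streamline-density fraction (default 1% of total
streamlines — appropriate for concentrated tract maps; the pipeline falls
back to the full domain with a warning when that mask is nearly empty, as
happens for diffuse desk-scale density stand-ins); functional comparisons
use Pearson on grey-matter voxels.

## Seed-based functional connectivity and cluster FWE

A dense functional connectome is represented by component loadings
(voxels x c); connectivity between two voxels is the inner product of their
unit-normalized loading rows. Whether component weights (eigenvalues)
multiply the loadings before normalization is configurable and on by
default. Per subcortical seed: cortical connectivity map → Fisher z
(`atanh`, inputs clipped to ±(1 − 1e-7)) → mask-aware Gaussian smoothing at
5 mm FWHM (transform before smoothing, following the processing order as
described) → Pearson r with the LCN's cortical values → one-sided surrogate
p from the LCN's ensemble.

Cluster-level correction thresholds seeds at voxel-wise p < alpha, forms
connected components (26-connectivity default; 6 and 18 available), and
compares each observed extent with the null distribution of the *maximum*
extent: each surrogate in turn plays the observed map, its per-seed
correlations are ranked against the remaining surrogates (leave-one-out, to
avoid double-dipping), thresholded identically, and the largest surviving
cluster recorded. `fwe_p = (1 + #{null max extent >= extent}) / (1 + N)`.

The voxel-forming threshold interacts with the ensemble size: with N
surrogates the smallest attainable p is `1/(1+N)`, so voxel-wise p < 0.001
requires N ≥ 999. The pipeline keeps 0.001 as its production default and
warns when it is unattainable; calibration and recovery experiments at
N = 199 use voxel-wise p < 0.01 for this reason. Under the global null the
empirical family-wise error at nominal 0.05 measures ≈ 0.02 (conservative,
as expected from discrete surrogate ranks).

## Clinical statistics

Associations between LCN group and pathology variables use Pearson
chi-square tests without continuity correction, with listwise deletion of
missing data per analysis. Post-hoc inspection uses *adjusted standardized
residuals*, `(O − E) / sqrt(E (1 − rowsum/n)(1 − colsum/n))`, whose
two-sided normal p-values are Bonferroni-multiplied by the cell count; this
definition reproduces the conventional published residual→p mapping (e.g.
residual 3.29 in a 6-cell table → p ≈ 0.0060), whereas raw `(O−E)/sqrt(E)`
residuals (also available) do not. Survival is summarized by Kaplan–Meier
product-limit curves (lifelines) and modelled by Cox proportional-hazards
regression with Breslow tie handling via statsmodels `PHReg`, verified
against R `survival::coxph(ties="breslow")` to 7 decimals on a tied
fixture. Categorical terms are dummy-coded against fixed reference levels
(group 3, GBM, IDH-wt, female); age enters as the indicator of exceeding
the cohort median. Degenerate designs (constant covariates, monotone
likelihood) are dropped or flagged rather than raised.

## Synthetic study conditions

The generator plants every structure the analysis assumes, on a
desk-scale grid chosen so the full pipeline runs in seconds per cohort:
24³ voxels at 4 mm (brain ellipsoid ≈ 6 000 voxels, cortical shell ≈ 3 700,
left-hemisphere subcortical band ≈ 670). Defaults: `k = 3` sources anchored
on an inner "ventricle" arc (anchors ≥ 8 voxels apart) and extending as
Gaussian tubes (sigma 2.6 voxels) into the cortical shell, half-max
supports pairwise disjoint; cohort `n = 240` with uniform class
probabilities; lesions are the top-occupancy excursion set of
source + smoothed noise (noise sd 0.6 of the source peak, noise FWHM 2
voxels), pruned to the component containing the source anchor, with 30% of
subjects generated on the right hemisphere to exercise folding. Mean
occupancy is 6% of the brain with a lognormal spread (sigma 0.45 in log
units, clipped): glioma volumes vary widely between patients, and this
variation is also what gives the class-amplitude subspace full rank — with
identical lesion sizes the three class-membership patterns span only two
dimensions after centring and the third component degenerates to noise.

Clinical labels are drawn from per-source multinomials (source 1 enriched
for lower-grade and IDH-mutant/1p19q-codeleted tumours, echoing the
motivating cohort's structure); age ~ N(53, 15) years; survival is
exponential with log-hazard `beta_group + 0.7 * 1[age > median]` (group 1
HR 0.6, baseline hazard 0.035/month) under independent exponential
censoring (0.015/month, ≈ 30% censoring). Connectivity networks mix a
source with smoothed noise at a known weight `a`; structural stand-ins add
a squared-value density map. The synthetic connectome embeds each source's
cortical pattern in one component together with a Gaussian bump (amplitude
1.5, sd 2 voxels) on a paired subcortical node, plus smoothed-noise
components at relative weight 0.3 — weights chosen so node seeds reproduce
their source's cortical pattern at r ≥ 0.7 while leaving substantial
off-target structure.

What passing tests show: the implementation recovers exactly the structures
planted under these conditions (spatial sources at mean matched |r| ≥ 0.85,
group assignment ≥ 0.9, hazard ratios, correspondence power, cluster
locations) and its null procedures are calibrated against its own surrogate
model. What they do not show: robustness to registration error, to
non-stationary lesion texture, to mass effect and infiltration geometry, or
to real connectome rank structure — none of which the generator emulates.

## Determinism and seeds

Every stochastic operation takes an explicit seed; per-stage seeds derive
from one master seed by stage-name hashing (SHA-256, reduced below 2³¹), so
adding a stage never perturbs another stage's draws. Reruns with the same
seeds produce byte-identical tabular outputs.
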