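# Methods

## Problem and model

Visceral pleural invasion (VPI) — tumor penetration beyond the elastic layer
of the visceral pleura — upstages a lung adenocarcinoma to T2 regardless of
size, so a noninvasive preoperative VPI predictor for subpleural nodules
found on low-dose CT (LDCT) screening has direct clinical value.  This
package implements a habitat-imaging pipeline for that prediction task and
compares three logistic signatures on each cohort:

* **radiological** — backward-eliminated logistic regression on geometric
  measurements (maximal diameter, solid-component diameter,
  consolidation-to-tumor ratio CTR, lesion–pleura distance DLP, pleural
  contact lengths PL and SPL);
* **whole-lesion radiomic** — the same modeling chain on 106 IBSI-style
  features of the whole lesion;
* **habitat** — the chain on 93 features per habitat (279 for K = 3), where
  habitats are intratumoral subregions found by unsupervised clustering.

Habitats are built per lesion by over-segmenting the z-normalized volume
into ~50 spacing-aware SLIC superpixels, summarizing each superpixel by ten
gray-level histogram statistics (mean, median, variance, skewness,
kurtosis, min, max, 10th/90th percentile, 25-bin entropy), pooling training
superpixels, and K-means clustering (k-means++, 10 restarts, tolerance
1e-6, fixed seed).  The fitted centroids and feature standardization are
frozen and applied unchanged to validation/test lesions; habitat identity
is the centroid index, with no relabeling across cohorts.  The cluster
count is chosen as the Davies–Bouldin argmin over K = 2..10 (ties to the
smaller K); the shipped study configuration fixes K = 3, matching the
rim / transition / core phenotypes the phantom constructs.

## Synthetic cohorts

The multicenter patient data behind this design are not publicly deposited,
so the package ships a first-class phantom generator
(`habitatvpi.phantom`) whose defaults define the study conditions used by
every test and experiment:

* **geometry** — a spherical nodule (diameter 10–28 mm; nodules ≥ 30 mm are
  excluded by design) near an axis-aligned pleural plane; 65% of nodules
  contact the pleura (the plane clips the sphere; PL and SPL are the chord
  lengths of lesion and solid component in the plane), the rest sit 0.5–6 mm
  away; 60% are part-solid with solid fraction 0.3–0.85, the rest solid
  (0.85–1.0).
* **subregions** — concentric rim / transition / core with a smoothly
  perturbed boundary (5% radial jitter) and *per-case composition*: the
  normalized core and transition radii are drawn per nodule (0.40–0.60 and
  0.70–0.88), because real tumors differ in subregion proportions and that
  variability is what dilutes whole-lesion summaries of subregion-local
  properties.  Part-solid mean attenuations are −600 / −300 / +20 HU plus a
  +280 HU solid component (kept below the 400 HU clip so intensity signals
  are not censored); solid-type nodules −280 / −80 / +100 HU (+80 HU
  solid); voxel noise 45 HU.  These contrasts were chosen once so the
  frozen K = 3 clustering recovers the constructed subregions (mean
  adjusted Rand index > 0.6) while solid-type nodules remain harder than
  part-solid — which also produces missing habitats in roughly 10% of
  lesions, the phenomenon the imputation stage exists for.
* **batch effects** — five center–scanner batches, each applying a
  multiplicative scale (0.94–1.05), then an additive shift (−20..+15 HU),
  then extra noise (0–10 HU), before clipping to [−1024, 400] HU.
* **label model** — VPI is drawn from a logistic model on standardized
  covariates: solid diameter (β = 0.5), SPL (β = 0.4), a rim-texture
  latent (β = 1.5), and a core-attenuation latent (β = 1.2) shifting the
  core mean by 60 HU per unit.  The rim-texture latent sets the *spatial
  correlation length* of the rim noise (0.8·exp(0.5·z) voxels at fixed
  45 HU amplitude) rather than its amplitude — a coarse-vs-fine texture
  contrast that survives the fixed-bin-count discretization used for
  texture extraction, where a pure amplitude change would be normalized
  away.  Label-independent nuisance latents give the transition zone its
  own correlation length and a ±60 HU mean offset, so whole-lesion
  summaries of the rim/core signals are confounded by transition-zone
  heterogeneity while per-habitat features stay clean.  The intercept is
  solved by bisection so the expected prevalence matches the configured
  value (default 0.38).  Putting most of the label signal into
  subregion-local image properties is deliberate: it is the regime in
  which habitat analysis should outperform whole-lesion radiomics, and
  the directional experiments test exactly that.

What the phantom does **not** emulate: CT physics (beam hardening,
reconstruction kernels), lobulation/spiculation and other semantic signs,
non-planar pleura, and segmentation error (masks are ground truth).
Passing tests therefore demonstrate the correctness and internal logic of
the pipeline under its own assumptions, not clinical performance on real
LDCT.

## Preprocessing

Volumes are resampled to 1 mm isotropic (trilinear; masks nearest-neighbor).
Two intensity paths share that grid: the clustering path clips to the lung
window (−1250..250 HU) and z-normalizes within the lesion (population
variance, exact and testable); the texture path discretizes the masked
intensities into 25 equal-width bins (half-open intervals, top edge closed).
Fixed-bin-*count* discretization over the masked range was chosen over
fixed bin width; z-normalization is per-lesion.  Per-habitat texture
re-discretizes within the habitat mask (configurable to lesion-wide bins).

## Feature catalog

106 whole-lesion features: 14 shape, 18 first-order, 24 GLCM, 16 GLRLM,
16 GLSZM, 14 GLDM, 5 NGTDM, minus one excluded co-occurrence feature.
The exclusion is an explicit catalog entry (`EXCLUDED_FEATURE`), default
`GLCM_SumAverage`, which under matrix symmetry duplicates 2·JointAverage.
Per habitat, shape features are dropped except `shape_VoxelVolume`,
giving 93 per habitat.  Texture matrices use distance-1 neighborhoods,
26-connectivity, 13 unique directions averaged (GLCM/GLRLM); GLDM uses
α = 0.  Degenerate inputs follow fixed conventions: constant regions give
zero skewness/kurtosis/ClusterShade/NGTDM-Contrast; single-voxel
superpixels give zero variance.  Every matrix family is verified against
nested-loop brute-force constructions in the test suite.

## Harmonization

Feature-level parametric empirical-Bayes ComBat (normal / inverse-gamma
priors), written against the standard location–scale formulation and
cross-checked in the tests against Bioconductor `sva::ComBat` (agreement to
1e-4 on a shared fixture).  The model is fitted on the training split only
and applied frozen elsewhere; the outcome is *not* included as a protected
covariate by default (configurable).  Zero-variance features pass through
untouched.  The audit computes per-feature one-way-ANOVA batch R² before
and after, their means, the relative reduction, and a paired t-test.

## Modeling

Selection chain on z-scored training features (statistics frozen for other
splits): (1) Spearman pruning at |ρ| > 0.9, keeping the pair member with
the smaller Mann–Whitney p; (2) Mann–Whitney screen at two-sided p < 0.05
(exact U for small untied samples); (3) mRMR, MID difference scheme with
mutual information on equal-frequency 4-bin discretized features, top 10;
(4) L1-penalized logistic path with λ chosen by stratified 10-fold
cross-validated log-loss (minimum, not 1-SE).  The final fit is backward
elimination at stay-threshold p < 0.05 with Wald odds-ratio CIs.  The
probability cutoff is the training-set Youden point (ties to the lower
cutoff; classification is strictly above the cutoff).  On small cohorts
the pipeline uses a `min_features=1` floor so elimination cannot empty a
signature; the library default raises instead, which is the faithful
behavior.  The package also ships the three published signature equations
as reference JSON models (`habitatvpi/reference/`); they are data, not
fitted artifacts.

## Evaluation

AUC uses the Mann–Whitney midrank formulation; its CI uses the DeLong
structural-components variance on the logit scale (so the interval respects
[0, 1]).  Paired model comparison is DeLong's test; a type-I calibration
experiment (two noisy copies of one latent score, n = 150, 2000 null
replicates) checks the nominal 5% level.  Calibration uses the Brier score
and 10 equal-width reliability bins; decision curves use
NB(t) = TP/n − FP/n·t/(1−t) on a 0.01–0.80 grid (step 0.01).  Inter-rater
agreement is ICC(2,1) — two-way random effects, absolute agreement, single
measurement — matching `pingouin`'s ICC(A,1); the form is a package choice,
flagged here because alternatives (ICC(3,1), averaged raters) give
different values.

## Missing-habitat imputation

Absent habitats produce whole 93-column missing blocks.  Imputation is an
iterative random-forest scheme in the missForest style: columns are grouped
by identical missingness pattern (one group per absent-habitat block), each
group is re-imputed jointly by a multi-output random forest
(mtry = √p, 20 trees) trained on the complete cases, and the loop stops
when the relative change in imputed values increases or after 5 iterations.
The block-wise grouping is an adaptation to the known block structure; on
held-out truth it beats single-pass mean imputation, which is the test's
oracle.  Imputation runs per split to avoid information flow into training.

## Problem sizes and numerical choices

Experiments and tests run at desk scale, chosen as the smallest sizes at
which the tested signals are stable: unit fixtures ≤ 4×4×2 voxels;
shared cohorts of 60 cases; determinism checks at n = 60; the directional
habitat-vs-radiomic comparison on 20 cohorts of n = 150 (training fraction
0.8 — large enough that the four-step selection chain is stable; at n ≤ 100
selection noise on the training split frequently swamps the true model
ordering); DeLong calibration at 2000 replicates.  Phantom volumes are generated
at 0.8×0.8×1.0 mm spacing and resampled to 1 mm isotropic.  Splits sort
case ids deterministically before the 7:3 train/validation cut (emulating a
scan-date ordering); every stochastic stage is seeded from one master seed.

## Known limitations

* The phantom's pleura is a plane and its nodules are spheres; contact
  lengths are in-plane chords.  Real pleural geometry is curved and
  measurement conventions differ.
* Habitat counts beyond K = 3 are supported but untested against truth
  (the generator constructs exactly three subregions).
* The LASSO path uses liblinear coordinate descent; coefficients at very
  weak penalties can differ from an unpenalized fit in the 1e-2 range.
* DeLong's normal approximation is used at all sample sizes; very small
  cohorts (< ~20 per class) would warrant exact or bootstrap methods.
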