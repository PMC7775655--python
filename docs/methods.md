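# Methods

This note documents the models, conventions, and design choices behind
`pituradiomics`, in the order the pipeline runs them.

## Synthetic phantom cohorts

The generator produces the statistical structure the analysis assumes, not
anatomy. Each case is an ellipsoidal "tumor" embedded in Gaussian
background noise on a shared grid (default 64×64×24 voxels at 1×1×3 mm,
coronal-like anisotropy), rendered in two channels (CE-T1-like and
T2-like) with independent noise and texture draws.

- **Contrast.** The tumor mean sits `intensity_contrast` background-SDs
  above background (default 3.0 — a clearly enhancing lesion that still
  forces the segmenter to work).
- **Texture.** Within-tumor intensity variation is a Gaussian random field:
  white noise smoothed at correlation length `texture_granularity_mm`,
  rescaled to `heterogeneity_sd`. One parameter therefore controls NGTDM
  coarseness monotonically: larger granularity ⇒ locally more uniform
  texture ⇒ higher coarseness.
- **Classes.** Progression/recurrence (P/R) cases draw larger tumors
  (log-normal around 35.5 mm maximum height vs 18 mm for non-P/R, matching
  the cohort medians the generator emulates) and coarser texture
  (granularity 3.0 vs 1.2 mm, heterogeneity 1.0 vs 0.6). Texture effect
  sizes are free design parameters of the phantom — no claim about real
  cohorts is attached to them.
- **Class split.** The number of P/R cases is `round(n · prevalence)`
  exactly, with labels shuffled; at n=50 and prevalence 0.56 every seed
  yields 28 P/R cases. A split that would leave fewer than 2 cases in
  either class is rejected.
- **Progression rule by construction.** Follow-up lesion dimensions grow
  by Uniform(−1, 2) mm per axis for non-events (never strictly above
  2 mm), while events additionally grow by Uniform(3, 15) mm on one random
  axis. The generated labels therefore agree exactly with
  `label_progression` on every case, which the tests assert.
- **Survival.** Progression-free time follows a Weibull
  proportional-hazards model (shape 1 by default, i.e. exponential;
  closed-form inverse sampling). The log-hazard is linear in a latent
  severity (class indicator + 0.3 × standardized log tumor height); the
  baseline rate ln2/90 per month and a class log-HR of ln 3 put the median
  time-to-P/R near 20 months. Event times for labeled P/R cases are drawn
  from the hazard model conditioned on occurring before the administrative
  censoring time (default 96 months, inverse-CDF truncation); non-events
  are censored there. The unconditional primitive `simulate_survival` is
  what the calibration and power checks exercise.
- **Covariates** are drawn from class-conditional frequencies matching the
  published cohort profile (e.g. visual disturbance 92.9 % vs 59.1 %) so
  the group-comparison and Cox machinery sees realistic tables.

What phantoms do **not** emulate: pituitary anatomy, cavernous sinus
geometry, bias fields, scanner artifacts, partial-volume effects, or
inter-scanner variability. Passing tests demonstrate the algorithms, not
clinical performance.

## Segmentation chain

`resample_isotropic` interpolates trilinearly onto an isotropic grid at
the minimum input spacing (nothing is downsampled), preserving the grid
origin; world extent changes by less than one voxel. `normalize_roi`
applies the affine intensity map that gives the in-mask population
(n-denominator) mean 0 / SD 1 to the whole volume.

`fcm_segment` runs fuzzy c-means per slice on the intensities inside the
operator rectangle: k = 2 clusters, fuzzifier m = 2, objective tolerance
1e−5 (relative to the initial objective), ≤300 iterations, k-means++-style
seeded centroid initialization on the distinct intensities. The objective
Σ u^m d² is non-increasing by construction (asserted in tests); the lesion
cluster is the higher-centroid one (enhancing tissue on CE T1). A slice
that fails to converge keeps its best iterate and emits a warning.

`postprocess_mask` keeps the largest 26-connected 3D component, fills
holes slice-wise in 2D, then in 3D. `transfer_mask` resamples the mask as
a continuous field through a voxel-to-voxel affine with linear
interpolation and binarizes at 0.5; identity transforms reproduce the
input exactly. In the synthetic pipeline both channels share the grid
after resampling, so the transfer is an identity affine; the operation is
exercised with rigid transforms in the tests.

**Erosion.** `erode_shell` removes the boundary shell through the 3D
spacing-aware Euclidean distance transform: a voxel survives iff its
distance to the mask boundary is ≥ the requested depth (0.25 / 0.5 cm).
A 3D — rather than per-slice 2D — erosion is used deliberately: the
operation's contract is a physical depth, and only the 3D distance
guarantees that every retained voxel is at least that far from the tumor
surface (per-slice erosion leaves top/bottom-slice voxels touching the
boundary and overshoots the analytic eroded-sphere volume by ~13 %).
Eroding a small lesion away raises an error advising the original
variant; the pipeline records such cases and keeps the original mask for
them so variant cohorts stay complete (also when fewer than 8 voxels
survive, too few for texture statistics).

## Feature bank

214 features per case: 107 per modality — 18 first-order, 14 shape
(computed once from the shared mask, duplicated under both modality
namespaces), 24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM. No filtered
(wavelet/LoG) images. Names are `{modality}_{family}_{feature}` and stable
across runs.

- **Discretization:** equal-width binning of the z-normalized in-mask
  intensities into 32 levels (min → level 1, max → level 32); exposed as
  configuration. All texture features are therefore invariant to affine
  intensity rescaling, which a test asserts.
- **First order:** population moments; skewness = standardized third
  moment, kurtosis = excess kurtosis (both 0 for constant ROIs); entropy
  and uniformity on the same 32-bin histogram.
- **Shape:** surface area and volume from a marching-cubes isosurface in
  physical coordinates. The mask is smoothed with a 0.6-voxel Gaussian
  before meshing; a raw binary isosurface carries a staircase bias that
  inflates a digitized sphere's surface ~10 %, while the smoothed mesh is
  within ~3 % (sphere) and ~4 % (cube) of the analytic
  surface-to-volume ratios. Axis lengths come from PCA of the voxel
  centers (length = 4√eigenvalue); diameters are maximal pairwise
  distances over convex-hull vertices.
- **GLCM:** symmetric, normalized co-occurrence at distance 1 for each of
  the 13 unique 3D directions; features computed per direction and
  averaged. Logs base 2. IMC1 = (HXY − HXY1)/max(HX, HY). Degenerate
  conventions: single gray level ⇒ IMC1 = IMC2 = 0, correlation = MCC = 1;
  a single-voxel ROI (no pairs) raises.
- **NGTDM:** 26-neighborhood means over in-mask neighbors only;
  coarseness = 1/Σ pᵢsᵢ with sentinel 1e6 for perfectly uniform ROIs.
- **GLRLM** (runs along the 13 directions, feature-averaged), **GLSZM**
  (26-connected equal-level zones), **GLDM** (dependence = count of
  26-neighbors within level tolerance α = 0, stored at column d+1) follow
  the standard emphasis/nonuniformity/variance/entropy definitions; matrix
  sums conserve voxel, run, or zone counts.

Every matrix family is checked exactly against deliberately naive
brute-force enumeration oracles on small ROIs, and the GLCM family
additionally against scikit-image's `graycomatrix`/`graycoprops` under
matched 2D settings (agreement is exact to machine precision, r = 1.0
across 30 phantoms).

## Selection, SVM score, and evaluation

The classifier is an SVM with the scale-free Gaussian kernel
G(xₙ,x) = exp(−‖xₙ−x‖²) (γ = 1 on per-fold standardized features) and box
constraint C = 1; both are configurable. The selection objective is the
mean misclassification rate under stratified 10-fold CV, averaged over
independently re-randomized repeats (protocol default 1000; tests and the
acceptance script use 1–5 repeats and state so — the estimate is the same
quantity at higher variance). Folds are clamped to the minority-class
count for small cohorts. Greedy forward selection accepts the best
candidate feature only if it improves the objective by ≥ 1e−6 (the
termination tolerance), stopping otherwise or at `max_features` (3, the
model depth used for this application). Candidates are scored on identical
folds and ties break toward the canonically first feature name, making
selection invariant to column order.

`train_svm` stores the support-vector expansion explicitly (weights
wₙ ≥ 0, labels yₙ, bias b, standardization parameters); `svm_score`
evaluates f(x) = Σ wₙyₙexp(−‖xₙ−x‖²) + b directly and matches the
library decision function to 1e−8 (the SMO tolerance is tightened to 1e−8
so the fit is solver-order invariant).

A known behavior of the scale-free kernel worth recording: because γ is
fixed while squared distances grow with the number of selected features,
the marginal CV gain of a feature that merely duplicates an existing shift
direction can shrink below the gain of a best-of-many noise feature. The
planted-signal recovery check therefore plants features that are
individually detectable *and* jointly indispensable (a 1.5 SD common class
shift plus an extra 3.0 SD on one of the three features per positive
case); under that design forward selection recovers all three before any
noise feature in ≥ 90 % of replicates. With three identically shifted
(fully redundant) planted features the third is recovered only ~60 % of
the time — a property of the kernelized objective, not of the
implementation.

`roc_analysis` sweeps all score thresholds (rule: positive iff
score ≥ cutoff), computes the trapezoid AUC (identical to the normalized
Mann-Whitney U statistic, asserted to 1e−10), and returns the Youden-J
maximizing cutoff, breaking ties toward higher specificity. Confusion
summaries carry TP/TN/FP/FN, accuracy, AUC, and the cutoff. The pipeline
evaluates confusion rows on out-of-fold SVM scores (each case scored by a
model that never saw it).

## Outcome statistics

- **Progression:** strictly more than 2.0 mm growth on at least one axis
  (exactly +2.0 mm is not progression).
- **Resection extent:** GTR iff residual volume < 10 % of the original.
- **Group comparisons:** categorical variables use the chi-square test,
  switching to Fisher's exact test when any expected cell count is < 5
  (Fisher applies to 2×2 tables; larger sparse tables keep chi-square with
  a warning). Continuous variables use the two-sided Mann-Whitney U and
  are summarized as median (IQR).
- **Survival:** Kaplan-Meier per group with a two-sided log-rank test;
  Cox proportional hazards via lifelines (Efron tie handling, suitable for
  month-resolution ties). Multivariate mode automatically promotes exactly
  the covariates with univariate p < 0.05. Non-convergence or separation
  is surfaced in a flags field, never silently dropped. Where Cox reports
  per-unit hazard ratios, continuous covariates (age, height, volume,
  score) enter untransformed.

## Pipeline and provenance

`run_pipeline` executes segment → features (original, 0.25 cm, 0.5 cm
variants) → select → score → ROC/cutoff → per-variant confusion →
Kaplan-Meier/Cox, writing a run directory (`masks/`, `features/`,
`model/`, `reports/`). Every table and the summary JSON embed a SHA-256
hash of the analysis-relevant configuration plus the seed; re-running with
the same configuration reproduces the feature CSVs byte-for-byte. The
operator's bounding rectangle is derived from the truth mask with a
3-voxel margin in synthetic runs; a mask-override hook stands in for
manual correction.

## Problem sizes and numerical choices

Tests and the acceptance script run the full algorithms at reduced problem
sizes chosen as the package's own defaults for desk-scale verification:
phantom grids of 32–64 voxels per axis, cohorts of 12–50 cases, selection
with 1–5 CV repeats, 20-seed segmentation batches, 100-replicate survival
batches at n=500. The survival-recovery check (true HR 2, estimate within
[1.7, 2.4]) is intrinsically tight: the Cox log-HR standard error at n=500
is at best √(4/500) ≈ 0.089, so ~94 % of replicate batches pass the band
even with near-complete follow-up; the check uses light censoring
(baseline rate 0.05/month, administrative censoring at 60 months, ~95 %
events).

## Known limitations

- Phantom simplicity means segmentation Dice (~0.93) and classification
  accuracy on synthetic cohorts overstate what any of this achieves on
  clinical images.
- The FCM segmenter assumes a bright lesion on the clustered channel;
  non-enhancing or cystic lesions would need the mask-override hook.
- Shape features inherit marching-cubes digitization error (few percent at
  typical lesion sizes; worse below ~5 mm radius).
- The cohort-level covariate generator draws covariates independently
  given the class, so covariate-covariate correlations (e.g. height vs
  chiasm compression) are not reproduced.
- GLCM/GLRLM direction aggregation averages feature values, not matrices;
  conventions differ across radiomics software, so absolute values are
  comparable only under matched settings.
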