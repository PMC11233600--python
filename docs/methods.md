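# Methods

`habitatrad` implements a habitat-radiomics workflow for predicting a
binary molecular label (EGFR mutation status) from CT volumes of early
stage lung nodules, and a synthetic phantom generator that makes every
stage of that workflow verifiable without patient data. This note
records the model, the parameter choices, and the places where the
design was genuinely open.

## The synthetic cohort model

No public CT cohort with EGFR labels exists at the scale needed for
testing, so the generator builds spherical nodule phantoms whose
internal texture heterogeneity carries the class signal:

- **Geometry.** A nodule is the set of voxels whose centers lie within
  `nodule_radius_mm` of a voxel-centered origin, on a grid with
  (possibly anisotropic) spacing. Cohort defaults: 36x36x24 voxels at
  0.8x0.8x1.25 mm (a typical chest-CT reconstruction), radius drawn
  uniformly from 5-8 mm, background -800 HU.
- **Plateaus.** The nodule interior is partitioned into `n_plateaus`
  (default 3) intensity plateaus. The default geometry is
  equal-thickness *axial slabs*. Flat interfaces are deliberate: for any
  window-statistics classifier, exact recovery of the planted partition
  requires every voxel's 3x3x3 window to be majority-own-plateau, which
  flat interfaces guarantee (the outermost slab layer sees 18 own vs 9
  foreign window voxels) and curved radial interfaces provably violate
  (on lattice-sphere shells we measured voxels with up to 70%
  foreign-window fraction). Radial shells and Voronoi blobs remain
  selectable geometries for sensitivity work; they are *not* exactly
  recoverable.
- **Class signal.** Each sample draws a latent plateau-contrast
  `c ~ N(120, 25) HU` (wild-type); mutants shift the mean by
  `effect_size_d` (default 1.5) within-class SDs. Plateau levels are
  `mean_hu + c * linspace(-1, 1, n_plateaus)`, plus `noise_sd = 20` HU
  i.i.d. Gaussian noise. An ideal observer of the latent alone has
  Bayes AUC `Phi(d / sqrt 2)` (0.856 at d = 1.5) — chosen so the
  designed separability sits in the range reported for habitat
  signatures on real cohorts.
- **Clinical covariates.** Class balance defaults to 63.8% mutant;
  smoking prevalence is (0.228, 0.474) and female fraction
  (0.655, 0.443) for (mutant, wild-type), mirroring the class-covariate
  associations of published surgical stage I NSCLC series. Stage, CT
  pattern, histology and lobe are sampled label-independently, because
  only smoking survives multivariable clinical analysis in that
  literature.
- **Reproducibility.** One root `SeedSequence`; child 0 drives labels
  and clinical covariates in sample order, children 1..n drive the
  volumes, so per-sample generation could be parallelized without
  changing the output.

What the generator does **not** emulate: lung anatomy, partial-volume
and reconstruction-kernel effects, ground-glass attenuation physics,
scanner batch effects, or any *known* image correlate of EGFR status —
the texture-shift mechanism is a modeling device. Passing tests
therefore demonstrate that the pipeline recovers the signal it is
pointed at, not that the signal exists in real CT.

## Preprocessing

Fixed order: clip HU to [-800, 800], then resample to isotropic 1 mm^3
(SimpleITK, tri-linear for intensities; the mask is interpolated as a
float field and re-binarized at 0.5, preserving sphere volumes to well
under 5%). Output shape per axis is `round(extent / target)`, keeping
physical extent to within one voxel. Interpolation orders are config
fields so alternatives are testable.

## Regions

- **Peritumoral shells.** Dilation is defined in physical units: a
  voxel joins the dilated set iff its center is within `r` mm of some
  ROI voxel center, computed exactly via the Euclidean distance
  transform of the mask complement with per-axis sampling. The shell is
  the dilation minus the tumor (a dilation reaching the grid edge warns
  and clips). Radii 1, 3, 5 mm.
- **Local feature map.** For every tumor voxel, 13 statistics of its
  3x3x3 window: mean, median, min, max, range, variance, SD, skewness,
  kurtosis, energy (sum of squares), entropy, uniformity, coefficient
  of variation. Windows are truncated at the grid edge and, by default,
  to in-ROI voxels — otherwise rim windows ingest -800 HU background
  and habitats degenerate into distance-to-surface bands. The
  entropy/uniformity histogram uses a 25 HU bin width anchored at the
  window minimum, making it shift-invariant.
- **Habitats.** K-means (k-means++ with 10 restarts, tol 1e-6, fixed
  seed) with k = 3, per sample, on z-scored channels. By default only
  the four shift-equivariant *location* channels (mean, median, min,
  max) enter the clustering. This is deliberate: dispersion channels
  (variance, entropy, energy, CV) respond to plateau *interfaces*
  rather than tissue intensity class; including them makes K-means
  carve out spurious boundary habitats (measured ARI vs planted
  partition drops from 1.0 to ~0.25-0.5) and breaks shift invariance,
  since energy and CV are not shift-equivariant and z-scoring cannot
  repair that. `cluster_channels=None` restores all-channel clustering
  for sensitivity analysis. Cluster labels are renumbered by ascending
  mean local intensity, so the labeling is deterministic across seeds.

## Feature bank

93 features per region x transformation, plus 14 geometry-only shape
features per region:

- **Shape (14):** mesh volume and surface area from a marching-cubes
  surface of the padded mask, voxel volume, surface/volume ratio,
  sphericity, max 3D diameter and the three maximal in-plane 2D
  diameters, the three PCA axis lengths (4 sqrt eigenvalue of the
  physical-coordinate covariance), elongation, flatness. Single-voxel
  masks yield zeroed axis/diameter descriptors with a warning, never
  NaN.
- **First order (18):** energy, total energy, entropy, min, p10, p90,
  max, mean, median, IQR, range, MAD, robust MAD, RMS, skewness,
  kurtosis (uncorrected fourth standardized moment), variance,
  uniformity. Population moments; constant regions use the conventions
  skewness = kurtosis = 0, entropy = 0, uniformity = 1.
- **Texture (75):** GLCM (24), GLRLM (16), GLSZM (16), GLDM (14),
  NGTDM (5) over gray levels discretized at a fixed 25 HU bin width
  anchored at the region minimum. GLCM and GLRLM use the 13 unique 3D
  directions, symmetric co-occurrences, and average per-direction
  feature values (the merged-matrix alternative was rejected for
  simplicity). GLSZM zones and GLDM dependences use 26-connectivity;
  GLDM dependence size counts the center voxel, with alpha = 0. NGTDM
  excludes voxels with no in-ROI neighbor; coarseness is capped at 1e6.
  Degenerate single-level regions use: correlation = 1, MCC = 1,
  IMC1 = 0, NGTDM contrast/busyness/strength = 0.
- **Transforms:** original; Laplacian-of-Gaussian at 1 and 3 mm
  (kernel truncated at 8 sigma so constants map to numerical zero); the
  8 sub-bands of a single-level stationary 3D wavelet (coif1) — the
  undecimated transform keeps sub-bands aligned with the mask. Only LoG
  and wavelet are implemented; the larger transform set sometimes used
  in radiomics software is unspecified and out of scope, so no
  particular total feature count is a target.

Correctness is defined against literal-formula brute-force oracles
(voxel-pair enumeration, run walking, zone flood-fill), not against any
existing extraction tool; the test suite checks every feature at
tolerance 1e-9 on random 5^3 images.

## Feature selection

Fixed cascade on training samples only: (1) ICC(2,1) >= 0.85 between
features extracted under the original and a 1-voxel-perturbed
segmentation (erosion, or dilation when erosion would empty the mask);
(2) z-scoring (parameters stored for held-out reuse) and Welch t-test
at p < 0.05; (3) greedy Pearson de-correlation at |r| > 0.9 — the
worst pair loses its member with the larger mean |r|, ties broken by
name; (4) mRMR, difference form, mutual information on equal-frequency
tertiles, deterministic name-order tie-break, k = 30; (5) L1 logistic
regression with lambda on a 30-point log grid chosen by 5-fold
cross-validated deviance (`rule="min"` default; `"1se"` available and
sparser). Zero-variance features drop with a logged reason; a
zero-pooled-variance t-test is p = 1 by convention. Survivor sets are
nested by construction and the train/validation partition is frozen at
cohort-generation time, so perturbing validation labels cannot alter
the selection report.

The Pearson threshold, mRMR variant and k, and the mRMR-then-Lasso
order are package choices (config-exposed); the thresholds 0.85 (ICC)
and 0.05 (t-test) follow the published workflow.

## Models and nomogram

Per-region signatures (intratumoral, each shell, habitats-concatenated)
are classifiers scored by stratified 5-fold CV AUC over a small grid:
MLP, random forest, SVM, logistic regression, XGBoost, LightGBM,
Extra-Trees. The final model refits on the full training set; the
signature is `predict_proba` in [0, 1]. Picking the best algorithm by
*test*-set AUC — as some published workflows do — is a leakage-prone
selection rule; the pipeline's default assigns algorithms per region in
config and evaluates them on the held-out partition.

Clinical covariates get univariable logistic ORs (categoricals coded as
single integer-ordered columns, so each covariate reports one OR) and a
stepwise multivariable model (enter p < 0.05, remove p > 0.10);
separation falls back to an L2-penalized fit, flagged, without CIs.

The nomogram is a logistic fusion of signature scores (peritumoral
3 mm, habitat, and the pluggable DTL score column) plus smoking. The
point scale is an affine re-encoding: each predictor's observed
training minimum (maximum for negative coefficients) maps to 0 points
and the widest coefficient x range spans 100 points, so total points
convert back to the fitted probability exactly (round-trip tolerance
1e-9). The shipped DTL column is a logistic score on summary statistics
of the maximum-area axial slice — a stand-in that exercises the fusion
interface; any per-sample score column can replace it.

## Evaluation

AUC is the Mann-Whitney statistic (ties 1/2); its CI and the paired
test for correlated AUCs use DeLong's structural components. Accuracy,
sensitivity, specificity, PPV and NPV are reported at the
Youden-optimal threshold derived on training scores and frozen for
held-out partitions. Calibration uses deciles-of-risk bins and the
Hosmer-Lemeshow chi-square with df = g - 2; empty or tied bins merge
with a neighbor and the df adjusts. Note the df = g - 2 reference
presumes probabilities fitted on the evaluated data — against *true*
generating probabilities the test is anti-conservative (~11% at the 5%
level in our simulations), so the suite's calibration null fits a
logistic model first. Decision curves report
`NB(pt) = TP/n - (FP/n) pt/(1-pt)` on a 0.01-0.99 grid (step 0.01)
against treat-all and treat-none. The cosine learning-rate schedule
(task-specific and backbone-frozen variants) is provided as a utility
for reproducing transfer-learning training recipes.

## Pipeline

`simulate -> preprocess -> regions -> extract -> select -> train ->
evaluate`, with per-stage outputs, a manifest keyed by the config hash,
and stage-level resume (deleting one stage's outputs re-runs only that
stage). Every random operation traces to the single `seed` in the YAML
config. Defaults are sized for desk-scale runs: the full feature bank
on a 60-sample cohort with LoG transforms completes in minutes on one
CPU; the test suite uses smaller cohorts (20-24 samples, original
transform only) and the statistical recovery checks run at n = 300
samples x 20 repeats on the fast intratumoral first-order path.

## Known limitations

- Exact habitat recovery is guaranteed only for flat plateau
  interfaces and location-channel clustering; real tumors have neither,
  and the noiseless-recovery result should be read as a correctness
  check, not a claim about real habitats.
- The DTL signature is a statistical stand-in, not a trained network;
  nomogram results involving it exercise the fusion interface only.
- The t-test filter assumes approximately continuous features; heavily
  discrete features (e.g., zone counts on tiny regions) can violate its
  nominal level.
- Stepwise selection and best-by-AUC model choice are implemented
  because the workflow they reproduce uses them, with their known
  inferential caveats.
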