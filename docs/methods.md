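# Methods

## Problem and labels

A levodopa challenge test (LCT) record carries MDS-UPDRS III motor scores
off and on medication. The improvement rate is (OFF − ON)/OFF × 100 %; the
binary outcome is *good* iff the rate is ≥ 30 % (the boundary is inclusive,
following the usual responder convention). The rate is undefined for
OFF ≤ 0 and is guarded accordingly. Inclusion rules keep records with a
known LEDD, a unique (subject, visit) pair, OFF ≥ 5 and LEDD ≤ 5000 mg/day;
the inequalities are strict as stated (OFF < 5 and LEDD > 5000 excluded),
so boundary values are kept, and each exclusion carries a machine-readable
reason code with first-failing-rule precedence (missing LEDD, duplicate
visit, low OFF, high LEDD).

Because subjects contribute several visits, splits are grouped: subjects
are shuffled by the seed and assigned whole to the training set until the
training record count reaches the 0.8 target fraction. The realized train
fraction therefore overshoots by at most one subject's records; with three
records per subject and 219 records the split lands at 176–178 / 43–41.

## Synthetic cohorts

The generator produces the statistical skeleton of such a cohort, not
anatomy:

- **Atlas**: ROIs are disjoint axis-aligned boxes (≥ 27 voxels, one-voxel
  separation) carved from an 8-voxel cell grid; 16 ROIs default, named after
  the subcortical set (l/r caudate, putamen, thalamus, GPi, GPe, STN, SN,
  RN) when 16 are requested.
- **Volumes** (default 48×56×48 at 3 mm — desk scale in place of
  193×229×193 at 1 mm, preserving a ≥ 3× downsampling path for the deep
  extractor): a smooth baseline field (Gaussian-filtered noise, sd 5 around
  a mean of 100) shared across the cohort, a global age trend
  `age_slope × (age − 60)`, i.i.d. voxel noise of sd 10, and — for good
  responders only — an intensity shift `d × 10` and a noise-variance ratio
  `texture_effect` inside the designated signal ROIs. Effect sizes are thus
  in units of the voxel noise.
- **Clinical covariates** match a real training cohort's marginals: age
  64.12 ± 9.22 y (normal), disease duration 41.88 ± 21.61 months and LEDD
  645.40 ± 426.97 mg/day (moment-matched lognormals, so the configured mean
  and sd hold exactly on positive support), OFF 27.51 ± 12.38 truncated at
  5 by rejection (the truncation raises the realized mean by ≈ 1 point),
  sex M with probability 116/173 independent of class. A configurable
  `clinical_link` (default 0.5 sd) separates the classes antisymmetrically
  (good: −link/2 on duration and LEDD, +link/2 on OFF; bad the reverse), so
  clinical-only models beat chance (~AUC 0.68) while the marginal means stay
  at their configured values.
- **Responses**: the class is Bernoulli(good_fraction); the improvement
  rate is drawn Uniform(35, 70) for good and Uniform(−10, 25) for bad, and
  ON = OFF × (1 − rate/100), so the label is always recomputable from the
  stored scores and never straddles the 30 % threshold.
- **Healthy controls** (age-correction calibration set) share the baseline
  and age trend, carry no class effect, and have ages Uniform(45, 80).

All randomness flows from one master seed through named substreams (one per
record), so extending a cohort never changes earlier records. What passing
tests on this generator show is that the *pipeline machinery* recovers
planted effects without leaking test data; they cannot show robustness to
registration error, scanner effects, anatomy-correlated covariance, or any
other structure the generator does not emulate.

## Imaging feature branches

**Gray-matter intensity.** Volumes are treated as aligned modulated
gray-matter maps (segmentation/registration are upstream and out of scope).
Gaussian smoothing uses σ = FWHM/(voxel × 2√(2 ln 2)) per axis with reflect
padding (preserves the mean; FWHM 8 mm default). The age model is a
per-voxel OLS of intensity on age over healthy controls; correction
subtracts slope × (age − reference age). The discriminative mask is a
voxelwise two-sided Welch t-test between responder classes at α = 0.001,
uncorrected, fitted on training data only (the originating method's exact
rule is in an external supplement; α is exposed). PCA retains the first 50
components, centered on the training mean, no whitening, sign fixed by
making each component's largest-magnitude loading positive.

**Subcortical texture.** Per-ROI fixed-bin-count quantization (32
equal-width bins over the ROI range — affine-invariant), then a 19-feature
first-order set plus GLDM (α = 0 level tolerance, 26-connectivity) and
GLSZM (26-connectivity) families; entropy-type features use log₂.
LDHGLE = Σ P(i,j)·i²·j²/N_z and LAHGLE = Σ P(i,s)·i²·s²/N_z are the
named emphases of interest. Correlation pruning is greedy: while any pair
exceeds |r| > 0.9, the strongest pair's member with the larger mean
absolute correlation is dropped (later column on ties), computed on
training rows. The original 86-features-per-ROI inventory is not public;
the inventory here (46 per ROI) is configurable and the count is logged,
not asserted.

**Morphological network.** ROI intensity histograms over 64 bins shared
across ROIs of one volume (whole-volume range), ε = 1e-10 smoothing for
strictly positive support. Divergences in nats; edge weight
w = exp(−JS) ∈ (0.5, 1] since JS ≤ ln 2 — a bounded similarity, chosen
because the cited construction leaves the transform open. Graphs are fully
connected by default (no thresholding; a proportional threshold could be
added upstream of the metrics). Features are the Onnela weighted clustering
coefficient (weights normalized by the network maximum; degree < 2 ⇒ 0) and
strength/(K−1) degree centrality, 2K features with stable names.

**Deep extractor.** A 3D residual network in the medical-segmentation
encoder configuration: 7³ stem stride 2 → 3³ max-pool stride 2 → four
basic-block stages at 64/128/256/512 channels with strides 1/2/1/1 and
dilations 1/1/2/4 — overall output stride 8. Block depth (10 default, 18,
34) does not affect the output size. The head is max-pool(kernel 8,
stride 8, padding 0) + flatten: for 193×229×193 the last conv map is
25×29×25 and the output is 512×3³ = 13,824 features, names `ResNet_<i>`
with the channel-major row-major flatten bijection documented in
`feature_to_coords`. The net is written in numpy: convolutions are chunked
im2col + float32 BLAS matmuls (peak buffer ≈ 120 MB), batch-norm is an
affine per-channel map, weights are He-initialized from a seed or loaded
from an `.npz` bundle validated against the architecture. Inputs are
z-scored per volume before the forward pass. Inference-only; repeated
extraction is bit-identical. A `tiny-cnn` profile (three 3³ conv stages,
16/32/16 channels, output stride 4, head pool 2 — an explicit override of
the default pool) serves 48×56×48 volumes, yielding 4,032 features.

## Selection cascade

mRMR uses the MID criterion on plug-in mutual information (nats) with
equal-frequency 5-bin discretization of continuous columns (low-cardinality
columns are used as-is); ties break by column order; top 50 kept. LASSO is
an L1-penalized linear fit on the 0/1 labels over internally standardized
features; α\* minimizes seeded stratified 5-fold CV mean squared error over
30 log-spaced values in [1e-4, 10]; survivors have |coef| > 1e-10 at the
full-data refit. RFE drops one feature per refit of an L2 logistic
regression (C = 1), smallest |coefficient| first (later column on ties);
the kept count maximizes seeded 5-fold CV AUC over candidates
1..min(30, p), smaller count on ties; importances are the signed final
coefficients. The cascade is nested by construction (RFE ⊆ LASSO ⊆ mRMR).
Repeats (default 10, as in the full-scale analysis) revary only the CV fold
seeds; the final set is the across-repeat intersection, with a flagged
majority-vote (≥ half) fallback for empty intersections. Desk-scale
experiments in the test suite use 1–3 repeats; at these problem sizes the
repeats rarely disagree, so the intersection is insensitive to the count.

## Modeling and statistics

Min–max scaling is fitted on training rows; constant columns map to 0 and
test values are not clipped. Classifiers: RBF-SVM (C ∈ {0.1, 1, 10},
γ ∈ {scale, 0.01, 0.1}), XGBoost (depth {2, 3}, learning rate {0.1, 0.3},
50/100 trees), MLP (one or two hidden layers, L2 {1e-4, 1e-2}); each tuned
by seeded stratified 5-fold CV on ROC AUC and refit on the full training
set. Scores come from the decision function when available, otherwise the
positive-class probability. AUC is micro-averaged over the one-vs-rest
score columns; a binary task binarizes to a single positive column, so the
micro average equals the standard AUC (asserted at runtime). The
clinical-vs-union comparison is a paired one-tailed t-test over the seed
ensemble: d = union − clinical, t = mean(d)/(sd(d)/√n), df = n−1; when
sd(d) = 0 (possible at desk scale with deterministic models) p is 0, 1, or
0.5 for positive, negative, or zero mean difference. Seeds drive fold
assignment and stochastic model initialization; in the repeated-experiment
helper each run seed also regenerates the cohort and the grouped split, so
the ensemble reflects full-run variability.

Validation mode is contractual: a `FrozenPipeline` bundles every fitted
artifact (age model, mask, PCA basis, pruning list, selection, scalers,
classifiers) and its `predict` performs zero fitting — enforced in tests by
hashing all fitted state before and after scoring an external cohort.

## Saliency

Selected deep features are mapped through the flatten bijection to their
(channel, x, y, z) pooled-map positions and seeded with a gradient;
excluded positions get −0.001 exactly. The seed backpropagates through
flatten (reshape) and the max pool (routed to each cell's argmax — the
exact adjoint, verified against finite differences away from block-max
ties). Channel weights are the spatial means of this gradient; the map is
ReLU(Σ_c w_c A_c) at last-conv resolution, trilinearly upsampled to the
volume grid, max-normalized to [0, 1] (so the 0.4 threshold is
well-defined), and decomposed into 26-connected clusters with per-ROI
overlap |cluster ∩ ROI|/|ROI|; the dominant cluster is the largest.

Two seeding modes exist: the default assigns each selected feature its
signed RFE importance; the alternative assigns +1.0. With a *pretrained*
backbone the signed mode is the natural reading of "importance as
gradient". With the seeded random weights used throughout the tests,
however, coefficient signs reflect arbitrary kernel-sum signs, and
negative seeds cancel exactly the channels that carry the planted signal —
empirically destroying localization. The end-to-end attribution check
therefore uses the +1.0 mode, which localizes the dominant cluster to a
planted ROI in most seeds; both modes remain available via
`seed_gradients(..., use_importances=...)`. Cohort-level maps average the
per-subject normalized maps of good responders and renormalize.

## Problem sizes and numerical choices

- Test and acceptance cohorts: 219 records (73 × 3) at 48×56×48, 60–100
  healthy controls; leakage/freezing checks use 50 records at 32×40×32.
- Planted-recovery conditions: feature-level d = 1.5, 5 informative of 500,
  n = 200; imaging-level d = 1.5 (one ROI) for the ablation, d = 2.5 (two
  ROIs) for attribution, where the random-weight tiny backbone dilutes
  voxel-level contrast at the feature level.
- The full-size 193×229×193 forward pass runs in a few minutes and ≈ 1.2 GB
  on one CPU.
- Degenerate inputs: constant ROIs quantize to level 1 and produce zero
  variance-type features; constant feature columns have MI 0 and min–max
  image 0; single-feature RFE returns the feature unchanged; empty
  selections fall back to the unselected feature matrix in the experiment
  driver.
- Determinism: every stochastic step (generator, splits, CV folds, model
  seeds, weight init) is seeded; PCA signs and tie-breaks are fixed as
  described, so reruns are bit-identical.

## Known limitations

Synthetic anatomy is boxes on a smooth field; registration, segmentation
and scanner harmonization are out of scope (volumes are assumed aligned).
The texture inventory approximates, not reproduces, the original
86-feature set. The deep backbone's depth and input normalization follow
common practice since the original configuration is underspecified;
pretrained weights are a plug-in, not shipped. Saliency conclusions at
random initialization validate the attribution plumbing, not anatomical
claims.
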