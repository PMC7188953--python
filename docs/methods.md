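# Methods

This note documents the models, estimators and numerical choices behind
`radiotexnet`, what the synthetic phantom cohort does and does not emulate,
and the known limitations.

## Synthetic tumor phantoms

Each subject is an ellipsoidal ROI (default semi-axes 6×5×5 voxels on an
18³ grid, voxel spacing 0.76×0.76×1 mm carried but unused) of textured
"tissue" on an air-like background fixed at −1000 HU. The within-mask field
is white Gaussian noise convolved with an isotropic Gaussian kernel of
width `corr_len` voxels and then affinely rescaled so the mask voxels have
*exactly* the class's target mean and SD in HU. This is the simplest
controllable texture model: `corr_len` sets the spatial coherence the
texture matrices respond to, `sd_hu` the histogram spread, `mean_hu` the
radiodensity offset.

Class-conditional defaults: the positive ("small-cell-like") class uses
mean 45 HU, SD 140 HU, corr_len 2.5; the negative ("adenocarcinoma-like")
class mean 25 HU, SD 90 HU, corr_len 1.0. Clinical covariates are drawn per
class — smoking Bernoulli(0.9714 vs 0.2647), male Bernoulli(0.6857 vs
0.3529), age Normal(66.91, 9.75) vs Normal(58.55, 11.94), race categorical
(0.20/0.743/0.057 vs 0.4706/0.4412/0.0882 over Asian/Caucasian/Other) —
matching typical published two-class lung-cancer cohort demographics, so
smoking is strongly class-associated while race is metadata only. The
texture effect sizes are free parameters of the phantom, chosen to give a
clearly separable cohort at the default settings; nothing in real CT
pins them down, so cohort-level accuracy on phantoms says nothing
quantitative about patient data.

Not emulated: lung anatomy, vasculature, partial-volume and respiratory
artifacts, scanner reconstruction kernels, segmentation variability. A
passing end-to-end test therefore demonstrates the *pipeline's*
correctness and sensitivity to controlled texture differences, not
clinical performance.

## Lloyd-Max quantization

For each (volume version, Ng) the within-mask intensities are quantized by
the Lloyd-Max algorithm: equal-quantile initialization (deterministic, no
random restarts), then iterated nearest-centroid assignment (boundaries are
centroid midpoints; a value exactly on a boundary goes to the *higher*
level) and conditional-mean centroid updates. Convergence when the largest
centroid movement is below `tol` (default 1e-6 × within-mask range) or
after 200 iterations. Any level left empty is re-seeded deterministically
by splitting the most populous splittable level at the median of its
distinct values, which cannot increase the MSE; the per-iteration MSE trace
is recorded and is non-increasing. If the ROI has fewer distinct values
than Ng, the quantizer degrades to one level per distinct value (MSE 0)
and the boundary/centroid arrays shrink to the occupied length so the
strictly-increasing-boundaries invariant still holds.

Each of the 9 volume versions is quantized independently at each Ng —
subband reconstructions have their own dynamic range, so reusing raw-volume
boundaries would waste levels.

## Wavelet subbands

A single-level separable 3D DWT (PyWavelets, symmetric half-sample
extension) with the orthogonal Daubechies-1 kernel by default (configurable,
e.g. `coif1`); the kernel name is recorded in every feature-table manifest.
Subband labels give the filter applied along (x, y, z); reconstruction of a
single subband inverts the transform with the other 7 zeroed and trims to
the original shape (odd dimensions grow by one sample under the extension
convention). Linearity guarantees the 8 reconstructions sum back to the
original volume, which the tests assert to 1e-6 relative; with the
orthogonal default kernel the coefficient energy also matches the voxel
energy (Parseval) to 1e-8 relative.

## Feature definitions

All features use only within-mask voxels; out-of-mask voxels break runs,
are excluded from co-occurrence pairs and neighborhood means, and never
contribute to statistics. The feature vector is cropped to the tight mask
bounding box before the wavelet transform, making every feature invariant
to any prior padding or cropping of the volume.

* **Global (8)** — max, min, range, mean, variance, skewness, kurtosis of
  the raw within-mask intensities (population moments; kurtosis
  non-excess, Gaussian → 3; a zero-variance ROI emits 0 for
  skewness/kurtosis instead of NaN), plus the Shannon entropy (bits) of the
  quantized-level occupancy. All eight are emitted once per (version, Ng)
  block even though only the entropy depends on Ng — this keeps the
  48-per-block bookkeeping uniform.
* **GLCM (9)** — a single symmetric Ng×Ng matrix accumulated over the 13
  unique distance-1 3D offsets and normalized to sum 1; energy, contrast,
  entropy, homogeneity, correlation (0 when degenerate), sum average,
  variance, dissimilarity, autocorrelation.
* **GLRLM (13)** — maximal same-level runs merged over the 13 directions;
  SRE, LRE, GLN, RLN, RP (= runs / (13 × voxels)), LGRE, HGRE, SRLGE,
  SRHGE, LRLGE, LRHGE, GLV, RLV. Conservation: Σ r(i,j)·j = 13 × voxels.
* **GLSZM (13)** — 26-connected equal-level zones; the analogous 13
  features with ZP = zones / voxels. Conservation: Σ z(g,s)·s = voxels.
* **NGTDM (5)** — per-level occupancy nᵢ and accumulated deviation
  sᵢ = Σ|i − mean of within-mask 26-neighborhood| over voxels with at
  least one neighbor; coarseness (capped at 1/ε, ε = 10⁻¹²), contrast,
  busyness, complexity, strength, all with ε-guarded denominators so a
  constant or single-voxel ROI yields defined values.

Merging directions into one matrix (rather than averaging per-direction
features) makes GLCM/GLRLM exactly invariant under 90° rotations, as are
the other families by construction. A literal brute-force oracle
(explicit pair loops, run walking, flood fill, neighborhood scans) is kept
in `radiotexnet.oracle`, written independently of the vectorized engine;
tests require agreement to 1e-10 on random tiny volumes.

Feature names follow the grammar `family.feature @ rawNg=<n>` /
`family.feature @ WT(<subband>) Ng=<n>` / `<name> @ Clinic`, ordered by
volume version (raw, LLL…HHH), then Ng, then family, then feature.

## Feature selection

Columns are normalized by their maximum absolute entry (all-zero columns
are left as zeros and flagged). Relevance is the Pearson correlation with
the 0/1 target (constant columns map to 0, not NaN). Collinear pairs with
|corr| > 0.85 are pruned greedily in descending-|corr| order, dropping the
member with lower |relevance| (ties drop the later column); the log of
removals is part of the selection report.

Mutual information uses the plug-in estimator in bits on equal-frequency
discretized columns (default 4 bins; the binary target is used as-is).
Discretization is rank-based with stable index tie-breaking; a column with
fewer distinct values than bins gets one label per distinct value, so a
constant column collapses to a single label. The plug-in estimator is
positively biased at small n (~(bins−1)(levels−1)/(2n ln 2)); with the
4-bin default and cohort-scale n this bias is shared across features and
does not affect the ranking materially.

mRMR runs as *backward deselection*: repeatedly remove the feature whose
removal maximizes the remaining set's difference criterion
φ(S) = mean_{f∈S} I(f;y) − w · mean_{f<g∈S} I(f;g) (w = 1 by default),
until k = 20 remain. Exact ties remove the later column, making the whole
stage bit-deterministic. With w = 0 this reduces to top-k by MI relevance.
A forward variant (`scheme="forward"`) is available for comparison. The
final list is *reported* in descending |Pearson relevance| order. Clinical
columns compete identically to image features; `include_clinical=False`
reproduces the image-only variant.

## Network and training

The classifier is a fully connected tanh network, default
20→10→7→5→2 (339 parameters), weights and biases initialized uniformly in
[−0.5, 0.5] from a seeded generator. Targets are ±1 one-hot: positive
(+1, −1), negative (−1, +1). The output activation is also tanh — the
decision thresholds raw node values, no softmax. The ROC score is
f = out₊ − out₋, which equals the single-node thresholding at 0 but gives
a proper ranking score; f = 0 exactly maps to the negative class.

Levenberg-Marquardt training: per epoch the full residual Jacobian is
assembled by backpropagation (verified against central finite differences
to 1e-6) and (JᵀJ + μI)Δ = −Jᵀe is solved; a step is accepted only if the
training MSE decreases (μ ← μ/10), otherwise μ ← μ×10 until acceptance or
μ > 10¹⁰ (abort with `mu_overflow`). Defaults μ₀ = 10⁻³, factor 10 — the
customary damping schedule. Stopping: training MSE < 10⁻³ (the "control
error"), 1000 epochs, μ overflow, or 6 consecutive validation-MSE
increases; the returned parameters are those with the best validation MSE
seen (including the pre-training state). Accepted-step MSE is strictly
decreasing by construction and asserted in tests.

## Evaluation

Each trial partitions the cohort 70/15/15 into train/validation/test with
largest-remainder rounding, stratified by class by default (an
unstratified 10-subject test set can lose a class entirely, leaving the
per-trial ROC undefined); the per-trial split seed is base_seed + trial and
the network seed base_seed + 10000 + trial, so a fixed base seed makes the
entire 30-trial summary byte-reproducible. Per-trial ROC uses a threshold
sweep with trapezoid AUC (equal to the rank-sum concordance statistic with
ties counted ½, asserted in tests). The averaged curve is vertical
averaging on a 0.01 FPR grid with step interpolation. The summary reports
the mean trial AUC, a 95% *percentile* interval over the 30 trial AUCs
(the construction of choice when nothing is known about the AUC sampling
distribution), and sensitivity/specificity at the grid point maximizing
Youden's J = TPR − FPR — the upper-left reading of the averaged curve. The
pooled confusion matrix aggregates the f > 0 decisions over all trials.

**Selection leakage.** By default feature selection runs once on the full
table before the trials, mirroring the classical select-then-split
workflow. This leaks test information into selection: on a label-permuted
40-subject cohort with 1731 features the leaky workflow yields a mean
"null" AUC of ~0.63–0.70 rather than 0.5 — the well-known selection-bias
effect. `selection_inside_trial=True` re-runs pruning + mRMR on each
trial's training subset only and restores the null to ~0.46–0.5; the
package's null-hypothesis acceptance check uses this leak-free mode, while
the strong-signal check keeps the default workflow. Both modes are exposed
so the leakage can be quantified on any cohort.

## Problem sizes used in the checks

The automated checks run on synthetic phantoms at deliberately modest
scale, chosen as the smallest sizes at which each property is cleanly
resolvable: feature bookkeeping on one 32³ subject; oracle equivalence on
50 random ≤5³ volumes with Ng ≤ 4; the cohort evaluation on 40 subjects
(20 per class, 18³ grids) with 30 trials; reproducibility on a 12-subject
cohort at Ng ∈ {16, 32}.

## Known limitations

* The wavelet kernel of the original texture-radiomics formulation is a
  free choice here (Daubechies-1 default); feature values are
  kernel-dependent, so cross-study numeric comparisons require fixing it.
* Global features other than entropy are duplicated across Ng blocks by
  design; the correlation pruning removes the copies immediately.
* The LM trainer forms the full JᵀJ; fine for a few hundred parameters,
  unsuitable for much larger networks.
* The plug-in MI estimator with 4 equal-frequency bins is a coarse
  dependence measure; it is used for ranking, not for calibrated
  information estimates.
* Phantom cohorts have exactly controlled class differences; absolute
  AUCs on them are not predictive of performance on patient CTs.
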