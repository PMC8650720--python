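# Methods

`nigrastab` studies one question: how much does a Parkinson's-disease
classifier that is conditioned on a substantia-nigra (SN) segmentation
depend on the exact contour it is given, and which architectural choices
remove that dependence?  Because clinical QSM cohorts are not freely
redistributable, every analysis runs on synthetic phantom cohorts whose
generator is itself part of the tested code.

## Phantom cohorts

Each subject is a 3D susceptibility-like volume (parts per billion, ppb)
containing a mirrored bilateral pair of bright ellipsoidal nuclei over a
dimmer background, plus the exact analytic voxelization of the nuclei as
the reference label.  The construction is:

1. **Geometry.** Two axis-aligned ellipsoids mirrored about the
   mid-sagittal plane, semi-axes drawn per axis from
   `nucleus_radius_range` (default 2.5–4.2 mm at the full default grid;
   2.4–2.9 mm at the experiment scale) with ±10 % jitter.  A voxel is
   foreground iff its center satisfies an ellipsoid inequality (ties
   foreground).  Every nucleus must keep a 3-voxel background margin.
2. **Intensities.** Interior voxels: class mean (`pd_mean = 120`,
   `hc_mean = 90` ppb) plus a per-subject offset
   (`between_subject_sd = 13` ppb) plus spatially correlated texture
   noise whose amplitude (`pd_sd = 28` vs `hc_sd = 15` ppb) and
   correlation length (1.5 mm) both carry per-subject lognormal jitter
   (35 % and 30 %).  Background: 40 ± 12 ppb correlated noise.  A
   one-voxel interior shell is brightened by `rim_contrast = 30` ppb.
   Optional Gaussian partial-volume smoothing (`pv_smoothing`, default
   off) softens the boundary step.
3. **Determinism.** All draws derive from one `numpy` seed; a cohort
   derives per-subject seeds from a master `SeedSequence`.

The defaults were chosen so that the cohort sits in the operating regime
the stability question is about: elevated and more heterogeneous
intensity in the disease class (iron deposition), a sharp rim at the
nucleus boundary (the edge contrast that drives masked-input
instability), class overlap large enough that a screened
radiomics-plus-logistic-regression baseline lands near 0.85–0.90
accuracy rather than at ceiling, and enough between-subject texture
variability that intensity summary features retain label sensitivity
after robustness screening.  What the phantoms deliberately do *not*
model: anatomy of neighboring nuclei, nigrosome substructure, age/sex
covariates, scanner or reconstruction physics.  Results on phantoms
therefore demonstrate mechanisms (how label error propagates through
each pipeline), not clinical effect sizes.

## Dice-graded label families

Perturbed label sets at prescribed Dice levels
(0.975, 0.946, 0.920, 0.897, 0.872 by default) are produced by warping
each reference mask through a smooth random displacement field
(Gaussian-smoothed white noise, `smoothness_sigma = 3` mm, peak
magnitude normalized to 1 mm) whose scalar magnitude α is solved by
bisection so the achieved Dice hits the target within ±0.005.  All
levels of one subject share a single field with increasing α, so the
family is a nested, gradual deviation — the same two properties
(smoothness, gradual deviation) a registration-derived deformation
between a manual and an automatic label would have.  Masks are warped by
trilinear interpolation of the {0,1} image and thresholded at 0.5
(boundary value 0 outside the grid).  If Dice(α) is non-monotone at
bisection resolution (fields can fold at large α), a dense 200-point
grid search takes over.  Because the field is normalized by its *global*
peak, the local magnitude near the nuclei can be much smaller; the
default search ceiling is therefore `alpha_max = 15` mm at the
experiment scale.

## Statistics

* **Dice**: `2|A∩B|/(|A|+|B|)`; two empty masks give 1.
* **Signed distance**: anisotropic Euclidean distance transform between
  voxel centers, negative inside the mask.
* **ICC(2,1)**: two-way random effects, absolute agreement, single
  rater, from the ANOVA decomposition
  `(MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n)`.  Constant matrices return a
  −∞ sentinel so degenerate features fail any `> 0.8` screen instead of
  raising.
* **CCI** (classification consistency index): fraction of pooled test
  subjects whose predicted diagnosis agrees between two label sources.
* **Classification panel**: accuracy, rank-based AUC (ties ½),
  sensitivity (PD recall), specificity (HC recall), balanced accuracy.
* **Paired tests**: matched-samples t-test on per-split metrics with
  Bonferroni correction (the correction method is configurable; the
  most conservative standard choice is the default).

## Radiomics + logistic regression arm

Features are computed from the masked volume: 17 first-order statistics,
6 shape descriptors, and 8 gray-level co-occurrence (GLCM) statistics at
1-voxel offsets averaged over the 13 unique 3D directions after 16-bin
discretization over the in-mask range (~31 features; a full production
radiomics configuration can be plugged in — anything mapping
`(volume, mask) → pandas.Series`).  Feature robustness is screened with
ICC(2,1) between the reference and *every* perturbed label family, a
feature surviving only if ICC > 0.8 for all pairings (the conservative
reading; a single-pairing screen is a one-line change).  The classifier
is an L2 logistic regression with balanced class weights (the cohort is
disease-majority; balancing keeps the decision threshold calibrated) and
recursive feature elimination: drop the smallest standardized |weight|
per iteration, lexicographically greatest name on ties, until
`n_final = 10` remain.

## Convolutional arms

The extractor is a stack of stride-1, same-padding 3D convolutions whose
first layer is fixed at 6 channels / 5×5×5; the classifier head is a
small two-layer perceptron over pooled channel features with a
batch-normalization stage on the pooled vector (pooled gated features
are orders of magnitude below unit scale, which otherwise stalls early
training).  Both conditioning modes share this skeleton:

* **masked**: input = ROI × binary label, pooled by global average
  pooling (GAP).  The label enters the *input*, so its edges become
  sharp image structure.
* **gated**: input = the un-zeroed ROI; the label enters only as a
  spatial gate at pooling.  Two normalizations are implemented: the
  in-gate weighted average `Σ(g·f)/Σg` and the global mean `mean(g·f)`
  over all ROI voxels.  Perturbations strictly outside the gate support
  provably cannot change the pooled vector under either.

ROIs are fixed-shape windows centered on the (rounded) label centroid
with a dilated-bounding-box fallback; the centroid moves far less than a
bounding box under boundary noise.  Inputs are scaled by a fixed 100-ppb
constant — QSM is an absolute quantitative scale, and a per-ROI z-score
would cancel exactly the iron-load contrast that carries the diagnosis.
Training uses Adam (lr 1e-2, weight decay 1e-3 on weight matrices),
cross-entropy, random axis flips and ±1-voxel translations (neither
left/right polarity nor exact ROI placement is diagnostic), and keeps
the epoch with the best validation accuracy.

The layer engine itself (conv3d via im2col, batch norm, manual backprop,
Adam) is in `nigrastab.nn`, written for the small stride-1 models used
here; every backward pass is verified against finite differences in the
test suite.

## SN2 segmentation network and the joint model

SN2 is a coarse-to-fine segmenter with no spatial downsampling anywhere
(the nucleus is tiny; pooling hurts contour precision) and densely
connected blocks instead of residual ones.  Two parallel trunks produce
an initial SN probability map and a signed-distance regression (targets
clipped to ±10 mm, scaled to [−1, 1]); their outputs are concatenated
channel-wise, fused by a 3×3×3 convolution stage, and a softmax yields
the fine segmentation.  Loss: soft Dice + voxelwise cross-entropy on the
fine map plus an L1 term on the distance head (weights 1.0 / 0.5).

The joint diagnosis model feeds the fine probability map p through the
piecewise-linear gate δ(p) — 0 for p ≤ 0.4, 5p − 2 on (0.4, 0.6], 1
above — and pools the classifier extractor's feature maps through that
gate; the head then scores the subject.  No label is consumed at
inference.  Both pooling normalizations are available for the δ gate;
the experiments default to the in-gate weighted average for two
reasons: it is the normalization every binary-gated arm of the
comparison uses, so the four-way comparison differs only in where the
gate comes from, and the global-mean reading couples the pooled
features to the predicted-support volume, which measurably destabilizes
the classifier at this cohort size.  A gate that is identically zero
yields the head's output on the zero feature vector (flagged).  End-to-end training combines the segmentation
losses with the classification cross-entropy (weight 1.0); gradients
flow through δ (piecewise-linear, differentiable a.e.).  Training
warm-starts the SN2 trunks from a segmentation-only model and the
classifier from the fold's gated classifier, then fine-tunes everything
jointly; batch-norm running statistics are recalibrated after the
transplant because the δ-gated global-mean pooling has a different
feature scale than binary weighted-average pooling.  An
end-to-end-from-scratch switch exists (`warmup_epochs`).

## Experiments and desk scale

All experiments run under stratified nested cross-validation (outer test
folds, inner validation used only for epoch selection), repeated over
permutations, every seed derived from one master seed:

1. **Population stability**: train on reference labels, evaluate the
   panel once per Dice level.  The radiomics-LR curve is averaged over
   three independent perturbation-field realizations, since the trend
   concerns the expectation over boundary-error draws rather than one
   draw.
2. **Consistency**: pool test predictions over permutations × folds and
   compute pairwise CCI over label sources for the masked and gated
   models.
3. **Joint comparison**: four configurations on identical splits —
   gated trained/tested on reference labels; the same models tested on
   automatic labels; gated trained and tested on automatic labels; and
   the joint end-to-end model with no test-time labels — with paired
   t-tests against the reference-train/automatic-test arm.

The automatic label source is a pair of SN2 models trained on
complementary stratified halves of the cohort, each labeling only the
half it never saw, so every automatic label has genuine held-out
quality (a deployed segmenter never trains on the case it labels).
Each training stops early once held-out Dice reaches ≈ 0.87: phantom
nuclei are far easier to segment than midbrain anatomy, and an
unconstrained segmenter would be nearly perfect, which would make
"automatic labels" indistinguishable from reference ones.  Sharing two
segmenters across splits (rather than training one per split) is a
desk-scale simplification; it exposes only label geometry, never
diagnoses, to the classifier experiments.

Default desk scale: 50 subjects (31 PD / 19 HC, preserving the ~62 %
disease prevalence of the motivating cohort design of 87 + 53), 24×24×16
voxel grids at 1 mm, 18×18×10 ROIs, a two-conv extractor
(6@5³ → 8@3³), 7 folds × 1 permutation, 20 training epochs (12 for the
joint fine-tune, 16 for SN2).  The study-shaped numbers (140 subjects,
100/20/20 splits, 50 permutations) remain configuration values.

## Numerical and degenerate-input choices

* Dice of two empty masks is 1; empty vs non-empty is 0.
* A constant rating matrix has no ICC; the sentinel fails screens.
* GLCM features of a single-gray-level region are defined as 0 (energy
  1) with a logged note.
* A δ-gate that is identically zero yields the head's output on the
  zero feature vector, flagged in the log.
* An SN2 prediction with empty foreground falls back to the reference
  mask when exporting automatic labels (logged; does not occur at the
  default settings).
* RFE ties break lexicographically; bisection tolerance 0.005 Dice.

## Known limitations

* Phantom separability and fragility are design choices; absolute
  accuracies do not transfer to clinical data.
* At this cohort size the masked and gated CNNs are small
  (two convolution layers); representational claims about deep
  extractors are out of reach.
* The CCI matrices at desk scale pool ~50–100 test predictions per pair,
  so individual entries carry sampling noise of a few percent.
* Batch normalization makes training-order effects possible; runs are
  deterministic for a fixed seed but not across BLAS implementations.
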