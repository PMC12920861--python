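# Methods

## Problem and model

Vocal-fold (VF) motility is assessed in videoendoscopy through the
anterior glottic angle (AGA): the angle at the anterior commissure (A)
between the free borders of the left and right vocal folds, whose
posterior endpoints are the keypoints LV and RV. Given the three
keypoints, with `(x1, y1) = LV − A` and `(x2, y2) = RV − A`,

    AGA = |atan2(x1·y2 − y1·x2, x1·x2 + y1·y2)|

reported in degrees in [0, 180]. The atan2 form is signed; the clinical
quantity is a magnitude, so the absolute value is taken. Coordinates are
0-based pixel centers, x rightward, y downward (image convention).

The estimator is a three-channel Gaussian **heatmap regression** network.
Ground truth for a keypoint at `(xc, yc)` is the unnormalized Gaussian

    f(x, y) = exp(−((x − xc)² + (y − yc)²) / (2σ²)),  σ = 20 px at 224×224,

one channel per keypoint in fixed order (LV, RV, A), peak exactly 1,
neither truncated nor renormalized. Prediction reads the per-channel
argmax (row-major first occurrence on ties; no sub-pixel refinement).
Training minimizes the weighted MSE

    L = Σ_c w_c · (1/N) Σ_j (pred_jc − true_jc)²,   w = (1.2, 1.2, 1.0),

where N counts pixels (and batch samples) per channel. The LV/RV
up-weighting emphasizes the fold free borders. Two baselines are
implemented for comparison: **direct coordinate regression** (same
encoder, two separable convolutions, global average pooling, a linear
head with 6 sigmoid outputs = normalized x, y per keypoint; coordinate
MSE loss) and **glottal segmentation** (same encoder–decoder with a
1-channel sigmoid output trained with soft Dice loss on the triangle
rasterized from LV, A, RV; keypoints are recovered from the predicted
mask via the minimum enclosing triangle).

## Architecture

The encoder is a standard MobileNetV2: a stride-2 stem with 32 filters,
17 inverted residual blocks (expansion 1 or 6, 3×3 depthwise, linear
1×1 projection; channel schedule 16-24-32-64-96-160-320), and a final
1×1 projection to 576 channels at output stride 32. The decoder has four
blocks, each nearest-neighbour ×2 upsampling, concatenation with the
stride-matched encoder feature (taps at the last layer of strides 2, 4,
8, 16 — channel widths 16, 24, 32, 96 at width 1.0), then two 3×3
conv+BN+ReLU layers (widths 256, 128, 64, 32). A final ×2 upsample and
three 3×3 convolutions (ReLU, ReLU, sigmoid) produce the output at input
resolution. A width multiplier (not part of the original design) scales
every channel count, rounded to multiples of 4 with a floor of 4, so
small variants can train on one CPU; width 1.0 reproduces the 32→576
progression. The encoder skip-tap placement and decoder widths were open
design points; any monotone-decreasing decoder would do, and the chosen
one keeps the parameter count in the expected MobileNetV2-U-Net range
(checked against a layer-by-layer arithmetic count in the tests).

Encoder weights are randomly initialized (He normal, seeded). ImageNet
pretraining — used in the original clinical study — is exposed only as an
explicit `encoder_weights` hook and is off by default; this is a known
fidelity gap of the re-implementation, relevant when training on small
real cohorts.

The layers themselves (`vfpose.nn`) are a minimal numpy toolkit —
im2col-based conv2d, depthwise conv, batch norm, ReLU/sigmoid, nearest
upsampling, Adam — with hand-written backward passes, verified against
central-difference gradients. It trades speed for zero compiled
dependencies and bit-reproducible CPU runs.

## Training protocol

Adam, initial learning rate 1e-3, batch size 8, at most 200 epochs,
early stopping when the validation loss has not improved for 10
consecutive epochs; the lowest-validation-loss weights are restored.
On-the-fly augmentation per training iteration, each transform firing
independently with probability 0.5: horizontal flip (which swaps the
LV/RV identities — anatomical left/right reverse under mirroring;
without the swap, flipped labels would be anatomically wrong), vertical
flip, rotation uniform in ±30° about the image center (resampled up to
5 times, then skipped, if a keypoint would leave the frame), brightness
shift in [−0.1, 0.1], hue shift in [−0.2, 0.2], saturation scale in
[0.5, 1.5]. Augmentation operates on the [0, 1] resized image; per-frame
per-channel mean removal happens at batch assembly so the intensity
transforms act on valid RGB.

Preprocessing resizes frames (nominally 640×480) anisotropically to the
square network input with bilinear interpolation, scaling keypoints with
the same per-axis factors; aspect ratio is not preserved, and all pixel
errors are reported in 224×224 space (errors measured at other input
sizes are rescaled by 224/size).

Cross-validation is 5-fold and patient-grouped: patients are shuffled
with a fixed seed and partitioned into near-equal test groups, so no
patient contributes frames to both a fold's test set and its train or
validation data. The validation set — needed by early stopping but of
unspecified construction in the source protocol — holds out 20% of each
fold's training patients (at least one), also patient-grouped and
seeded.

## Keypoint decoding from masks

The segmentation baseline yields keypoints through the minimum-area
enclosing triangle of the predicted mask: convex hull of the foreground
pixel centers (monotone chain), then an exhaustive search over triangles
whose three sides are flush with hull edges, keeping the smallest one
containing the hull. Hulls of thresholded masks are small, so the cubic
enumeration is inexpensive; the tests check it against an independent
naive search on hulls of up to 12 points (0.5% area tolerance) and that
it always contains every foreground pixel.

The three recovered vertices are unlabeled. The assignment rule — a
convention of this package, since none is specified for the original
evaluation — takes the vertex with the smallest interior angle as A (the
apex of the elongated glottal triangle) and orients LV/RV so that
(LV−A)×(RV−A) > 0 in image coordinates, i.e. the anatomical left fold
lies on the image right, the endoscopic convention. Exact ties (an
equilateral triangle) resolve to the lowest-y, then lowest-x vertex.
Masks with fewer than three non-collinear foreground pixels are
undecodable: they raise, are recorded as missing predictions, excluded
from per-image means, and counted — mirroring the infeasible-AGA cases
the segmentation approach suffers on small or noisy glottal gaps.

## Metrics and statistics

Per-image, per-keypoint error is `sqrt((Δx² + Δy²)/2)` — the RMSE over
the two coordinates. An alternative reading of image-level "RMSE" is
the Euclidean distance (√2 larger); the convention is isolated in
`stats.keypoint_error`. AGA error per fold is MAE and RMSE in degrees
over test images. Segmentation quality uses the Dice similarity
coefficient 2TP/(2TP+FP+FN); the training loss is its soft, ε-smoothed
complement (ε = 1e-7), which reduces to the hard-count formula on
binarized inputs. Two empty masks score DSC 1 by convention (logged).

Methods are compared on fold-level means (n = 5 folds as subjects) with
a one-within-factor repeated-measures ANOVA: two-way decomposition
without replication, F = MS_method/MS_error with df (m−1, (m−1)(n−1)).
Effect size is classic η² = SS_method/SS_total — the convention that
reproduces the reference values (one reported η² of 0.50 matches no
standard convention on the published cells, where classic η² gives
0.600; it is documented as a discrepancy and not checked). Pairwise
comparisons are paired t-tests on fold values, Holm–Bonferroni adjusted
(via statsmodels), with Hedges' g as

    g = (mean_a − mean_b) / s_pooled · J,
    s_pooled = sqrt((s_a² + s_b²)/2),  J = 1 − 3/(4·df − 1),  df = 2n − 2,

the equal-n small-sample-corrected form; this convention reproduces the
reference effect sizes (2.76, 1.20, 2.25, 0.18, 2.77, −0.91) from the
fold cells, and matches pingouin's `compute_effsize(..., "hedges")`,
used in the tests as an independent cross-check (as is pingouin's
`rm_anova`). No sphericity correction is applied — the comparisons are
plain RM-ANOVA by design.

The reference fold-level cells (five folds × three methods, keypoint
RMSE and AGA MAE/RMSE) ship as a CSV fixture; `vfpose tables` and the
acceptance script recompute every reported aggregate from them. Two
reported quantities are not recomputable from the rounded cells and are
excluded: the prose ±SDs (not across-fold SDs of the cells under either
ddof convention) and the cross-fold DSC of 0.68 (no per-fold DSC cells
are published). The reported direct-regression "average RMSE delta of
2.54 px" computes to 2.534 from the rounded cells and is checked at
0.01; the segmentation delta of 9.95 px is inconsistent with the cells
(which give 1.47) and is excluded.

## Synthetic data

The generator renders what the estimator actually relies on, with
exactly known ground truth: a rounded dark lumen with radial shading,
two bright quasi-parallel fold bands meeting at the commissure, and a
dark triangular glottal gap whose vertices are exactly (LV, RV, A) — so
the realized AGA equals the sampled angle by construction. Nuisance
factors emulate clinical acquisition: illumination gradients, isotropic
and directional motion blur, Poisson-placed specular highlights,
Gaussian sensor noise, white-light vs narrow-band (blue-green) palettes,
and, on oncologic frames, a bright occluding mass at the commissure
(motivated by the higher anterior-commissure errors observed in
oncologic patients; the specific occlusion model is this package's
invention).

Cohort structure matches the clinical dataset's summary statistics:
124 patients by default, 1–5 frames per patient sharing per-patient
anatomy (apex position, axis, fold length, palette) with small per-frame
jitter, an oncologic fraction of 28/124, and per-frame AGA drawn from a
log-normal fitted to the published summary (median 15.12°, quartiles
8.09/22.19 → σ_log = ln(22.19/8.09)/(2·0.6745) ≈ 0.748), clipped to the
observed range [1.32°, 91.85°]. Keypoints stay ≥ 5 px inside the frame.

What the generator does not emulate: real mucosal texture, vessel
patterns, camera distortion, interlacing, non-triangular glottal
configurations, and annotation noise. Passing the recovery tests
therefore shows the pipeline is correct and the heatmap formulation is
the stronger estimator on this family of images; it does not certify
clinical-grade accuracy on real laryngoscopy.

## Problem sizes used in tests and the acceptance script

The numpy trainer is exact but slow, so the standing benchmarks run a
reduced configuration chosen once: 64×64 inputs (σ = 20·64/224 ≈ 5.7 px;
errors rescaled to 224-space), width multiplier 0.5, a 90-patient
synthetic cohort (dataset seed 7), 200 training / 50 held-out frames
with patient-grouped splits, Adam 1e-3, batch 8, up to 10 epochs,
patience 4, no augmentation. Under these conditions the heatmap network
reaches ~4–8 px mean keypoint error (224-space) and beats direct
regression on the same split in 5/5 seeds; the standing test asserts
< 10 px and ≥ 4/5 seeds. Unit tests use still smaller configurations
(32×32, width 0.25–0.35) that exercise the same code paths.

## Numerical choices and edge cases

- Rasterization: a pixel belongs to the glottal triangle iff its center
  is inside or on the boundary (half-plane sign test, tolerance 1e-9).
  Collinear keypoints cannot be rasterized and raise.
- Heatmap argmax ties break to the first row-major occurrence; an
  all-constant channel is flagged as low confidence (warning) and its
  first pixel returned.
- Degenerate AGA inputs (A coinciding with LV or RV) raise rather than
  return NaN.
- Gaussians are computed over the full grid in float64 at encode time;
  training tensors are float32 throughout.
- BatchNorm uses batch statistics in training and running averages
  (momentum 0.9) at inference; gradients were validated against central
  differences, with the caveat that near-zero BN gradients sit below
  float32 cancellation noise.
- Identical method columns in the ANOVA (zero method and residual sums
  of squares) define F = 0 rather than 0/0.
- All randomness — cohort sampling, fold shuffling, augmentation, data
  order, weight init — flows from explicit integer seeds through
  numpy Generators; equal seeds give bit-identical runs on one machine.

## Known limitations

- No ImageNet-pretrained encoder by default (hook provided); the
  original study's absolute errors are not reproducible without the
  private clinical dataset in any case, which is why the acceptance
  layer targets the published fold-cell statistics plus synthetic
  recovery rather than the clinical error magnitudes.
- The weighted-L1 ablation's threshold and weights are undocumented in
  the source protocol; the implementation exposes them as parameters
  (defaults: threshold 0.5, weights 2.0/1.0) and draws no quantitative
  conclusions from them.
- The minimum-enclosing-triangle search considers flush-side triangles
  (each side's line through a hull edge); the rare optimal triangle with
  midpoint-tangency sides can be marginally smaller, which the 0.5%
  oracle tolerance absorbs and which is irrelevant to keypoint recovery
  at pixel scale.
- The vertex-labeling rule and the validation-split construction are
  this package's conventions, stated above, not part of the original
  protocol.
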