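# Methods

## Problem and pipeline

Adult developmental dysplasia of the hip (DDH) is read from anteroposterior
pelvic radiographs through three angular indices of acetabular coverage and
inclination — Center-Edge (CE), Tönnis, and Sharp — each defined on four
landmarks per hip: teardrop inferior boundary (A), femoral head center (B),
lateral acetabular edge (C), medial acetabular aspect (D).  The package
implements the full chain

    image → 8 landmarks → reference lines → 3 angles per hip
          → per-angle category → weighted score → binary diagnosis

with each stage a standalone, separately tested function.

## Geometry

All angles are computed from direction vectors with two-argument
arctangents; no stage divides by a coordinate difference, so there are no
singular orientations.  The horizontal reference is the inter-teardrop
line (direction normalized to positive x); the vertical reference is its
perpendicular through B.  Because every angle is measured against this
patient-intrinsic frame, all three angles are exactly invariant under
rigid rotation and uniform scaling of the landmark set, and mirror
reflection across the pelvic midline swaps the two hips' measurements
exactly — these invariances are enforced by property tests.

Sign conventions extend the clinical magnitudes: CE is signed (negative
when the lateral edge lies medial to the vertical reference, i.e. severe
uncovering), Tönnis is signed (negative for a downward-sloping sourcil),
Sharp is the unsigned acute angle between lines.  For normal-to-moderate
anatomy these coincide with the usual clinical values.

## Phantom generator

The study conditions are embodied in a synthetic phantom because the
clinical radiographs this kind of system is trained on are hospital data.
Landmarks are constructed analytically so the target angles are recovered
*exactly* (round-trip error < 1e-6°, typically ~1e-13°): A points on a
horizontal line separated by the inter-teardrop distance; B at a fixed
offset from A (0.30 of the separation lateral, 0.04 superior); C solved as
the intersection of the CE ray from B and the Sharp ray from A (the three
angles share C, so C must satisfy both); D on the line through C at the
Tönnis angle below horizontal at 0.25 of the separation.  These
proportions approximate adult AP anatomy (femoral head radius 20 px and
separation 110 px at 256×256; the absolute scale is arbitrary since angles
are scale-free).  Pairs whose defining rays are near-parallel
(CE + Sharp → 90°) intersect arbitrarily far from the joint and are
rejected as anatomically contradictory; the dataset sampler redraws them.

Rendering places smooth high-contrast primitives whose generating
coordinates are the landmarks: a cone-profile disc peaking exactly at B, a
soft ridge from D ending at C with a short iliac rim continuing past C, a
compact blob at A, and a faint pelvic-brim ellipse for context, followed
by a 1 px Gaussian blur and additive Gaussian noise (default sigma 4 gray
levels, seeded).

Angle sampling draws, per angle, a category (normal 0.5, borderline 0.25,
DDH 0.25) and then a uniform value within that category's band, so all
categories are represented while normal anatomy dominates; the resulting
positive rate (~12–15% of hips) is of the same order as clinical DDH
cohorts.  Diagnosis labels come from the default scoring rule applied to
the noiseless ground-truth angles, giving calibration-recovery tests an
exactly known generating rule.

Rater variability is simulated as per-landmark Gaussian jitter with
standard deviations A 2.0, B 1.5, C 2.5, D 4.0 px for each of 3 raters;
the D:B ratio (~2.7) encodes the observed fact that the medial acetabular
aspect is the least reproducible landmark, two to three times more
variable than the femoral head center.  The consensus annotation is the
replicate mean, mirroring multi-annotator averaging.

What the phantom does *not* emulate: soft-tissue and trabecular texture,
exposure variation, pelvic tilt/rotation out of plane, osteophytes and
deformity, and pediatric anatomy.  Passing tests therefore demonstrate
correctness of the measurement/scoring chain and the trainability of the
detector — not clinical-grade detection performance on real radiographs.

## Detector

A compact region-based keypoint network implemented directly on numpy
primitives with explicit backpropagation (im2col convolutions, bilinear
RoIAlign with exact scatter-add gradients, SGD with momentum):

- **Backbone**: four 3×3 convolution stages (two stride-2, then two
  stride-1, the last with dilation 4 for a ~50 px receptive field),
  producing a stride-4 feature map.  Variants `base` (12-24-32-32
  channels), `wide` (16-32-48-48), and `deep` (extra stage) exist for the
  sensitivity harness.
- **Proposal stage**: a small convolutional head scoring single-class
  objectness per feature cell plus anchor-relative box deltas.  Cells in
  the central half of the pelvis box are positive, the rest of the box
  interior is ignored (locally indistinguishable from positives), outside
  is negative.  At inference the decoded boxes of the nine
  highest-objectness cells are averaged with objectness weights — much
  more stable than a single argmax cell — and refined twice by the box
  branch, then expanded by a fixed 12% context margin so the RoI reliably
  contains all eight landmarks.
- **Branches**: RoIAligned features, augmented with two RoI-normalized
  coordinate channels (the landmark layout inside the pelvis RoI is highly
  stereotyped, and explicit coordinates let the branches exploit that
  prior within a few hundred SGD updates), feed (i) a two-convolution
  keypoint head emitting K = 8 per-pixel-sigmoid probability maps and
  (ii) a pooled two-layer box-regression head on standard
  proposal-relative normalized offsets.
- **Supervision**: one-hot masks (a single 1 at each keypoint's grid
  cell) with the focal loss, focusing parameter γ = 2, normalized by the
  number of foreground pixels (the convention of the focal-loss detection
  literature; a total-pixel normalization is available for ablation).  At
  γ = 0 the loss reduces exactly to summed binary cross-entropy, which the
  tests assert to 1e-10.  Gaussian-heatmap supervision exists for the
  sensitivity harness only.  The final keypoint-logit bias is initialized
  to the background prior (≈ −6.9), the standard dense-detection trick
  that keeps the early background term small.
- **Box loss**: Smooth-L1 (0.5 d² below |d| = 1, |d| − 0.5 above) summed
  over (x, y, w, h).  The public `smooth_l1_box_loss` operates on whatever
  parameter scale it is given, so raw-pixel unit tests evaluate the
  printed kernel directly, while training uses proposal-relative
  normalized offsets (raw-pixel regression does not converge at practical
  scales).
- **Training**: SGD, momentum 0.9, weight decay 1e-4, initial learning
  rate 0.005 divided by 5 when the validation loss fails to improve for
  three consecutive epochs; default 15 epochs at mini-batch 4; gradients
  clipped at global norm 10.  Augmentation is joint small-angle rotation
  (±5°, resampled if a keypoint would leave the image) plus additive
  noise; measured angles are invariant to the joint rotation because the
  reference lines rotate along.  The single-image objectness term carries
  a fixed weight of 4 so the proposal stage trains at a comparable rate to
  the branches.
- **Decoding**: per-channel argmax (ties to the lowest row, then column),
  cell center mapped back through the RoI transform.

### Mask resolution

The keypoint grid default is 112×112.  The decisive constraint is angle
precision: the Tönnis angle is measured over the short C–D segment
(~27 px at the default phantom scale), so a grid-cell quantization of
c px contributes roughly `atan(c/2 / 27)` ≈ 1° per pixel of cell size.
A ~220 px pelvis RoI needs ≥ ~110 cells to keep the cell near 2 px and
the quantization contribution to every angle under about a degree —
hence 112.  Smaller grids (56) are fine for landmark localization as
such, but measurably blur the borderline bands of the scoring system.

### Desk-scale behavior

The shipped study conditions (240 training phantoms at 256×256, 5 epochs,
held-out test phantoms) train in a few minutes on one CPU and reach mean
per-keypoint error ≈ 0.9 px ≈ 0.8% of the inter-teardrop distance, with
end-to-end diagnosis F1 ≈ 0.9 against the phantom scoring labels.  The
remaining errors are dominated by grid quantization near category
boundaries, which is the expected failure mode of a threshold-based score.

## Scoring and calibration

Boundary values are assigned to the borderline category (the borderline
bands are closed intervals: CE [20°, 25°], Tönnis [10°, 13°], Sharp
[42°, 47°]).  Under the default table the minimum positive total is
exactly 5, and no hip can be positive without at least a borderline CE —
an enumeration over all 27 category triples asserts this structure, along
with monotonicity (worsening any single category never lowers the total
or rescinds a positive diagnosis).

Calibration fixes normal scores at 0, keeps borderline scores at 1 by
default (searchable), searches DDH scores over {1..4} per angle and the
threshold over {1..12}, and scores every candidate by stratified k-fold
cross-validated F1.  Ties are broken by: lower across-fold variance, then
lower threshold, then lexicographically smaller score vector — fully
deterministic.  Distinct integer score vectors can induce the same
diagnosis function; candidates whose fold-wise F1 vector equals the
winner's are reported as an equivalence class rather than hidden.

Diagnosis reports round angles to one decimal and derive the categories,
scores, and decision from those same printed values, making every report
exactly re-derivable from its own text (the explainability contract).
Full-precision angles remain available through the measurement API and
CSV outputs.

## Evaluation metrics

- **OKS**: `exp(-d² / (2 s² k²))` with s² the ground-truth box area.  The
  per-landmark falloffs default to `k = 2·sigma/s` computed from the
  rater-jitter model at the default phantom scale (A 0.030, B 0.023,
  C 0.038, D 0.061) — the same human-variability construction used for
  the reference human-pose constants — with a uniform k = 0.05 fallback.
  Thresholding is per keypoint (each of the 8 contributes its own TP/FN),
  strict inequality, over the fixed grid 0.50:0.05:0.95; a missing
  detection contributes 8 false negatives.  mAP/mAR are unweighted grid
  means.
- **ICC**: ICC(2,1) — two-way random effects, absolute agreement, single
  measurement — the standard form for method-vs-reference agreement, with
  F-distribution 95% confidence bounds; computed via pingouin and verified
  against a direct ANOVA mean-squares oracle to 1e-8.
- **Bland-Altman**: bias and bias ± 1.96 sd (sample sd), plus the
  per-pair (mean, difference) points for plotting.
- **Mann-Whitney U**: exact enumeration for combined n ≤ 12 without ties,
  normal approximation with tie correction otherwise (scipy).
- **Sensitivity harness**: trains and evaluates a list of detector
  configurations (backbone variants, γ = 0 cross-entropy, heatmap masks)
  on identical seed-fixed splits and tabulates mAP/mAR; a failing row is
  recorded with its error and does not abort the table.

## Numerical and design notes

- Degenerate inputs raise informative errors with side/label context:
  coincident landmarks, zero-area boxes, missing annotation slots,
  constant rating matrices, folds without positive labels.
- Seeds control everything stochastic: phantom sampling, rater jitter,
  augmentation draws, weight initialization, fold splits, bootstrap
  resampling.  Identical seeds reproduce manifests bit-for-bit.
- The bounding box is the tight landmark box padded by 10% of its
  diagonal on all sides — fixed and documented rather than clinical.
- One pelvis RoI per image carries all 8 keypoint channels; the detector's
  channel order is side-specific, so no post-hoc left/right matching is
  needed.
- The crossval experiment averages per-hip angle measurements across fold
  models before scoring (measurement-level ensembling), and reports a
  1,000-resample percentile bootstrap CI over test hips alongside
  per-fold F1 values.

## Known limitations

- The detector is deliberately compact and CPU-trainable; it demonstrates
  the architecture and training contracts at phantom scale and is not a
  clinical-grade radiograph model.
- Only one pelvis per image is supported; multi-object scenes are out of
  scope.
- DICOM ingestion, pelvic-tilt correction, femoral-side indices, and
  severity grading beyond the binary diagnosis are out of scope.
- Phantom realism limits are listed above; results on phantoms bound the
  method's correctness, not its clinical accuracy.
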