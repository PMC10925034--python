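# Methods

## Overview

`echoqc` models the quality-assessment loop of fetal echocardiography
screening: segment the key anatomical features of the eight standard
planes, score how well each image visualises them, keep the best frame per
plane while scanning, and evaluate all of it with the Dice-outcome
accuracy. Because clinical screening data cannot ship with the package,
a synthetic phantom supplies frames with exact ground truth; the phantom
is first-class, tested code, and its limitations (below) bound what any
result obtained on it can say about real scans.

## The phantom

Each standard plane is a fixed layout of parametric primitives — filled
ellipses, elliptical annuli, and ribbons (rotated rectangles) — standing
in for that plane's anatomical features. The default registry distributes
28 named features over the eight planes (e.g. the four chambers and
septal crux on 4CV; stomach, descending aorta and spine on Situs); the
assignment lives in configuration (`PlaneProtocol` YAML), not code, so a
clinically curated mapping can replace it without touching the renderer.

A seeded per-frame jitter shifts (±3 % of the frame), rotates (±0.15 rad)
and scales (0.88–1.12×) every primitive. The jitter is deliberately large
enough that a structure's extent cannot be recovered from its canonical
position alone: when degradation hides a structure, the information is
genuinely gone, which is what couples the quality score to achievable
segmentation accuracy.

Cardiac planes additionally render a dim rib-cage rim around the heart
region. The rim is context, never annotated: it gives heart-plane frames
a global appearance cue that non-heart frames lack, the same role the
thorax plays in real cardiac views. Non-heart frames contain
structure-like clutter blobs at random positions with no annotation —
the hard case for false positives.

Four degradation knobs emulate the dominant quality problems of screening
ultrasound:

| knob | range | emulates |
|---|---|---|
| `shadow_fraction` | [0, 1] | acoustic shadow wedge from the transducer apex; inside the wedge residual contrast drops ~16× and in-wedge noise breaks edges, so occluded structures are unrecoverable |
| `blur_sigma` | ≥ 0 px | defocus / motion blur |
| `gain_offset` | [−0.5, 0.5] | mis-set receive gain |
| `speckle_level` | ≥ 0 | multiplicative speckle noise variance |

Ground-truth masks are rasterised before degradation, so degradation
changes the image only — the annotation describes what is anatomically
present, not what is visible.

### Quality score

The QS maps degradation onto the 1–10 scale used by human raters: 10 for
a perfectly outlined structure, 5 for a structure seen through a degree of
shadow or blurriness, 1 when the outline is not seen. Only those three
verbal anchors are specified, so the score is piecewise linear in a
weighted degradation index `D = shadow + (7/90)·blur + 0.6·|gain| +
0.4·min(speckle, 1)` clipped to [0, 1], with `QS = floor(10 − 9·D + 0.5)`
clamped to 1..10. The blur coefficient is calibrated so the shipped
moderate preset (shadow 0.4, blur 2.0 px) lands exactly on 5; shadow alone
saturates the scale (total occlusion → 1); rounding is half-up so the mid
anchor is exact. The score is monotone non-increasing in every knob and
one value is assigned per image, matching how quality is stratified in
reporting.

## The network

A U-Net-style encoder–decoder: a stem block (16 channels by default) at
full resolution, five encoder stages that each halve resolution, five
decoder stages that each upsample ×2 (nearest-neighbour + convolution),
concatenate the matching encoder output, and apply two
convolution + batch-norm + LeakyReLU (slope 0.01) layers, and a final 1×1
head emitting `n_structures + 2` channels: 28 structure classes, one
explicit background class, and one quality-score channel (30 channels in
the default configuration). Structure and background channels are
normalised per pixel with a softmax; the QS channel is pooled by spatial
mean, shifted by +5.5 and clamped to [1, 10]. Making background an
explicit 30th class keeps the per-pixel normalisation well-posed; pooling
the QS channel by global mean is the simplest reduction consistent with a
single per-image score, and both choices are isolated behind the output
head so alternatives can be swapped in.

Encoder widths are configuration. The default desk-scale preset is
(16, 32, 64, 96, 128), which trains on one CPU core in minutes; a
topology-faithful preset mirroring the published RegNetY-1.6GF stage
widths (48, 120, 336, 888) exists for completeness but is not intended
for CPU training.

The layers (convolution via nine shifted tensor contractions, batch norm,
LeakyReLU, nearest upsampling, Adam) are implemented directly in numpy
with hand-written backpropagation; gradient correctness is pinned by a
float64 finite-difference check in the test suite. At the default sizes
the whole forward+backward step for a batch of four 64×64 frames takes
~0.2 s on one core.

## Training

The composite loss is
`w_seg · (soft-Dice + weighted cross-entropy) + w_qs · |QS error|`:

* **Cross-entropy** over the 29 softmax classes, with structure pixels
  weighted 15× relative to background. Structures cover a small fraction
  of each frame, split over 28 classes; without the weight the softmax
  collapses to all-background at desk scale. On all-background
  (non-heart) frames each pixel is instead weighted
  `1 + 6·(epoch/n_epochs)·(structure probability mass the model places
  there)` — ramped hard-negative pressure. Background is abundant and
  easy on heart frames, but on non-heart frames it is the lesson; with
  uniform weight the suppression signal is drowned out by the heart
  frames' foreground gradients and false positives survive training.
  The pressure focuses on the model's own false-positive pixels (a
  blanket background weight was observed to degrade segmentation) and
  ramps from zero because early in training structure probabilities are
  diffuse everywhere, so immediate pressure acts as a blanket push that
  stalls learning: the model first learns the anatomy, then unlearns
  its false positives.
* **Soft-Dice** per class and image with smoothing constant 1.0, so an
  empty target against an empty prediction contributes exactly zero —
  required by the empty-mask strategy. Only classes present in a frame's
  target (plus background) contribute; suppressing absent classes is the
  cross-entropy's job, and an extra push-down from all 28 absent classes
  was observed to swamp the presence signal.
* **L1** on the pooled QS prediction against the frame's true score,
  weight 0.1 (QS errors span ~9 units while the segmentation terms are
  O(1); 0.1 balances their gradients).

Optimiser: Adam, learning rate 3·10⁻³, batch size 4, no schedule. The
small batch buys gradient steps, which matter more than batch statistics
at this data scale. Training keeps the parameters of the epoch with the
best validation score (mean required-feature Dice minus `val_qs_mae/18`,
so segmentation dominates but a collapsing QS head is penalised). A
non-finite loss aborts with `TrainingDiverged`.

**Non-heart frames** enter the training set at a configurable fraction
(default 30 %) with all-empty target masks, i.e. every pixel labelled
background. This is what teaches the model to stay silent on frames that
show no cardiac plane.

**Split hygiene**: one `VideoScript` plays the role of one subject;
train/validation/test splits are assigned at the script level (stratified
so heart and non-heart scripts appear in every split), so no
pseudo-subject leaks across splits.

### Study configuration

The configuration used by the acceptance tests and `scripts/acceptance.py`
is: twelve screening scripts, each visiting all eight planes with four
frames per plane (one guaranteed near-clean, the rest drawn across the
degradation range), 64×64 frames, 30 % non-heart fraction, encoder widths
(16, 32, 64, 96, 128), 15 epochs. This yields ~440 training frames
(~320 cardiac + non-heart) and trains in about seven minutes on one core —
small enough to rerun routinely, large enough that held-out Dice on
above-average-quality frames clears 0.7. Held-out evaluation uses four
fresh screening scripts (128 frames spanning the quality range) plus 50
fresh non-heart frames, none seen in training; evaluating on fresh
scripts rather than the single test-split script keeps the reported
numbers from being dominated by one pseudo-subject.

## Evaluation

`dice` is 2·|P∩T|/(|P|+|T|), undefined when both masks are empty — that
case is routed directly to TN by `classify_outcome` without touching
Dice. The outcome rules: TP for Dice ∈ [0.5, 1] (inclusive at 0.5), TN
when both areas are zero, FN for Dice < 0.5 (a missing prediction counts
as Dice 0), FP for non-zero predicted area without annotation. Accuracy
is the count ratio (TP+TN)/(TP+TN+FN+FP), accumulated in exact rational
arithmetic before the final division.

Reports aggregate a structure's outcomes over frames of that structure's
own plane only — frames of other planes never contribute TNs, which would
otherwise inflate every structure's accuracy with vacuous negatives.
Per-plane figures are the mean and SD over the plane's minimum required
features; QS stratification filters frames by ground-truth (annotated)
QS, with "above average" defaulting to QS ≥ 6; a plane left with no
qualifying frames is reported missing, never as zero.

## Auto-capture

Each streamed frame is segmented, binarised (threshold 0.5, minimum
presence area 0 px — both configurable, since the FP definition hinges on
"non-zero predicted area"), and assigned to a plane: a plane is attained
when all its minimum required features are predicted present; among
attained planes the highest mean required-feature area fraction wins,
with exact ties falling back to the canonical plane order. The stored
best frame per plane is replaced only on a strictly higher predicted QS,
so ties keep the earliest frame and constant-quality segments do not
churn. Malformed frames are logged and skipped, never fatal. The
completeness report lists captured planes, missing mandatory planes, and
non-mandatory planes captured beyond the protocol (the sagittal arch
defaults to non-mandatory). An `OracleModel` that emits the ground-truth
masks and true QS lets the capture logic be verified independently of any
trained weights.

## Statistics

`fleiss_kappa` implements the classic equal-raters-per-item definition
κ = (P̄ − P̄ₑ)/(1 − P̄ₑ) and returns NaN when P̄ₑ = 1 (a single category
used everywhere), where chance-corrected agreement is undefined; unequal
row sums are rejected rather than silently approximated.
`chi_square` covers independence (margin-product expected counts,
df = (r−1)(c−1)) and goodness-of-fit (df = k−1, uniform default), without
continuity correction unless the Yates flag is set. `mann_whitney_u`
uses mid-ranks, reports U = min(U_a, U_b), and computes the two-sided
p-value exactly — P(|U − μ| ≥ |u − μ|) by enumeration over all
group assignments of the pooled mid-ranks — when both groups have ≤ 8
observations (quality scores are small heavily tied integer samples,
exactly where the normal approximation is worst), falling back to the
tie-corrected normal approximation with continuity correction above that.
All p-value distributions come from scipy; statsmodels and scipy serve as
independent cross-checks in the tests, never as the implementation.

## What the phantom does and does not show

Passing tests on the phantom demonstrate that the architecture, losses,
metrics, capture logic and statistics are implemented correctly and that
the qualitative mechanisms — quality-dependent accuracy, false-positive
suppression via empty-mask training, best-frame capture — operate as
designed. The phantom does not model wave propagation, fetal motion,
probe pressure, maternal habitus, color Doppler, or anatomical variation
beyond affine jitter; absolute accuracy or Dice values obtained on it say
nothing about performance on clinical images, and no claim of clinical
performance is made or implied.

## Known limitations

* The 28-feature registry and per-plane required subsets are a plausible
  default, not a clinically validated mapping; both are configuration.
* Fleiss' kappa requires equal ratings per item; panels with varying
  rater counts must be analysed per equal-rater subset.
* The numpy network is single-threaded and desk-scale by design; there is
  no GPU path, pretrained-encoder loading, or augmentation beyond what
  the phantom's jitter provides.
* Exact Mann–Whitney enumeration is combinatorial; the ≤ 8 per-group
  cutoff keeps it instant, and larger samples use the tie-corrected
  normal approximation.
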