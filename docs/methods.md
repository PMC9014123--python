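# Methods

This note documents the models, procedures and design decisions implemented
in `fundusfusion`, and what the synthetic experiments do and do not show.

## Problem setting

Diabetic macular edema (DME) on a colour fundus photograph is commonly
proxied, following the ETDRS criterion, by the presence of hard exudates
(HE) — small bright lipid deposits — at or within one optic-disc diameter
(1DD) of the center of the macula.  The package implements a joint approach:
a single convolutional backbone feeds both an anchor-based lesion-detection
head and a binary DME-classification head, trained together with a weighted
sum of the two losses.  Around that core sit the supporting procedures a
screening workflow needs: fusing several readers' box annotations into one
ground truth, cropping away the black border of the 45° field of view,
applying the geometric 1DD rule with detected landmarks, and the evaluation
statistics (image-level detection outcomes, ROC/AUC with DeLong inference,
two-proportion comparisons).

## Coordinate and box conventions

Boxes are continuous, 0-based, half-open rectangles `[x_min, x_max) x
[y_min, y_max)` with the origin at the top-left pixel corner, so the area of
an integer-corner box equals its pixel count and rasterization oracles are
exact.  Files that store `(x, y, width, height)` are converted at the I/O
boundary.  Two boxes that share only an edge have IoU 0.  Whether annotation
tools index from 0 or 1 is generally tool-specific; this package fixes
0-based indexing everywhere.

## Annotation consensus

Three readers annotate each image independently.  Two sets are merged by
matching boxes one-to-one and keeping, for each matched pair, the box with
the larger area, verbatim; unmatched boxes from either reader are retained.
A pair may match only when its IoU strictly exceeds 0.15 (an IoU of exactly
0.15 keeps both boxes).  The merged set is then merged once more with the
third reader's set, in that fixed order.

The matching itself is the one genuinely open design point: when overlaps
are many-to-many, "compare the two readers' boxes" underdetermines the
pairing.  The package uses the maximum-total-IoU one-to-one assignment
(solved with `scipy.optimize.linear_sum_assignment` restricted to
above-threshold pairs).  This is deterministic, order-robust up to
equal-area ties (ties keep the first argument's box), and coincides with
exhaustive enumeration over all feasible matchings — the oracle the test
suite checks against on 500 random instances.  A greedy
highest-IoU-first pairing was considered and rejected: it can diverge from
the enumeration oracle on crossed overlaps.  The two-step schedule
((1,2),3) is itself order-dependent in rare configurations; that is a
property of the procedure, not hidden by the implementation.

## Preprocessing

The fundus region is the tight bounding box of pixels whose channel-mean
grayscale exceeds 10/255 (configurable; the value is robust to sensor noise
in dark borders).  The crop is a tight rectangle — possibly non-square —
resampled bilinearly to a square model input (640 px at full scale, 128 px
in the desk-scale configuration), accepting anisotropic scale; boxes are
mapped by exact corner arithmetic and the affine transform is serialized so
predictions can be mapped back to source coordinates.  Augmentation is an
independent horizontal and vertical flip, probability 0.5 each, seeded.

## Synthetic scenes

The generator renders caricatures of 45°-FOV fundus photographs: a near-black
field, a bright circular fundus region with radial shading, one bright
elliptical optic disc, a darker macula roughly 2–2.5 disc diameters temporal
to the disc (the disc side is randomised), and 0–4 bright HE blobs.  The DME
label is *derived from the geometry*: a lesion placement is sampled according
to a Bernoulli(prevalence) draw — inside 0.85 DD of the macula center for a
DME scene, with every other lesion's nearest point kept outside 1.15 DD for
a non-DME scene — and the stored label is then recomputed with the geometric
rule from the placed boxes.  Truth and label therefore cannot disagree, and
the margin band (0.85–1.15 DD) keeps annotator jitter from straddling the
boundary.  Default prevalence is 0.42, mirroring a screening training
population where DME is common but minoritary; lesion-free non-DME scenes
arise from the lesion-count range `(0, 4)` and give the detection evaluation
its true negatives.

Simulated annotators perturb each truth box with independent
Normal(0, `annotator_jitter_sd`) corner noise (default 2 px at 256 px),
miss each lesion with probability 0.1, and add Poisson(0.1) spurious boxes;
boxes are re-validated to at least 2×2 px inside the image.  Synthetic
patients own 1–4 images (≈55 % single-image patients) so the patient-level
split logic is actually exercised; the split assigns whole patients to
train/val/test by cumulative image fractions.

Deliberately absent: vessels, drusen, hemorrhages, silicone-oil artifacts,
illumination drift, camera-specific colour response.  Lesion contrast is
high by design.  Consequently a passing end-to-end run demonstrates that the
fusion mechanism — shared features, fused loss, anchors, decoding, the
evaluation chain — works, not that the model would reach clinical
performance on photographs.

## The fusion network

One backbone, two heads:

* **Backbone** — a stride-2 convolution stack (widths `w, 2w, 4w, 4w`, ReLU,
  two extra stride-1 convolutions at the 1/8 and 1/16 scales) producing
  feature maps at strides 8 and 16.  It is a configurable width/depth
  extractor, not a replica of a named full-scale architecture; the contract
  is the topology (shared trunk, two task paths) at a CPU-trainable size.
* **Detection path** — a one-cell bi-directional feature pyramid over the
  two levels: features are projected to a common width, fused top-down and
  bottom-up with learnable non-negative scalar weights (fast-normalised),
  each fusion followed by a 3×3 convolution; a shared head (3×3 trunk, 3×3
  class and box convolutions) predicts, per anchor, a class logit and four
  encoded offsets.  Anchors are square, three octave scales per level
  (`2^0, 2^(1/3), 2^(2/3)` × stride).  Assignment: positive at IoU ≥ 0.5,
  negative below 0.4, ignored between, and every ground-truth box claims its
  single best anchor so small lesions falling between grid cells still train.
  The class bias is initialised to the background prior logit (π = 0.01).
* **Classification path** — exactly one convolution, one global average
  pooling, one fully connected layer with dropout (0.2), producing the DME
  probability through a sigmoid.

The training objective is

    E_loss = ω_ob · E_ob + ω_cl · E_cl

with `E_cl = −α (1−p_t)^γ log p_t`, `p_t = p` for a DME image and `1−p`
otherwise (α = 0.25, γ = 2), and `E_ob` the detection loss: anchor-level
focal classification plus Huber (δ = 1) regression on positives, divided by
the matched-anchor count (minimum 1).  Both terms are averaged over the
minibatch — the batch reduction is a documented choice; a sum would only
rescale the weights.  The default weights are ω_ob = 0.5, ω_cl = 100 (the
retrained balance; equal weights correspond to an initial-training setting).
`p_t` is clamped below at 1e-7; natural logarithm throughout.  The optimiser
is AdamW (decoupled weight decay 0.01, applied to kernels only) with a
half-cosine learning-rate decay over the schedule.

Full-scale defaults mirror the training regime the architecture targets:
input 640, learning rate 1e-4, batch 16, dropout 0.2.  The desk-scale
configuration (`FusionConfig.tiny`) uses 128-px inputs, backbone width 24,
batch 4 and peak learning rate 1e-3 — small batches give the short 20-epoch
schedule enough optimisation steps, and the larger rate suits the small
parameter count.  Inference applies a 0.3 score threshold and NMS at IoU
0.5; these are conventional detector defaults, exposed in the config.

Because no deep-learning framework is part of the package's dependency set,
the network runs on a compact reverse-mode automatic-differentiation engine
written on numpy (`fundusfusion.fusion.autograd`): conv2d with explicit
forward/backward (the input gradient is computed by k² shifted scatter-adds
to avoid large im2col buffers), pooling/upsampling, elementwise math, and
reductions.  Gradients are verified against central finite differences in
the test suite.  Piecewise operations (ReLU, clamp, Huber branch, |·|) treat
branch selection as locally constant, the usual subgradient convention.

The dual-model baseline consists of a detection-only and a
classification-only model built from the same components; the fusion model's
parameter count is strictly below their sum by exactly one backbone, which
is the point of sharing.

## Landmarks and the 1DD rule

The landmark detector is an interface: anything mapping an image to scored
boxes with `optic_disc` / `macula` categories qualifies, and the reference
implementation is a single-task instance of the same detection head with two
classes.  The highest-confidence candidate per category is kept.  The disc
diameter of a bounding box is the mean of width and height (discs are
near-circular); the macula center is the box centroid.  An image is DME iff
the distance from the macula center to the *nearest point* of some HE box is
at most one disc diameter — the boundary is inclusive ("at or within"), and
an image with no HE is non-DME.  Missing landmarks raise an explicit
ungradable error rather than silently returning non-DME.  The rule is
scale-invariant and monotone in the lesion set; both are property-tested.
Overlays draw HE boxes in blue and the disc box plus the 1DD circle in
white.

## Evaluation statistics

Detection is scored per image: TP if any predicted box overlaps any
ground-truth box with IoU > 0.15, TN if neither boxes nor predictions exist,
FP for predictions on a lesion-free image, FN otherwise.  Score thresholding
happens upstream at inference, so "any predicted box" means any box the
detector actually emits.  Sensitivity, specificity and accuracy carry 95 %
Wald intervals by default (Wilson available); a ratio with an empty
denominator is reported absent, never as 0.  ROC/AUC uses midrank
concordance (ties count ½), which makes the trapezoidal area equal the
Mann–Whitney probability exactly; AUC intervals and two-model comparisons
use the DeLong placement-value covariance with a two-sided normal p-value,
intervals clipped to [0, 1].  Model proportions are compared with the pooled
two-proportion z-test as named, with the caveat that the underlying images
are paired; a paired McNemar comparison would be the stricter choice and the
unpaired test is what is implemented and reported.  The operating point for
sensitivity/specificity from probabilities is the Youden-optimal threshold
on a validation split (fixed 0.5 also available); AUC is threshold-free.
Significance is α = 0.05 throughout.

## Scaled-down study sizes

The end-to-end study trains on 200 scenes and evaluates on 100 held-out
scenes at 128 px for 20 epochs (~3 minutes on one CPU core); the
annotator-noise study uses 200 scenes with corner jitter of 10 % of the box
size and a 10 % miss rate; the rule-recovery study samples 1,000 scene
geometries.  These sizes were chosen as the smallest at which the binomial
noise of the reported rates is acceptably below the margins being verified.

## Known limitations

* The synthetic scenes are mechanism fixtures; no claim about photographs
  follows from them.
* The consensus procedure's two-step schedule is order-dependent in rare
  many-to-many configurations.
* The autodiff engine is single-threaded numpy; it is sized for the tiny
  configuration, not for 640-px training.
* Landmark detection "accuracy" on real data needs a criterion (IoU
  threshold or center hit); the package defines presence-match at IoU > 0.5
  when a criterion is required.
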