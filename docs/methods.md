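# Methods

`vertemtl` implements a multitask pipeline that takes the paired axial CT
slices through the centres of the first and second lumbar vertebrae (L1,
L2) and produces a three-class bone-state call — normal, osteopenia, or
osteoporosis — together with the intermediate detections, masks and
boundary maps. This note records the model, the numerical choices, and
what the synthetic validation does and does not establish.

## Problem setting and label definition

Volumetric bone mineral density (BMD, mg/cm³) measured by quantitative CT
in the cancellous centre of L1 and L2, averaged over the two vertebrae,
classifies a subject as

* normal when BMD > 120 mg/cm³,
* osteopenia when 80 ≤ BMD ≤ 120 mg/cm³ (both ends inclusive),
* osteoporosis when BMD < 80 mg/cm³.

The pipeline learns this call directly from the two slices, with
localization and segmentation as auxiliary tasks that focus and inform the
classifier.

## Pipeline stages

**Localization.** A small single-scale anchor detector (strided conv
backbone to an 8×8 grid, nine anchors per cell) regresses
(t_x, t_y, t_w, t_h) plus objectness and a single "vertebra" class score.
Boxes decode as p_x = σ(t_x) + a_x, p_w = a_w·e^{t_w}, keeping the centre
offset inside one grid cell. The best box after NMS (IoU 0.5, ties broken
by lower (y, x)) centres a 224×224 crop; border crops use reflect
padding. The full YOLO-style architecture (deep backbone, multi-scale
feature pyramid) is deliberately replaced by a desk-scale head: only the
predicted centre is consumed downstream, and the anchor decode, target
assignment and loss structure are what the pipeline depends on.

**Dual-task segmentation.** A residual U-Net with one shared encoder and
two decoders predicts (a) the body mask through a sigmoid and (b) a soft
boundary heat map through a linear head clamped to [0, 1]. The boundary
target is built from the ground-truth mask: a separable
derivative-of-Gaussian Canny detector (non-maximum suppression along the
gradient direction, dual-threshold hysteresis with 8-connected linking)
extracts the contour, then a unit-peak Gaussian (σ = 2 px by default,
truncated at ±4σ) is centred on every edge pixel and composed with the
probabilistic-OR rule Heatsum(a, b) = 1 − (1−a)(1−b), followed by min-max
normalization. The fold is order-independent, so it is evaluated as a
running product of (1 − G). The boundary decoder's penultimate features
are concatenated into the mask decoder before its final block (a one-way
cascade) so contour evidence sharpens the mask.

**Level-set refinement.** At inference the CNN mask can be refined by a
Chan–Vese evolution with two additions: an edge indicator
g_T = 1/(1 + ν²|∇(bilateral(I))|), where ν² is the maximized between-class
(Otsu) variance of the bilateral-filtered image rescaled by its total
variance, and a gray-band constraint that pulls pixels whose intensity
lies within mean ± w·SD of the prior interior into the contour and pushes
others out (w = 2 by default). Numerical choices:

* φ is initialised as the signed distance of the prior mask (positive
  inside); no reinitialisation is performed (regularized formulation).
* H_ε(φ) = ½(1 + (2/π)arctan(φ/ε)) and δ_ε = ε/(π(ε² + φ²)) with
  ε = 1.5 px.
* The region means C1/C2 are recomputed every iteration over the hard
  partition φ > 0 / φ ≤ 0. The arctan Heaviside decays only like 1/φ, so
  H-weighted means on a large background would be badly biased toward the
  background; hard-partition means recover the true two-level means to
  within one gray level on piecewise-constant images.
* The band statistics are taken over the prior eroded by 3 px, with the
  SD floored at one 8-bit gray level. A CNN prior is least reliable at
  its boundary; eroding before sampling keeps rim and background
  contamination out of the band, which otherwise can swallow the
  background gray level and let the contour leak.
* The constraint force is applied with the sign that attracts in-band
  pixels into the region (+γ inside the band, −γ outside), i.e. the
  variational descent of γ∫Γ·H_ε(φ); under this reading in-band points
  contribute negative energy while inside the contour, which is the
  behaviour the constraint is meant to produce.
* Otsu's criterion is implemented as w0·w1·(u0−u1)² over the distinct
  image values (exact exhaustive search; images with more than 4096
  distinct values are binned first).
* Defaults μ = 1, υ = 0.5, λ1 = λ2 = 40, γ = 10, dt = 0.5, 200
  iterations. The weights are scaled so that on [0, 1] images the region
  terms (≈ 40 × 0.1² = 0.4) dominate the area term and the front moves a
  few tenths of a pixel per iteration; the curvature diffusion number
  dt·δ_max·μ ≈ 0.1 stays well under the explicit-scheme stability limit.
  The recorded energy (length + area + region + band terms) is
  non-increasing under these defaults.
* Refinement runs as non-differentiable post-processing at inference; it
  is not inside the training graph.

**Classification.** A residual backbone (stem stride 4, four stages) whose
blocks are preceded by a gated channel transformation (GCT):
s_c = α_c·(Σx_c² + ε)^{1/2}, ŝ_c = √C·s_c/(Σs_c² + n)^{1/2},
x̂_c = x_c·(1 + tanh(γ_c·ŝ_c + β_c)). With γ = β = 0 the gate is exactly
the identity, which is also the initialisation, so an untrained GCT
network reproduces a plain residual network. Mask-decoder feature maps
from the segmentation network are fused into the matching-scale stages by
a 1×1 conv over the channel concatenation (output channels preserved);
they are detached from the segmentation loss graph by default so the
classification gradient cannot corrupt the masks (ablatable). Global
average pooling plus a linear projection produces a 2048-d embedding per
vertebra regardless of backbone width; the projection weights are damped
(×0.125 at init) so the embedding norm — and hence the curvature seen by
the downstream fully connected layer — stays O(1), which removed a
persistent oscillation of the classification loss under SGD.

**Two-vertebra fusion.** One shared two-layer perceptron (hidden 256,
ReLU) scores each embedding; a softmax over the two scores yields weights
W1 + W2 = 1 (for two classes the softmax is exactly a logistic of the
score gap). The weighted embeddings are concatenated (4096-d) and a final
fully connected layer with softmax gives the study posterior. Sharing the
scorer makes the weights exactly symmetric under swapping the vertebrae.

## Class-imbalance sampling

Training draws follow p_j ∝ M_j^n over classes (n = 1 instance-based,
n = 0 class-based). Each classification example mixes an instance-based
draw with a class-based draw, x̂ = λx_I + (1−λ)x_C and the same convex
combination of one-hot labels, λ ~ Beta(α, 1) with α = 0.1. The mixed
samples feed only the classification loss; boxes, masks and heat maps
always come from the unmixed instance sample, since geometric targets do
not mix meaningfully. Mixing happens on the 224-px crops, after
augmentation and before normalization-sensitive stages.

## Multitask loss and training loop

Six terms — box IoU loss (1 − IoU between the decoded responsible anchor
and the truth box), detection class BCE, objectness BCE, soft Dice,
boundary MSE, and classification cross-entropy — are combined as

    L = Σ_i exp(−s_i)·L_i + s_i

with one trainable log-variance s_i per term. The s_i are clamped to
[−2, 5]: the upper bound keeps every effective weight above e⁻⁵ ≈ 0.007
(no term can be silently switched off), the asymmetric lower bound stops
a near-zero term (e.g. a converged boundary MSE) from being amplified by
up to e⁵ ≈ 148×, which in early experiments destabilised the whole run.
The s_i are updated by their own momentum-free SGD at half the model
learning rate; sharing the momentum optimizer made the effective per-term
rates oscillate enough to stall the classification term.

Other loop choices, each visible in the config:

* SGD, momentum 0.9, constant learning rate (default 1e-3; the phantom
  studies in the acceptance suite use 0.02, appropriate for a few hundred
  steps at desk scale), global gradient-norm clip at 50 as a spike guard.
* The classifier and fusion head run on their own SGD at twice the base
  learning rate (`cls_lr_scale`): the cross-entropy term converges far
  more slowly than the geometric terms at desk scale.
* Objectness BCE balances the lone positive anchor against the ~575
  negatives as mean-over-positives + 0.5 · mean-over-negatives.
* The (costly) segmentation targets alternate between the L1 and L2 slice
  per step, while the cheap detection head sees both slices every step —
  box regression needs the views far more than it needs depth of
  optimization (raising the localizer's learning rate instead makes the
  box loss oscillate; the `loc_lr_scale` knob defaults to 1). The
  classification batch (default 8 mixed draws per step) is independent of
  the geometric batch size.
* Classification crops are re-cut each epoch around a jittered centre
  (default ±12 px, see `TrainerConfig.crop_jitter`) so the classifier
  tolerates the detector's localisation error at inference.
* Normalization is mixed deliberately. The segmentation and localization
  paths use batch norm (their inputs are always clean slices/crops), with
  running statistics recalibrated every few epochs by a cumulative-mean
  pass over the training crops. The classification path uses group
  normalization instead: it trains on small λ-mixed batches but infers on
  clean crops, and batch-norm running statistics learned under mixed
  batches misdescribe the inference inputs badly enough to collapse
  eval-mode accuracy to chance; group norm is batch-size independent and
  behaves identically in training and inference.
* The returned weights are the Polyak–Ruppert average of the iterates
  over the last 30 % of steps (`avg_tail_frac`). Under uncertainty
  weighting each term's effective gradient stays roughly constant near
  the optimum, so the SGD iterates orbit it rather than settle; the tail
  average is the centre of that orbit and is markedly more accurate than
  the final iterate.
* Determinism: every random choice flows from one integer seed; two runs
  with the same seed produce bit-identical manifests and history CSVs.

Ablation toggles mirror the framework's three additions: `lf` (layered
fusion of segmentation features into the classifier), `gc` (gated channel
transformation), `ff` (adaptive two-vertebra fusion; off = fixed 0.5/0.5).
All-off is a plain detection + U-Net + ResNet baseline.

## Evaluation

Three-class results are evaluated one-vs-rest: accuracy (TP+TN)/total,
sensitivity TP/(TP+FN), specificity TN/(TN+FP), F1; overall accuracy is
the trace of the confusion matrix over its total and equals the
support-weighted mean recall. Undefined rates (zero denominators) are
reported as None, never as 0. Masks are scored by IoU and Dice
(Dice = 2·IoU/(1+IoU) holds exactly per case); detection by all-point
interpolated average precision at IoU 0.5; rankings by trapezoidal
one-vs-rest ROC AUC (via scikit-learn, cross-checked against the
Mann–Whitney statistic in the tests).

## The phantom cohort: what it does and does not show

Each synthetic case is a pair of 512×512 slices containing one elliptical
vertebral body (semi-axes 45–80 px, small rotation, centre jitter) with a
bright cortical rim (3 px, gray 0.88) and a cancellous interior whose gray
level is an affine map of the case BMD (slope 0.003 gray per mg/cm³,
intercept 0.10), over a textured background (mean 0.22, SD 0.02). BMD is
drawn per case from a class-conditional normal truncated to the class
interval (means 60/100/150 mg/cm³, SD 12 by default), so the label rule is
consistent by construction; both slices share the case BMD. The default
class means sit at the centres of the printed intervals; the intensity map
keeps the three class means separated by ≈ 4–5 interior-noise SDs at the
default settings, which is what the "easy cohort" capability checks use
(SD 8).

Desk-scale study sizes, chosen so the whole suite runs on one CPU in
minutes: cohorts of 60 cases (50/10/40 train/val/test stratified per
class), 20 training epochs, segmentation U-Net with 3 scales and base
width 4, classifier base width 8. All widths and depths are configurable
upward. The level-set refinement study uses rim-less, noise-free discs
with mid-class (osteopenia) BMD: the study's premise is a two-level
image, and a deeply osteoporotic BMD draw would map to the background
gray and leave no contour to recover.

Passing these studies shows the implementation can detect, segment,
refine and classify when the class signal is a clean monotone intensity
map — i.e. that the machinery is correct and trainable end to end. It
does not show clinical performance: real CT has calibration drift,
beam-hardening, anatomy overlap, cortical thinning correlated with BMD,
and inter-scanner variation, none of which the phantom emulates. The
hospital-scale accuracies reported for this class of model are therefore
out of scope here and are not reproduced.

## Known limitations

* The autodiff engine is plain numpy: single-device, float32 by default
  (float64 switchable), no operator fusion; it is sized for the
  desk-scale networks above, not for full-resolution clinical training.
* The level-set refinement assumes a roughly two-level crop; heavily
  textured interiors would need the bilateral/band parameters retuned.
* The detector is single-scale and single-class by design; fields of view
  with multiple vertebrae would need the non-goal multi-scale variant.
* Checkpoints store raw weight arrays plus the config; no versioned
  migration is attempted.
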