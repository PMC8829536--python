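# Methods

## The model

The package implements input-conditioned global color correction for
object detection. An image `x` (RGB, normalized to [0, 1]) is
transformed by

    x' = α · x + β,

with a single gain α and offset β applied identically to all three
channels. Unifying the channels (rather than predicting six per-channel
parameters) reflects the working assumption that the dominant nuisance
is achromatic illumination change — exposure and brightness — not a
color cast; it also keeps the head at two outputs and makes the
transform's effect easy to reason about.

A small network φ_θ (the DCT network) predicts (α, β) from the image
itself: encoder → global average pooling → one fully connected head.
Because the parameters are recomputed per image, the correction adapts
to each image's illumination rather than to a dataset-wide average.

### Parameter formulations

*Regression.* The head emits two unbounded pre-activations (a_x, b_x):

    α = α_max · sigmoid(a_x)          ∈ (0, α_max)
    β = β_max · (2/π) · arctan(b_x)   ∈ (−β_max, β_max)

Defaults α_max = 2, β_max = 0.1. The 2/π factor is what actually makes
the arctan squashing fill the stated open interval (−β_max, β_max);
with a bare 1/π the attainable range would be half as wide. At extreme
pre-activations the sigmoid saturates in floating point, so the
implementation clamps α into the open interval numerically (smallest
positive double, `nextafter(α_max, 0)`).

*Classification.* The head emits `k_max + (2·j_max + 1)` logits,
softmaxed per group into distributions over discrete value grids

    V_α = {i_α·k : k = 1..k_max},      V_β = {i_β·j : j = −j_max..j_max},

and (α, β) are the expectations under those distributions. Defaults
i_α = i_β = 0.1, k_max = 20, j_max = 2, giving α ∈ [0.1, 2] and
β ∈ [−0.2, 0.2]. The β grid deliberately has 2·j_max + 1 levels so that
zero (no offset) is always representable. Expectations are convex
combinations, so predictions can never leave the grid hulls.

### Clipping policy

The transform itself is applied **without** clipping during training
and sweeps — clipping would break linearity and zero out gradients —
and **with** clipping to [0, 1] only for image export and
visualization. The synthetic degradation `x_obs = a·x + b`, by
contrast, clips **by default**: real sensors saturate, which is
precisely why the inverse problem is nontrivial (a clipped bright
domain cannot be exactly inverted).

## Encoders and parameter counts

Four canonical feature extractors are built as NumPy layer stacks with
their published stage layouts (truncated before the classifier):
resnet18 and resnet34 (512 final channels), mobilenet_v2 (1280),
shufflenet_v2 1.0× (1024). Their trainable parameter counts equal the
standard feature-extractor counts exactly; with the 2-output regression
head they come to 11,177,538 (11.2 M), 21,285,698 (21.3 M) and
2,226,434 (2.2 M) parameters respectively. Batch-norm scale and shift
are counted as trainable; running statistics are not. These encoders
run inference on CPU (im2col convolutions) but are not trainable here —
there is no deep-learning framework in the dependency set, and
gradient-training a 11 M-parameter encoder in hand-written NumPy is not
this package's job.

The fifth family, `toy_linear`, is a per-pixel linear map R³ → R^C
followed by global average pooling (equivalently: an affine map of the
image's mean RGB vector, C = 8 by default). It is exactly
differentiable by hand and is the encoder actually used when the
transform is trained at desk scale. Its capacity is deliberately
minimal: predicting a global linear correction from global color
statistics is exactly the hypothesis class the problem calls for, and
it keeps the training loop free of approximation.

The classification-head variant is a single fully connected map to all
`k_max + (2·j_max + 1)` logits, split and softmaxed per group. No extra
intermediate layer is inserted; published classification-head budgets
that imply one are not reproduced by this design.

## The toy detector and its losses

The detector contract is a single method `detect(image) ->
[Detection]`; anything honoring it can be plugged into training,
ensembling and evaluation. The bundled `ToyDetector` is a four-layer
convnet (stride 8) that predicts, per grid cell, an objectness logit
and four box offsets: cell-relative center through a sigmoid, width and
height as log-scale factors around a 10 px base. It is a minimal
stand-in that preserves the structure of one-stage dense detection —
not a production detector.

Target assignment: a cell is positive iff a ground-truth box center
falls inside it; on collisions the box whose center is closest to the
cell center wins, ties going to the smaller box. The loss is

    L = BCE(objectness over all cells) + mean over positive cells (1 − GIoU),

so unassigned cells contribute no localization loss. GIoU — IoU minus
the normalized slack of the smallest enclosing box — is implemented
with exact analytic gradients (verified against finite differences and
against a rasterized-counting oracle in the tests). Width/height
offsets are clamped to e^±6 for numerical safety; the clamp zeroes the
gradient outside the interval.

Inference thresholds default to confidence 0.5 and NMS IoU 0.5, both
configurable.

## Two-step training

1. **Detector**: SGD with momentum 0.9 on minibatches with basic
   augmentation — horizontal/vertical flips, ±15 % scale jitter,
   brightness/contrast jitter. Momentum 0.9 is fixed as the
   conventional value.
2. **Transform**: the detector is frozen (asserted; its weights are
   bit-identical before and after), and the DCT is trained through it:
   image → (α, β) → x' = αx + β (no clip) → frozen detector →
   detection loss. The gradient reaches θ through
   ∂L/∂α = Σ ∂L/∂x'·x and ∂L/∂β = Σ ∂L/∂x', which requires the
   detector's input gradient — supported by the hand-written conv
   backward. Only flips are used as augmentation in this step; the
   transform should see the illumination statistics of the raw
   training images, and geometric flips are the augmentations that
   provably leave those statistics unchanged.

Desk-scale defaults: 600 detector steps at lr 0.1 and 400 DCT steps at
lr 0.05 (batch 4). These were sized so that the full two-step pipeline
runs in under ten seconds per seed on one CPU while the detector
reaches a stable loss plateau; the full-scale schedules (cosine
annealing; step decay /10 every third of training) remain available
via `TrainConfig.lr_schedule`. DCT learning rates well above ~0.1
saturate the sigmoid head early and stall training — the loss surface
through a frozen detector is not benign, and the bounded
parameterization means overshooting is absorbing.

Training the DCT is implemented for the regression formulation. The
classification formulation is fully supported at inference and in the
parameter mappings; its training would need the expectation's gradient
through two softmaxes, which the desk-scale training loop does not
implement.

## Ensembling (VME) and TTA

Given K prediction sets for one image, boxes are clustered greedily:
the highest-confidence unassigned box seeds a cluster and absorbs, per
source set, at most one unassigned box with IoU above τ (default 0.6);
ties within a source go to the higher confidence. A cluster survives
iff its member count (seed included) exceeds floor(K/2) — a strict
majority vote — and is collapsed to one detection by averaging member
coordinates and confidences alike. With K = 1 every box trivially
survives, so a single model passes through unchanged. An exhaustive
plain-loop oracle with the same semantics exists solely to validate the
implementation (they agree on 1000+ fuzzed instances).

Averaging (rather than max-confidence) was chosen for the fused score
to keep the fused detection's confidence an unbiased summary of its
supporters; a cluster may not contain two boxes of the same model, so
self-agreement cannot fake a majority.

Test-time augmentation produces the K sets from one model: identity,
left–right flip, up–down flip, 90° rotation, with box coordinates
mapped back exactly (the mappings are tested to 1e-9 against an
exact blob-locating detector, including non-square frames).

## Evaluation: Average Domain Accuracy

Per image, predictions (descending confidence, ties by input order)
greedily claim the unmatched truth of highest IoU, requiring IoU
**strictly** above 0.5; matching is one-to-one. Per-image accuracy is
TP/(TP+FN+FP); an empty image with no predictions scores 1.0 (the
detector did exactly the right thing; the convention matters because
domain means would otherwise be undefined for empty images). Domain
accuracy is the unweighted mean over its images, and ADA the unweighted
mean over domains — so domains, not images, are the unit of robustness.
Greedy confidence-descending matching is the de-facto standard; an
optimal-assignment variant would differ only in contrived geometries
and is not implemented.

## Synthetic data: what it emulates and what it does not

Scenes are textured green backgrounds (smoothed Gaussian field) with
5–15 straw-yellow elliptical objects of 3–7 px semi-axes (elongated,
randomly oriented, mildly color-jittered, center-shaded), positions
rejection-sampled to cap box overlap at IoU 0.25. Boxes are computed
from the rendered pixel mask, so they are tight by construction.
Domains differ only by a known global `x_obs = a·x + b` applied with
clipping. Default frames are 128×128 (tests use 64×64); the real
field patches the generator is modeled on are ~8× larger with ~4× more
objects per frame.

This captures exactly the structure the method assumes — objects
separable from background partly by color/intensity, domains differing
by global linear illumination — and nothing else. Passing tests
therefore demonstrate that the machinery works and that the transform
recovers known degradations; they say nothing about occlusion, blur,
appearance variation across growth stages, or non-linear sensor
responses in real field imagery.

The 3-domain reference benchmark uses gains a ∈ {0.6, 1.0, 1.5} with
b = 0 (pure exposure change, the axis the α-sweep probes) and clipping
on. On it, a detector trained on clean images loses the dark domain
entirely (accuracy 0.0), the fixed-α sweep peaks away from 1.0, and the
trained transform recovers most of the loss (see the README's worked
example); the transform's predicted gain on the a = 0.6 domain
compensates the degradation to within 0.2 of exact inversion on
average over seeds.

## Numerical choices and degenerate inputs

- Degenerate boxes (zero width/height) are rejected everywhere with
  `ValueError`; detection decode drops numerically degenerate boxes.
- Degenerate head grids (k_max = 1, j_max = 0) are legal and produce
  constant transforms.
- Probability vectors must sum to 1 within 1e-6; softmax outputs do by
  construction.
- GIoU min/max kinks use one-sided subgradients (the indicator
  convention of the analytic formulas); finite-difference checks pass
  at generic points.
- All randomness flows through explicit `numpy.random.Generator` seeds;
  identical seeds give bit-identical scenes, training curves and
  checkpoints.

## Known limitations

- A single global (α, β) cannot fix spatially varying illumination
  (shadows, vignetting) or channel-specific casts; per-channel or
  local transforms are out of scope.
- The big encoders are inference-only; end-to-end training with them
  requires a framework with autodiff and is outside this package.
- The toy detector's single 8 px-stride scale bounds achievable
  localization precision (visible as sub-0.8 IoU self-agreement under
  TTA on symmetric scenes).
- Pseudolabeling is provided in minimal form (thresholded predictions
  flagged `pseudo=True`); the retraining loop that would consume it is
  left to the user.
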