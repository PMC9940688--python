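# Methods

This note records how camfuse's pieces are defined, the defaults that
matter, what the synthetic fixtures do and do not emulate, and the choices
made where more than one reasonable definition exists.

## Backbones and the Grad-CAM contract

The three backbones are deliberately small, seeded variants of their
families; the method under study depends on the *structure* of the
target-layer activation tensor, not on ImageNet-scale weights, so tests
never rely on trained models (weight archives can be loaded when
available).

* **CNN** (`family="cnn"`): a 3x3 stem, then `depth` stages, each a
  stride-2 convolution plus one residual block; stage *i* has
  `embed_dim * 2^i` channels.  CAM target: the last stage output, shape
  `(embed_dim * 2^(depth-1), H/2^depth, W/2^depth)`.
* **ViT** (`family="vit"`): `P x P` patch embedding, class token,
  pre-norm transformer blocks (2 heads, MLP ratio 2, tanh-GELU).  CAM
  target: the patch-transformed output — class token dropped, the `N`
  patch tokens reshaped row-major (top-left origin) into
  `(embed_dim, sqrt(N), sqrt(N))`.  The geometry requires `N = HW/P^2` to
  be a perfect square.
* **Swin-style** (`family="swin"`): 4x4 patch embedding, then
  `log2(window_down/4)` stages of one shifted-window attention block plus
  a 2x2 patch merge that doubles the width, then `depth` blocks at the
  final grid.  The window is 4 (clipped to the largest divisor of the
  grid); shifts of half a window alternate between blocks.  This realizes
  window attention + shift minimally; the fidelity target is the output
  contract `(embed_dim * window_down/4, H/window_down, W/window_down)`,
  not Swin internals.

Every model ends in global average pooling plus a linear classifier over
pre-softmax logits; the class score used for CAM is the logit (standard
Grad-CAM practice).  Because the head is GAP + linear, the gradient of a
logit with respect to the target-layer activations is analytic
(`W[c]/(u*v)` per channel).  The test suite still verifies it against
central finite differences through the head (relative error < 1e-3), so
the contract — not the closed form — is what downstream code depends on.

## CAM construction

Channel weights are the spatial mean of the gradients; the weighted sum is
rectified, bilinearly resampled to the image size (output pixel centers at
`(i + 0.5)/H`, i.e. the align-corners-false convention — stated because
fusion compares maps across backbones with different native resolutions),
and min-max normalized per map.  An all-zero rectified map stays all zeros
rather than becoming NaN.  Normalization is per image, not per batch.
Maps persist as 16-bit single-channel PNG (`round(65535 * w)`) with a JSON
sidecar carrying image id, source view and target class.

## Attention selection

Intersection and union over continuous weights are the elementwise min and
max (the fuzzy-set reading; no other pointwise meaning exists for
continuous masks).  Defaults `w0 = 1.0`, `w1 = 0.5` respect the intended
ordering — consensus regions boosted, the remainder retained at half
weight — and are configuration-exposed, as is everything else in
`FusionConfig`.  The selection output is clipped to `[0, w0]`.

`Eigen{}` is implemented as the rank-1 SVD reconstruction of the
`K x (u*v)` channel stack (sign fixed so the spatial component correlates
nonnegatively with the channel mean, negatives clipped): channels that
agree survive, channel-incoherent noise is averaged out.  It is applied
across channels, not per channel — a per-channel 2-D "smoothing" would
be the identity at rank 1.  For the map-level mode (`K = 1`) it is exactly
the identity, so the convolution-free reference is unaffected.

The fusion network mirrors the IFCNN layout: CONV1 7x7/64 and CONV2
3x3/64 shared across the three inputs (each single-channel map replicated
to 3 channels first), per-channel min-max normalization of the CONV2
output to produce the selection weights, CONV3 3x3/64 tuning, CONV4 1x1/3
reconstruction, all stride 1 with zero padding, seeded He-initialised
weights and zero biases.  The network output's luminance (channel mean),
min-max normalized, is the fused importance map.  Training the fusion
network (e.g. on multi-focus data) is out of scope; reference weights can
be imported from an archive.

The selection rule generalizes to any subset of views (min/max over the
subset), which is what the two- vs three-view ablation uses; a singleton
subset is exactly the single-backbone pipeline.

## Key regions and the classifier

"Beyond the threshold" is read as `>= tau` on the normalized map, with
`tau = 0.5` by default (the threshold is a free parameter; whether it
should be relative to the map maximum is an open choice — absolute on a
min-max-normalized map makes the two coincide).  Empty masks are legal:
the pipeline warns and emits an all-black key region so batch runs never
crash on a degenerate map.

Features are the masked image bilinearly resized to `S x S` (default
`S = 64`) and flattened channel-last.  The classifier is an SVM (RBF
kernel, `C = 1`, `gamma = "scale"`, one-vs-rest) behind a per-feature
standardizer whose statistics come from the training split only.  Splits
are 80/20, stratified, seed-controlled.  These are documented defaults,
not tuned values.

## Augmentation protocol

Seven methods with fixed inclusion probabilities and parameter intervals:
HF p=0.5; brightness/contrast both in (-0.3, 0.3), p=0.4; shift in
(-0.65, 0.65), p=0.4; scale in (-0.1, 0.1), p=0.3; rotation in (-45, 45)
degrees, p=0.4; Gaussian blur with odd kernel in [3, 7], p=0.5; sharpen
with alpha in (0.2, 0.5) and lightness in (0.5, 1.0), p=0.3.  Conventions
the intervals alone do not pin down: shift is a fraction of each image
dimension (a +/-0.65 interval is implausible in pixels) with reflection
padding; brightness/contrast is `(x - 0.5)(1 + contrast) + 0.5 +
brightness`; blur sigma follows the usual kernel-size rule
`0.3((k-1)/2 - 1) + 0.8`; sharpen is the unsharp blend
`(1 - alpha) x + alpha (x + lightness (x - blur(x)))`.  Methods apply in
the fixed protocol order for determinism; outputs are clipped to [0, 1]
at source resolution.  Balancing tops each class up to a target count with
augmented copies of uniformly drawn source images, always retaining the
originals and recording each plan (seed + drawn parameters) in the
manifest.

## Fusion metrics

SF and AG have many definitional variants; the ones fixed here are
`SF = sqrt(RF^2 + CF^2)` with `RF^2` the sum of squared horizontal first
differences over `M*N`, and `AG` the mean over the `(M-1)(N-1)` interior
grid of `sqrt((dx^2 + dy^2)/2)` with forward differences.  Both take a
`scale` parameter (intensities mapped to `[0, scale]`); the default 255
matches the 8-bit convention of fusion benchmarks, while unit scale is
also supported since published SF values of order 0.03 and AG values of
order 18 suggest the two metrics are conventionally reported on different
scales.  Classification reports use macro averaging (unweighted class
means) with zero-division mapped to 0, percentages to one decimal.

## Synthetic fixtures

Each image is a textured ellipse on a band-limited noise background.
Shape, pose, stripe frequency/phase and tint are class-free nuisance
variation; the class is identified solely by a dark marking at the centre
of axis band `label % 3` (a second, off-axis marking encodes `label // 3`
beyond three classes).  The three view maps highlight overlapping bands
([0, 0.42], [0.29, 0.71], [0.58, 1.0] of the major-axis extent) at high
weight plus low-level background noise: each covers roughly half the
ellipse area (always < 60 %), the union covers it entirely, and no pixel
lies in all three bands.  Consequently *no single view observes more than
one marking position*, and fusion superiority is a designed consequence of
the fixture geometry — the generator self-checks these coverage facts in
its tests.

Robustness pairs rotate the image (uniform in +/-45 degrees) and give the
rotated member view maps whose band assignment is cyclically shifted —
each view attends to a different part of the insect than before, modelling
augmentation-induced attention drift.  The comparison rotates the
augmented maps back before thresholding, so IoU measures attention
stability rather than the rotation itself.

What the fixtures do **not** emulate: natural image statistics, multiple
growth stages per class, occlusion, background clutter correlated with the
class, or CAMs produced by trained networks (precomputed-view mode
deliberately decouples the fusion and classifier stages from backbone
quality, since untrained tiny backbones localize poorly).  Passing the
fixture-based tests therefore demonstrates the correctness and the
directional behaviour of the machinery, not field-level recognition
accuracy.

## Problem sizes and determinism

The standard study conditions are 3 classes x 100 images at 64 x 64 with
seeds {0, 1, 2} for classification, 50 pairs for robustness, and 60
fixture maps for the SF/AG comparison; these sizes make the full suite and
the acceptance script comfortably reproducible on a single CPU.  Every
source of randomness (weights, fixtures, splits, plans) flows from
explicit integer seeds; two runs under one configuration produce
byte-identical reports, checked verbatim in the tests.

## Known limitations

* Backbones are forward-only numpy models with an analytic head gradient;
  there is no training loop, so learned-CAM behaviour is out of reach.
* The fusion network runs with seeded random weights unless an external
  archive is imported; its contribution is therefore structural
  (shared-weight extraction + selection), not learned.
* The Swin-style model implements one window size and alternating shifts
  only.
* SF/AG directional comparisons are made on the synthetic fixture
  distribution; absolute values depend on the chosen intensity scale.
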