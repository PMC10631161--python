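# Methods

## Task and model

The package segments adrenal tumors in contrast-enhanced abdominal CT
volumes. The segmentation model is an encoder–decoder with a
transformer bottleneck:

* **Encoder.** A stem DSConv unit (depthwise k=3 'same' convolution +
  1×1×1 pointwise mix, group norm, ReLU) at full resolution, then four
  stages of two DSConv units followed by a stride-2 depthwise
  downsampling. Each stage halves all three spatial dimensions and
  doubles the channel width; with the default stem of 16 the widths are
  16 → 32 → 64 → 128 → 256, ending at C′ = 256 channels at 1/16
  resolution. The pre-downsampling feature map of each stage is kept
  for the skip connections.
* **Bottleneck.** A pointwise projection, then a channel-as-token
  reshape: the token sequence has length C′ and each token is one
  channel's flattened spatial map, dimension N = (W/16)(H/16)(D/16).
  A learnable positional embedding (C′ × N) is added. The transformer
  stack applies pre-norm residual layers of 8-head scaled-dot-product
  attention (d_k = d_v = N/8, no biases on the Q/K/V/O projections, one
  shared output projection) and a GELU feed-forward network with hidden
  dimension 4N. Dropout (default 0.1) acts on both sublayer outputs.
  This channel-token layout means attention mixes *channels* using
  global spatial signatures, rather than mixing spatial positions; it
  is unusual among volumetric transformers but is the layout this
  architecture family defines, and it keeps the sequence length fixed
  at C′ regardless of input size.
* **Decoder.** Tokens are reshaped back onto the bottleneck grid
  ("feature mapping"), then four 2×2×2 transposed-convolution
  upsamplings each double the spatial dimensions and halve the channel
  count; when skip connections are enabled the matching encoder map is
  concatenated and fused by one DSConv unit. A pointwise head and
  sigmoid produce per-voxel foreground probabilities at the input grid.

Ablation switches remove the skip connections (`use_skip`), the whole
token bottleneck (`use_transformer`), or vary the stack depth
(`n_transformer_layers` ∈ {0, 2, 4, 6, 8}).

Architectural details the source description leaves open and the
choices made here: normalization is group norm (training uses batch
size 2, where batch statistics are unreliable); conv-block activation
is ReLU and the FFN uses GELU; downsampling is a stride-2 depthwise
convolution; upsampling is a kernel-2/stride-2 transposed convolution
(each output voxel receives exactly one kernel tap, which avoids
checkerboard overlap); the stem does not downsample; zero 'same'
padding is used throughout, accepting the border-artifact caveat this
architecture family itself notes.

### Class imbalance

Tumor voxels are ~0.3 % of a scan, so two imbalance countermeasures are
built in:

* the sigmoid head's bias is initialized at the log-odds of a
  configurable foreground prior (default 0.01) so the initial
  prediction matches the class prior rather than 0.5 — without this,
  roughly a third of a short training budget is spent deflating the
  background probability mass;
* the training loss is the soft Dice computed **jointly over the
  batch** with a smoothing constant of 1 (the V-Net convention). A
  per-slab Dice with a tiny ε makes any slab with empty ground truth
  contribute an irreducible loss of ~1 and its gradient fights the
  tumor signal; the batch-joint form lets empty slabs act purely as
  false-positive pressure in the denominator. The per-case metric
  `dice_loss` keeps the conventional ε = 1e-5 form.

## Preprocessing

Window (level 40, width 300 → values clipped to [−110, 190] HU), then
resampling (in-plane grid scaled by 0.5 with cubic splines, z to 1 mm
slice spacing using the grid-point convention
n_out = round((n_in − 1)·s_in/s_out) + 1; nearest neighbour for masks),
then min–max normalization of the window bounds onto [0, 1], in that
order. Normalization uses the *fixed* window bounds, not per-volume
extrema, so intensities are comparable across cases; a constant volume
is therefore still well defined and only logs a warning. Masks take
the geometric path only.

## Training protocol

Adam (weight decay 1e-5), batch size 2, seed 1000, 80/20 case-level
split, random 32-slice slabs resampled every step, one slab per case
per epoch. Only the learning-rate endpoints are prescribed by the
protocol (2e-4 at epoch 0, 4e-7 at epoch 999); the default schedule
interpolates log-linearly (a multiplicative decay is the natural way to
traverse three orders of magnitude smoothly), with linear and cosine
alternatives and an optional linear warmup. Slabs shorter than the
volume are positioned uniformly; volumes shorter than a slab are
symmetrically zero-padded. An optional foreground-biased sampler
(`fg_slab_bias`) draws, with the given probability, a window guaranteed
to contain a foreground slice — a standard countermeasure to extreme
imbalance; it is off by default, matching the plain protocol. All
randomness (split, slab starts, shuffling, weight init, dropout)
derives from the configured seed; runs are bit-identical on a given
machine in single-threaded execution.

## Inference

Whole volumes are tiled along z with stride `slab_depth − overlap`; the
final slab is end-aligned rather than padded, so no synthetic slices
enter the network, and multiply-predicted voxels are averaged. Volumes
shorter than one slab are symmetrically zero-padded and cropped back.
Binarization is strict-greater at 0.5: ties go to background, the
majority class. Heat maps export one axial slice with a red-high
colormap.

## Evaluation metrics

DSC and IOU are exact voxel counts (two empty masks agree perfectly:
both are defined as 1; this degenerate case is logged). MAE is the
mislabeled-voxel fraction of the binarized prediction. Surfaces are
foreground voxels with at least one 6-neighbour background voxel
(out-of-grid counts as background); the Hausdorff distance is the full
maximum of the two directed maxima (not a percentile variant), and ASD
is directed prediction → truth as defined, with a symmetrized variant
behind a flag since most toolkits symmetrize. Distances are measured
between voxel centers in physical mm via the spacing; voxel units are
obtained by passing unit spacing. Implementation uses a k-d tree for
nearest-neighbour queries; the test suite cross-checks all five metrics
against an all-pairs brute-force oracle to 1e-9.

## Comparison statistics

`levene_test` is the original mean-centered Levene statistic with the F
reference distribution; `t_test` uses pooled-variance Student's t when
Levene does not reject at α = 0.05 and Welch's correction otherwise
(the standard reading of the Levene-then-t sequence), two-sided. Tests
are unpaired by default. Completely degenerate inputs (zero variance,
equal means) return t = 0, p = 1. Box summaries use linearly
interpolated quartiles and Tukey 1.5·IQR whiskers. The ablation
harness retrains each variant with the identical configuration and
seed on a shared split and tabulates the five mean test metrics.

## The phantom generator

`make_phantom` renders axis-aligned ellipsoidal tumors and two
kidney-like organ ellipsoids over a uniform soft-tissue background:
background ≈ 40 HU with 12 HU voxel noise, organs ≈ 100 HU, tumors
≈ 70 HU with a heterogeneity field (white noise smoothed at 2 mm,
scaled to 15 HU sd) — chosen so that after the 40/300 window the
tumor/background contrast is moderate but non-trivial; the clinical
protocol gives no intensity model. The mean image is Gaussian-blurred
(default 1.5 mm) to emulate blurred contours; the ground-truth mask is
the *unblurred* analytic ellipsoid interior. Specs are validated:
strictly positive grid and spacing, 1–2 tumors, long axis ≥ 10 mm,
tumors inside the grid and non-overlapping.

`make_cohort` samples per-case specs so that the expected bilateral
share is 49/182 and the expected tumor voxel fraction is 0.267 %
(lognormal volume jitter with unit mean), with slice count uniform over
40–100 and bilateral tumors mirrored about the mid-sagittal plane near
the organ poles. The default grid is 96×96 in-plane at 1.25 mm with
2 mm slices — a cropped abdominal field of view whose volume puts a
0.267 % tumor at a clinically plausible ~2.4 cm long axis. Each case
draws from an RNG stream keyed by (seed, case index), so cohorts are
reproducible case by case and under parallel generation.

What the phantoms do **not** emulate: organ atlases and anatomical
context beyond two kidney-like ellipsoids, beam hardening and scanner
artifacts, non-ellipsoidal tumor shapes, and intensity distributions
estimated from real data. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that the model can learn
blob-against-background segmentation under CT-like windowing and noise;
they say nothing about clinical segmentation accuracy.

## Scaled-down experiments

The clinical protocol (1000 epochs, 182 cases, four GPUs) is far beyond
desk scale, so `adreseg.experiments` defines reduced problem sizes:

* **Overfit sanity** — 4 phantoms with large sharp-margined tumors
  (semi-axes ~18×15×8 mm unilateral / 13×11×8 mm bilateral, edge blur
  0.5 mm, noise 4 HU) rendered directly on the 64×64×32 network grid at
  (2.5, 2.5, 1) mm; stem-8 model, 16-slice slabs, 300 optimizer steps,
  foreground-biased sampling p = 0.5, warmup to 1e-2 then log decay to
  2e-3, Adam β₂ = 0.99, dropout 0. A functioning network/loss/optimizer
  reaches whole-volume train soft Dice ≥ 0.95. The tumors are made
  large and crisp deliberately: this experiment isolates the
  optimization machinery, and measurement showed its limiter is
  optimization speed, not image ambiguity — a noiseless-phantom control
  scores *lower* at the same step budget, while realistic small blurred
  tumors cap the whole-volume soft Dice near 0.90 because a large
  fraction of their voxels lie in a genuinely ambiguous boundary band
  where the Dice loss's vanishing gradient sharpens probabilities only
  slowly.
* **Generalization smoke** — 25 cohort phantoms at the study-condition
  defaults (tumor fraction 0.267 %, bilateral share 49/182, blur
  1.5 mm, noise 12 HU) on 128×128 grids that preprocess to 64×64;
  80/20 split (20 train / 5 test), 450 steps, overlap-8 stitched
  inference, all five metrics on the held-out cases. Mean test DSC
  ≈ 0.87 at this scale.
* **Ablation smoke** — the component grid (ED, ED+SC, ED+SC+TF) and
  depth grid (2/4/6/8 layers) trained for a few epochs each on 32×32×32
  slabs, verifying the harness end to end and its determinism; at this
  budget the tables' metric values are not meaningful, only their
  structure and reproducibility.

The short-horizon learning rate (1e-2 → 2e-3) replaces the clinical
2e-4 → 4e-7 schedule, which is tuned for a thousand-epoch horizon and
barely moves a 300-step run.

## Numerical choices

* Autodiff engine in float32; convolutions are evaluated as direct
  tap loops (numba-jitted when available, with a pure-NumPy
  strided-slice fallback that defines the reference semantics).
* Adam: β₁ = 0.9, β₂ configurable (0.999 default, 0.99 in the short
  experiments), ε = 1e-8, L2 weight decay folded into the gradient.
* Weight init: He-normal for convolutions, Xavier-uniform for linear
  and attention projections, positional embedding ~ N(0, 0.02²),
  zero biases except the prior-initialized head bias.
* Group norm ε = 1e-5; softmax row-stabilized by max subtraction.
* Resampling: `scipy.ndimage.zoom`, cubic spline (order 3) for images,
  order 0 for masks; identity resampling is exact to interpolation
  tolerance.
* Tie-breaks: binarization is strict-greater (ties → background);
  empty-vs-empty overlap metrics are 1; surface metrics on an empty
  mask are NaN and flagged, never silently zero.

## Known limitations

* The phantom intensity model is an artifact choice, not a clinical
  claim; no attempt is made to reproduce the source study's clinical
  metric values, which depend on private data and GPU-scale training.
* The channel-token transformer layout is implemented as defined; a
  spatial-token variant is not provided.
* Whether the clinical evaluation used mm or voxel units for surface
  distances is unstated; both modes exist here, mm is the default.
* Training is single-process CPU; there is no multi-GPU path, data
  augmentation, or post-processing (no connected-component cleanup).
* Bit-identical reproducibility holds on a fixed machine; across CPU
  microarchitectures, floating-point reduction order in the jitted
  kernels and BLAS may differ, so a 300-step training outcome can vary
  in the third decimal.
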