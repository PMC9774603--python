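# Methods

## Problem and model

The package estimates frame-level pain intensity from a single face image.
Ground truth is the Prkachin–Solomon Pain Intensity score
`PSPI = AU4 + max(AU6, AU7) + max(AU9, AU10) + AU43`, computed from FACS
action-unit intensities (AU4, AU6, AU7, AU9, AU10 ∈ {0..5}, AU43 ∈ {0, 1}).
The raw 0–16 score range is clustered to six classes — 0, 1, 2, 3, {4, 5},
≥6 — and the classifier predicts the clustered level. Note the formula
admits 16 while the annotation convention for the clinical archive states
0–15; scores above 15 are accepted and fall into the top class either way.

The classifier is a parallel two-branch CNN:

* **Branch A (attention branch).** VGG-style 3×3 conv stacks. All spatial
  downsampling uses MaxBlurPool: a dense (stride-1) 2×2 max pool at constant
  size, a normalised binomial blur (default 3×3, `[1,2,1]⊗[1,2,1]/16`,
  reflect padding so DC gain is exactly 1 everywhere), then subsampling by
  the stride. The output of the chain is invariant to input shifts of
  exactly `stride` pixels away from borders and empirically much more
  consistent under 1-pixel shifts than strided max pooling. A
  channel-attention + spatial-attention block sits after the second conv
  stack ("shallow" placement; the locator is configurable), followed by the
  regional masking stage described below.
* **Branch B (context branch).** A small residual network — conv stem, then
  identity-shortcut blocks (1×1 projection only where widths change), max
  pooling between groups — supplying the global context branch A's masking
  suppresses.

Both branches end in global average pooling. Their feature vectors are
fused bilinearly: outer product, flattened row-major, signed square root,
L2 normalisation (ε inside the square root keeps the all-zero case and its
gradient finite). A linear softmax head over the fused vector produces the
six class probabilities.

## Attention internals

Channel attention follows the convolutional block attention design:
global-average and global-max descriptors each pass through a *shared*
two-layer bottleneck MLP (C → max(C/r, 1) → C, ReLU between), the two paths
are summed and squashed by a sigmoid, giving one gate in (0, 1) per channel.
Because the bottleneck mixes channels, the module is **not** permutation
equivariant at arbitrary parameters; equivariance and the
identical-channels-equal-weights property hold exactly when the bottleneck
parameters are channel-symmetric, and the tests exercise them in that
regime. Spatial attention stacks the channel-wise mean and max planes and
convolves them with one k×k filter (default 7×7, odd sizes only) plus
sigmoid. The composition order (CA, SA, CA–SA, SA–CA) is configurable and
is one of the ablation axes.

## Regional masking

The attention gates drive a core/non-core partition:

1. **Filter channels.** Channel weights are sorted ascending; the first
   `round((C+1)/4)` original indices (round-half-down, ties to the lower
   index) form the filter set — the channels judged least informative.
2. **Core mask.** The spatial weight map is flattened and the value at the
   1-based first-quartile position `(n+1)/4` (linear interpolation at
   fractional positions) becomes the threshold; pixels with weight ≥
   threshold are core (mask 1), the rest non-core (mask 0). The source
   description's mask equation literally assigns 0 to core pixels while its
   text says core pixels are *retained* by the multiplication; this
   implementation follows the text (core = 1). Whether the first quartile
   (retain the top 75 % of pixels) rather than the third (top 25 %) was
   intended is not decidable from the description; the quantile is
   configurable and defaults to 0.25 as printed.
3. **DropBlock shielding.** Within the filter channels, the masked content
   is further shielded stochastically during training. The default variant
   anchors on the filter channel with the largest mean activation, draws a
   threshold θ ~ U(0.6, 0.9) per forward call, keeps units of the anchor
   strictly above θ·peak, and broadcasts that binary mask to every filter
   channel (per-channel masking is available by config). A classical
   DropBlock (Bernoulli(γ) seed points dilated to block_size² zero blocks,
   with γ = (1−keep_prob)/block_size² · feat_size²/(feat_size−block_size+1)²)
   ships as the `gamma_stamp` variant, since that parameterisation is the
   method's stated one even though the pseudocode never consumes γ; at
   block_size = 1 it reduces to ordinary dropout with rate 1−keep_prob.

The whole masking stage is a **training-time regulariser**: at inference it
is the identity (the pseudocode's "Interface" mode is read as inference).
Masks multiply the feature map as constants — no gradient flows through the
thresholding — matching how structured dropout trains. Applying the core
mask at inference as well was tried during development and made predictions
*more* sensitive to background changes (the attention maps, and hence the
mask, move with the background), so the regulariser reading is both the
more standard and the empirically better one.

## Training and numerical choices

Networks run on a small bundled reverse-mode autodiff core over numpy
(float64), which keeps the package dependency-light and every gradient
finite-difference-checkable. Convolutions are stride-1 im2col + BLAS;
downsampling is only via the pooling ops. Initialisation is He-normal from
a seeded generator; the optimiser is Adam (default lr 1e-3 for plumbing,
2e-3 in the packaged experiments; β = 0.9/0.999). Cross-entropy over the six
levels is the loss; a 10 % holdout of the training split selects the best
checkpoint by validation accuracy. Max pooling routes gradients to the
first argmax per window; sigmoid inputs are clipped at ±60.

Everything is deterministic given the seeds: the pipeline derives per-stage
seeds from a global seed by SHA-256 hashing, so identical config + seed
reproduce byte-identical evaluation reports.

RMSE and PCC are computed on the clustered 0–5 scale (the label space the
model predicts). PCC of a constant sequence is reported as missing (NaN/null),
not 0, since its denominator is undefined.

## Synthetic data

The generator renders an elliptical face over a flat, noisy, or cluttered
background. AU intensities are sampled by rejection so the PSPI clusters to
the requested level (level 0 forces all-zero AUs), then mapped to geometry:
AU4 lowers and tilts the brows, max(AU6, AU7) narrows the eye apertures,
AU43 closes the eyes, max(AU9, AU10) adds nose-wrinkle strokes, and the
mouth stretches and opens with the total PSPI — a deliberate global
"grimace" cue that gives the easy regime its strong geometry–level
coupling. `deformation_strength` scales every coupling; at 0 the rendering
ignores the AUs entirely, a negative control in which labels carry no pixel
signal. Face geometry and background consume independent random streams, so
the same face seed produces identical facial pixels across background modes.
Cluttered backgrounds place random rectangles/ellipses with contrast
comparable to the facial features, so background shielding is genuinely
exercised.

What the generator does **not** emulate: photographic texture, identity
structure, pose, lighting, temporal continuity, or the label noise of human
AU coding. Passing tests on it demonstrate that the pipeline's mechanics
work and that the architecture can exploit AU-coded geometry; they say
nothing about accuracy on real clinical data.

## Packaged experiment scales

The packaged study conditions are deliberately CPU-scale: label recovery
trains the reduced-width parallel model (stages 8/16/32, input 48×48) on
504 flat-background frames for 25 epochs; the background-robustness
comparison trains stages 8/16 at 40×40 on 288 frames per condition for 24
epochs, three seeds, reporting the median flat→clutter accuracy drop with
and without masking. The published clinical benchmark numbers require the
restricted archive and training at far larger scale, and are out of scope.

## Known limitations

* The quartile polarity of the core mask (Q1 vs Q3) is an unresolved
  ambiguity of the source description (configurable, default as printed).
* Channel attention's bottleneck mixes channels (see above); properties that
  assume per-channel symmetry hold only for symmetric parameters.
* The dataset-curation arithmetic on the published frequency table retains
  floor(40029/10) = 4002 neutral frames, a 32.35 % share — the published
  32.4 % corresponds to keeping one frame more (random one-in-ten).
* float64 numpy training is orders of magnitude slower than a GPU
  framework; the packaged experiments are sized accordingly.
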