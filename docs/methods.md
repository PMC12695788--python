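# Methods

This note documents the model, the numerical conventions, the synthetic data
generator, and the design decisions taken where the architecture left
genuine freedom. It states nothing the tests or `scripts/acceptance.py` do
not themselves compute.

## Model

The detector is a real-time detection-transformer: a convolutional backbone
emits a P2/P3/P4/P5 pyramid (strides 4/8/16/32); the P5 map passes through
one intra-scale transformer encoder layer (AIFI, 8 heads, 1024-wide FFN,
fixed 2-D sine-cosine positional encoding); a cross-scale fusion neck merges
strides 8/16/32 at a 256-channel fusion width; and a query decoder turns a
fixed set of queries into scored boxes directly, with no non-maximum
suppression. Two necks are provided: the baseline CCFM (CSP-style fusion
nodes built from RepConv runs, strided-convolution downsampling) and the
multi-domain MDFFN (CMKBlock fusion nodes, SPDConv lossless downsampling,
and a P2 entry node). The decoder performs IoU-aware query selection — a
linear proposal head scores every memory token against grid anchors
(grid size 0.05·2^level, anchors within (0.01, 0.99) valid), the top-300
initialise the queries — followed by three layers of self-attention,
multi-scale deformable cross-attention (8 heads × 3 levels × 4 points,
offsets scaled by half the reference box size), and iterative box
refinement in logit space. Reference points are detached between layers,
the standard refinement recipe.

Assumptions inherited from this family of detectors: one-to-one
(Hungarian) assignment between queries and ground-truth boxes during
training with a focal(α=0.25, γ=2) + 5·L1 + 2·GIoU loss, auxiliary losses on
every decoder layer and on the encoder proposals, and axis-aligned boxes.
Denoising-query training — an optional convergence aid in this model
family that leaves the loss definition unchanged — is not implemented.

### RepConv fusion semantics

Each RepConv branch carries its own BatchNorm (the three-term fused sum
requires it), and fusion uses the stored *running* statistics: the fused
kernel is exact for inference-mode normalization, which is how the
conversion is defined and tested (equivalence ≤ 1e-5 pre- and
post-activation, since SiLU is applied after the branch sum in both forms).
The identity branch folds to a "diagonal unit" 3×3 kernel — centre tap
gamma/sqrt(var+eps) on the channel's own map. Activations: SiLU in RepConv
and ADSample, GELU for the MDCM input projection, ReLU for the MDCM
residual output.

### Spectral modules

FFT convention (pinned, observable through the magnitudes): unnormalized
forward transform, 1/(H·W) inverse — numpy's default. The dual-domain
attention weights are plain convolution outputs of the pooled descriptor
(no squashing nonlinearity): the module definition applies the 1×1
convolution to GAP(x) directly, and the equations are implemented as
written. Since a real per-channel scalar w multiplies the whole spectrum,
F_fca = |w·x|; the module is nevertheless computed through the FFT so that
the convention stays on the tested path. The frequency-modulation block
(FMB) initialises α=0, β=1, i.e. as the identity; consequently its two 1×1
convolutions receive zero gradient until α moves away from zero (α itself
has nonzero gradient from the first step). Complex-differentiation rules
for fft2/ifft2/elementwise products/|·| are finite-difference-checked in
the autodiff test-suite.

### ADSample

Pattern templates: N = n² points laid out as an n×n grid; even n uses
offsets {0..n−1} (a stride-n window covered exactly once), odd n uses
centred offsets, matching the receptive field of an odd strided kernel.
Coordinates are unnormalized pixels, origin at the top-left pixel centre;
out-of-bounds bilinear neighbours contribute zero. The offset convolution
is zero-initialised so training starts from regular patterned sampling, and
the (N,1) column convolution is implemented as a dense contraction over
(channels × N), which is arithmetically identical to rearranging the N
samples along the height axis and convolving with an (N,1) kernel at
stride (N,1).

Placement: in EFENet-based models ADSample replaces the three stride-2
stage-transition convolutions; in the ResNet-18 baseline (which has no
standalone transitions) it replaces the strided 3×3 convolution inside each
downsampling residual block, keeping the 1×1 projection shortcut; in the
CCFM neck it replaces the two bottom-up downsampling convolutions. The
MDFFN neck keeps SPDConv as its downsampler — that module is the neck's own
contribution. Default N = 9 (3×3 pattern): it matches the 3×3 receptive
field of the strided convolution it replaces and keeps the column
convolution at parameter parity with it (N·C·C′ = 9·C·C′), consistent with
the near-neutral parameter budget of the sampler swap; N = 4 is used for
the reduced training-smoke models where cost matters more than parity.

## Default configuration and the complexity targets

The architecture fixes scales and mechanisms but not every width/depth.
The free choices were fixed once, against an exact parameter counter and a
measured MAC count, so that the assembled variants reproduce the published
complexity table: baseline 19.8 M, backbone-swap 13.8 M, full model 14.7 M
parameters and 55.5 GFLOPs at 640×640 (the baseline measures 57.0 GFLOPs
under the same convention, matching its published 56.9). The resulting
defaults:

| choice | value | note |
|---|---|---|
| EFENet widths / stem | 64·128·256·512 / 32 | same pyramid widths as the ResNet-18 it replaces |
| EFENet depths / n / hidden | (3,3,3,1) / (2,2,1,2) / 0.5·width | shallow stages carry the depth: small-target capacity at high resolution, cheap parameters |
| neck fusion width | 256 | decoder width |
| CMK split / strip | 25% / 31 | thin processed branch, long strips |
| SPD reductions | 118 (neck), 70 (P2 entry) | 1×1 width ahead of space-to-depth |
| decoder | 3 layers, 300 queries, 256 wide, FFN 1024 | the r18-class decoder configuration |
| prediction heads | tied across decoder layers | one score head + one box MLP applied at every refinement step |
| FLOP convention | GFLOPs = 2 × MACs | counts dense multiply-accumulates (convs, linears, attention matmuls); FFTs and interpolation excluded |

Tying the prediction heads across refinement steps is the one deliberate
departure from the fully per-layer heads some implementations use; it is a
standard weight-sharing variant of iterative refinement and is what brings
the decoder budget to the published totals. The P2 level is fused downward
(SPDConv to stride 8, merged into the finest fusion node) and is *not*
passed to the decoder, so decoder cost is independent of the P2 addition;
`NeckConfig.use_p2` records this as configurable. FMB is applied to the
MDCM output inside the CMKBlock processing branch (the residual equation of
MDCM itself contains only the kernel sum and the dual-domain attention
term).

## Numerical choices

* Everything computes in float64. The fusion-equivalence and DFT-oracle
  tolerances (1e-5 absolute) hold with large margin; float32 would sit
  uncomfortably close to them at 512 channels.
* Depthwise large-kernel convolutions run via FFT convolution; their MAC
  cost is still tallied at the sliding-window count, as complexity tables
  conventionally do.
* Greedy metric matching breaks score ties by original detection order
  (stable sort); Hungarian matching uses `scipy.optimize.
  linear_sum_assignment` on a focal/L1/GIoU cost with NaNs mapped to a
  large finite cost.
* AP uses COCO-style 101-point interpolation by default (11-point and
  exact step integration selectable); precision/recall report 0 with a
  warning when a denominator is empty; AP is undefined (error) for a class
  with no ground truth, and such classes are excluded from mAP with a
  warning.
* The counting regression reports OLS slope/intercept/R² of machine on
  manual counts, while MAE/RMSE are computed from the raw machine−manual
  differences (counting error, not fit residuals).
* Dataset split rounding: train = floor(0.7·n), val = round(0.2·n), test =
  remainder — the convention that yields 1367/391/196 at n = 1954.
  Augmentation "factor" counts the original: factor 4 = original + 3
  augmented copies (1367 → 5468). Boxes leaving the frame under geometric
  augmentation are clipped and dropped below 20% visible area (configurable).

## Synthetic scenes: what they do and do not emulate

`generate_scene` renders a textured green background with elliptical
leaf/branch clutter, Poisson-many shaded berry discs (red/green, radius
6–16 px at 640² by default, 35% of berries placed in clusters around an
earlier berry), leaf-shaped occluders over a configurable fraction of
berries (berries under 25% visible are dropped from the labels), and a
global illumination gain spanning backlit to frontlit conditions. Labels
are exact disc bounding boxes, so rendered centroids match label centres to
sub-pixel accuracy.

Not emulated: perspective and depth-of-field, specular foliage, motion
blur, fruit shape variation beyond circles, correlated colour casts, and
annotation noise. Passing tests on these scenes therefore demonstrate that
the architecture is trainable end-to-end and that the pipeline arithmetic
is correct; they say nothing about accuracy on real orchard photographs,
which the published headline accuracies refer to and which require the real
dataset and long GPU training — both out of scope here.

## Problem sizes used by the test-suite

Module tests run at 4–16 channels and 4–16 px maps, where the independent
oracles (sliding-window convolution, dense DFT matrices, brute-force greedy
matching, normal equations) are exact and fast. The learning smoke check
trains a 0.66 M-parameter reduced model (2 decoder layers, 30 queries,
128×128 input) on 20 scenes for 200 AdamW steps (lr 2e-3, batch 4) —
about two minutes on one CPU core — and requires mAP50 ≥ 90% on its own
training set. Complexity checks build the full-size models and measure one
640×640 forward pass. These sizes were chosen so the correctness content of
each check is undiluted while the whole suite stays interactive.

## Known limitations

* `berrydetr.nn` is a minimal autodiff core: single-threaded numpy, no
  dropout, grouped convolutions only as depthwise, batch-norm running
  statistics shared across the module's uses. It is intended for desk-scale
  experiments and verification, not large-scale training.
* The published inter-row deltas of the ablation table are not mutually
  consistent (the neck increment differs depending on the backbone row it
  is measured against); the defaults here reconcile the directly targeted
  rows, and the neck increment over the baseline lands between the two
  published implied values (+0.82 M).
* Letterboxing pads bottom/right only; detections are mapped back through
  the single scale factor.
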