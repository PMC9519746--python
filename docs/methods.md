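# Methods

## Problem and model

`attnmorph` performs unsupervised deformable registration of 3D scalar
volumes. Given a fixed image f and a moving image m on a common voxel grid,
a convolutional network g_θ(f, m) = u predicts a dense displacement field
u (in voxel units); the transformation is φ(p) = p + u(p), and a
differentiable spatial transformer resamples m at the displaced positions
so that m∘φ can be compared with f. No ground-truth deformations or
segmentations enter training: the network parameters θ are fitted by
minimizing an intensity-similarity loss plus a smoothness regularizer.

The field predictor is a U-Net: the 2-channel concatenation (f, m) is
downsampled by 3×3×3 stride-2 convolutions with LeakyReLU (slope 0.2,
configurable), and decoded by alternating nearest-neighbour ×2 upsampling,
skip concatenation and 3×3×3 convolutions, ending in a 3-channel head that
emits u at full resolution. Default channel widths follow the established
VoxelMorph convention — encoder (16, 32, 32, 32), decoder
(32, 32, 32, 32, 32, 16, 16) — and are fully configurable. The head is
initialized from N(0, 1e-5²) so an untrained network predicts a
near-identity registration; this keeps the first warp well-behaved and is
standard practice for registration networks.

### Dual attention on skip connections

Each skip connection passes through two attention blocks before
concatenation into the decoder:

1. **Coordinate attention.** The skip feature map (C, D, H, W) is pooled
   three times — a 1D global average along each spatial axis — giving
   descriptors (C, D), (C, H), (C, W). These are concatenated along the
   pooled axis, passed through a shared reduced-width 1×1 transform
   (rectifier nonlinearity, reduction ratio r = 8 with an intermediate
   width floor of max(C/r, 4)), split back per direction, and mapped by
   per-direction 1×1 transforms + sigmoid into three gates. The block
   output is x · g_d(d) · g_h(h) · g_w(w) per channel. The usual
   formulation of this block is two-dimensional (height/width poolings and
   a two-gate product); the three-axis pooling with a three-factor gate
   product is its symmetric 3D extension and is the only extension
   consistent with the multiplicative gate form. Because each gate lies in
   (0, 1), elementwise |output| ≤ |input|.

2. **Gated spatial attention.** The (possibly coarser) decoder feature at
   the matching resolution acts as gating signal g: both g and the skip
   feature x_l are projected by 1×1×1 convolutions to F_int = max(C/2, 4)
   channels, added, rectified, collapsed to one channel by a final 1×1×1
   convolution with bias, and squashed by a sigmoid into per-voxel
   coefficients α ∈ (0, 1) that rescale x_l. Irrelevant regions are
   suppressed; salient regions pass through. When g is coarser it is
   nearest-neighbour upsampled onto x_l's grid first.

Composition order is coordinate attention first, then the spatial gate,
then concatenation (configurable only through the code; the order is not
uniquely determined by the block definitions, and this default keeps the
channel-gating upstream of the voxel-gating). Both blocks support a
`saturate` mode that forces every gate fully open; in that mode the network
reproduces the attention-free U-Net computation exactly, which is used as
an equivalence oracle in the tests and as an ablation switch
(`attention_enabled=False` removes the blocks and their parameters
entirely).

An open ambiguity in the surrounding literature is whether the spatial
gate should consume channelwise average-/max-pooled maps (CBAM-style) or
additive learned projections of g and x_l; this package implements the
additive-projection form, which is the one written as an explicit formula
in the sources this design follows.

## Loss

The similarity term is windowed local cross-correlation. For each voxel p,
local means of f and w = m∘φ over an n³ window (default n = 9) are
removed and the squared local covariance is normalized by the two local
variances, each stabilized by eps = 1e-5; each local term lies in [0, 1]
by Cauchy–Schwarz, and `local_cross_correlation` returns the sum over the
grid, so CC(f, f) = |Ω| for non-degenerate images. Window statistics are
taken over the intersection of the window with the grid (boundary windows
use fewer samples) rather than zero padding: padding both images with
identical zeros manufactures spurious boundary correlation, breaks the
affine-intensity invariance of CC, and biases the loss toward the
boundary shell. CC is invariant to affine intensity rescaling of either
image (up to eps effects), which is why no particular intensity
normalization of the inputs is required for training to be well-posed;
min-max rescaling at load time only stabilizes things numerically.

The *training* similarity loss is the per-voxel mean, L_sim = -CC/|Ω|
(−1 at a perfect match). Normalizing per voxel puts L_sim on the same
scale as the (per-voxel) bending penalty below, so the weight α has a
grid-size-independent meaning; with the raw sum, any fixed α would make
the regularizer vanish relative to the similarity term as the volume
grows.

The regularizer is the bending energy of the transformation,

    P = (1/V) Σ_p Σ_c [T_xx² + T_yy² + T_zz² + 2 T_xy² + 2 T_xz² + 2 T_yz²],

with T = φ per component; since the identity has vanishing second
derivatives, P is evaluated on u directly. Second derivatives are
discretized with the compact [1, −2, 1] stencil (pure terms) and nested
central first differences (mixed terms); a 2-voxel margin per face is
excluded from the mean so no one-sided second-derivative stencils are
needed, which means grids must be at least 5 voxels per axis. P ≥ 0
always and P = 0 exactly on affine fields u = A·p + b, so the penalty
promotes local affinity without punishing global linear trends. The total
loss is L = L_sim + α·P with α = 0.05 by default (α = 0 recovers the
similarity-only ablation). A first-order diffusion penalty
(`gradient_penalty`) is provided solely as an ablation alternative.

## Transform and field analysis

Warping uses trilinear interpolation (differentiable with respect to both
the image and the field) for intensities and nearest-neighbour for label
maps; out-of-grid sample positions are border-clamped by default, with a
zero-fill option. Field regularity is assessed through the Jacobian
∇φ = I + ∇u, discretized by central differences (one-sided at the
boundary); `nonpositive_jacobian_fraction` reports the percentage of
(masked) voxels with det ≤ 0. The non-strict inequality is the default
because det = 0 is equally non-diffeomorphic; a `strict` flag switches to
det < 0. When label maps are available, the non-background mask is the
union of non-zero labels; otherwise the whole grid is counted.

## Evaluation

Registration quality is scored as Dice overlap 2|A∩B|/(|A|+|B|) per
structure after warping the moving labels with nearest-neighbour
interpolation. A label absent from both maps scores 1.0 and is flagged in
the report, so absent small structures do not poison summary means.
Summaries pool Dice over (structure × pair) observations; standard
deviations use the sample (n−1) denominator, with SD defined as 0 for a
single observation. CSV reports carry one row per (pair, structure) plus
one `pct_nonpositive_jacobian` summary row per pair.

## Synthetic data

The generator stands in for labeled brain-MRI datasets at reduced scale.
Phantoms are a large central ellipsoid ("head", label 1) containing
smaller ellipsoids (labels 2..k) at seeded offsets, each with a distinct
intensity level in [0.35, 0.95] on a zero background, plus additive
Gaussian noise (default SD 0.02) clipped to [0, 1]; with zero noise the
image is piecewise constant. Deformations are drawn as normal
control-point displacements on a coarse lattice (default spacing 8
voxels), cubically interpolated to the grid, scaled to a target maximum
amplitude (default 4 voxels), and accepted only if every Jacobian
determinant is positive (otherwise shrunk by 0.8 and re-checked, with a
bounded retry count) — so every generated case has a guaranteed
topology-preserving ground truth. The moving image/labels are the fixed
phantom warped by that field with the same warp operator used in training,
which is self-consistent but shares the operator's interpolation bias.

What the phantoms do **not** emulate: MRI physics (bias fields, Rician
noise), anatomical texture within structures, multi-modal contrast, and
inter-subject topology differences. Passing the synthetic tests
demonstrates that the estimator, losses and evaluation chain are correct
and that the regularizer behaves as designed — not that full-scale
brain-MRI accuracy figures are reproduced, which would require the real
dataset, orders of magnitude more optimization steps, and full-resolution
grids.

## Optimization and scale choices

Training uses Adam at batch size 1, cycling deterministically through the
supplied pairs. Full-scale defaults are learning rate 1e-4 and 50,000
iterations. The desk-scale preset (`TrainConfig.desk()`) used for the
synthetic experiments runs 400 iterations at learning rate 1e-3 on 32³
volumes: a single-pair problem trained for a few hundred steps needs a
proportionally larger step than a 50k-step schedule, and 32³ with the
default architecture is the largest size that keeps a paired
(α = 0.05 vs α = 0) experiment comfortably within a desktop-CPU run.
Training aborts with diagnostics (step and loss components) if the loss
becomes non-finite. Loss histories log (total, similarity, smooth) with
total = similarity + smooth exactly.

The numerical core is a small reverse-mode autodiff engine over numpy
arrays (`attnmorph.autodiff`) implementing exactly the operations the
model needs — 3×3×3 convolution (as 27 shifted-slice matrix products),
nearest-neighbour upsampling, box sums, trilinear warping, channel-wise
linear maps, and elementwise primitives — with float32 parameters and
activations. Every kernel is verified against explicit-loop brute-force
oracles and central-difference numerical gradients in the test suite.

## Known limitations

- Displacements are predicted and regularized in voxel units; anisotropic
  spacing is carried through I/O (and `world_displacement` converts to mm)
  but the losses do not weight axes by physical spacing.
- No diffeomorphic integration layer (scaling-and-squaring); regularity is
  encouraged by the bending penalty, not guaranteed.
- Input grids must be divisible by 2^depth; no automatic padding.
- Batch size is fixed at one volume pair per step.
- The trainer offers no augmentation, learning-rate schedules or
  multi-resolution pyramids.
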