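# attnmorph

Unsupervised deformable registration of 3D medical image volumes, built
for researchers who need a dense, smooth voxel-wise alignment of a moving
scan to a fixed scan (brain MRI being the archetypal case) without any
ground-truth deformations or segmentation labels at training time.

## The method

A convolutional network predicts the registration in a single forward
pass. Given fixed and moving volumes f, m: Ω ⊂ ℝ³ → ℝ on a common grid, a
U-Net style encoder–decoder g_θ(f, m) = u emits a dense displacement field
u, defining the transformation φ(p) = p + u(p). A differentiable spatial
transformer resamples the moving image to m∘φ, and θ is learned by
minimizing

    L(f, m, φ) = −CC(f, m∘φ)/|Ω| + α·P(φ)

where CC is the windowed local cross-correlation (n³ windows, default
n = 9; intensity-scale-invariant, summing per-voxel squared normalized
local covariances, each in [0, 1]) and P is the bending energy — the mean
squared second spatial derivative of the transformation,

    P = (1/V) ∫ [T_xx² + T_yy² + T_zz² + 2T_xy² + 2T_xz² + 2T_yz²],

which vanishes exactly on affine maps and penalizes curvature and folding
in the field (default weight α = 0.05).

Two attention blocks sit on every skip connection of the U-Net:
**coordinate attention** (three 1D global poolings, one per spatial axis,
producing per-axis sigmoid gates whose product rescales the skip features)
and a **gated spatial attention** block (additive 1×1×1 projections of the
skip features and the decoder-side gating signal, collapsed to per-voxel
coefficients α_i ∈ (0, 1)). Saturating every gate reduces the model
exactly to a plain VoxelMorph-style U-Net, which is both a tested
equivalence oracle and the ablation switch.

Evaluation follows the field's standard pair: Dice overlap
2|A∩B|/(|A|+|B|) per labeled structure after warping the moving labels,
and the percentage of voxels with non-positive Jacobian determinant
det(∇φ) ≤ 0 (folding). A synthetic module generates multi-label ellipsoid
phantoms and guaranteed fold-free smooth deformation fields, so the whole
pipeline is testable end-to-end with no downloads.

Everything runs on a plain CPU stack (numpy/scipy with a small built-in
reverse-mode autodiff core); no GPU framework is required.

## Worked example

```bash
python examples/train_toy_registration.py
```

trains the full dual-attention model on one synthetic 16³ pair (about a
minute on a CPU) and prints:

```
step    0  total -0.3861  similarity -0.3861  smooth 0.000000
step   50  total -0.6338  similarity -0.6499  smooth 0.016170
step  100  total -0.6837  similarity -0.7062  smooth 0.022536
step  150  total -0.7371  similarity -0.7698  smooth 0.032760

loss: -0.3861 -> -0.7783 (-1 would be a perfect local-correlation match)
mean Dice before registration: 0.6936
mean Dice after registration:  0.9615
% non-positive Jacobian of the learned field: 0.0000
```

The similarity column is −CC/|Ω|: at step 0 the untrained network predicts
a near-identity field, so the value (−0.39) is just the residual local
correlation of the unaligned pair; it approaches −1 as the warped moving
image aligns with the fixed image. The `smooth` column is α·P, the
weighted bending penalty of the predicted field — it grows as the field
takes shape but stays small because the regularizer suppresses curvature.
Registration lifts the mean label Dice from 0.69 to 0.96 while the learned
field stays free of folds (0% non-positive Jacobians).

The other examples show the synthetic generator with its ground-truth
bookkeeping (`examples/synthesize_and_evaluate.py`) and the attention
blocks in isolation (`examples/attention_blocks_demo.py`).

## Command line

The same workflow is scriptable from a shell; every run writes its fully
resolved configuration next to its outputs:

```bash
attnmorph synth --shape 32 --structures 3 --amplitude 4 --seed 1 --out case/
attnmorph train --fixed case/fixed.nii.gz --moving case/moving.nii.gz \
    --iterations 400 --alpha 0.05 --out run/
attnmorph register --checkpoint run/checkpoint.npz \
    --fixed case/fixed.nii.gz --moving case/moving.nii.gz --out reg/
attnmorph evaluate --fixed-labels case/fixed_labels.nii.gz \
    --moving-labels case/moving_labels.nii.gz --field reg/field.nii.gz \
    --out report.csv
```

Volumes, label maps and 4D displacement fields are NIfTI (.nii/.nii.gz);
reports are CSV with one row per (pair, structure) Dice plus a
`pct_nonpositive_jacobian` summary row per pair.

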