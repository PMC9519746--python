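"""Generate a synthetic registration case and score its ground truth.

Builds a 32^3 three-structure phantom, deforms it with a smooth fold-free
field of 4-voxel amplitude, and evaluates (a) the unregistered overlap
between fixed and moving labels and (b) the overlap recovered by the known
ground-truth field.  The Dice gap between the two is what a registration
algorithm can hope to close on this case.
"""

import numpy as np

from attnmorph import (
    DeformationField,
    FieldSpec,
    PhantomSpec,
    evaluate_pair,
    make_registration_case,
)

shape = (32, 32, 32)
fixed, moving, true_field, fixed_labels, moving_labels = make_registration_case(
    PhantomSpec(shape, n_structures=3, intensity_noise_sd=0.02, seed=1),
    FieldSpec(shape, amplitude=4.0, smoothness=8.0, seed=1),
)

identity = DeformationField(np.zeros((3,) + shape, dtype=np.float32))
baseline = evaluate_pair(fixed_labels, moving_labels, identity, pair_id="identity")
# warping the fixed labels by the true field reproduces the moving labels
recovered = evaluate_pair(moving_labels, fixed_labels, true_field, pair_id="truth")

print(f"ground-truth deformation: max |u| = {np.abs(true_field.u).max():.2f} voxels")
print(f"unregistered mean Dice   = {baseline.mean_dice:.4f}  "
      f"(overlap destroyed by the deformation)")
print(f"ground-truth mean Dice   = {recovered.mean_dice:.4f}  "
      f"(interpolation losses only)")
print(f"% non-positive Jacobian  = {baseline.pct_nonpositive:.4f}  "
      f"(the generated field is fold-free by construction)")
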