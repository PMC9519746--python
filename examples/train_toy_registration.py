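"""Train the dual-attention registration network on one synthetic pair.

A 16^3 case keeps this demonstration quick (about a minute on a laptop
CPU).  The script prints the loss trajectory and the Dice improvement of
the learned registration over the unregistered baseline; the bending
penalty (the `smooth` column) stays small because alpha = 0.05 discourages
curvature in the predicted field.
"""

import numpy as np

from attnmorph import (
    DeformationField,
    FieldSpec,
    LossConfig,
    PhantomSpec,
    TrainConfig,
    evaluate_pair,
    make_registration_case,
    register,
    train,
)

shape = (16, 16, 16)
fixed, moving, _, fixed_labels, moving_labels = make_registration_case(
    PhantomSpec(shape, n_structures=2, intensity_noise_sd=0.02, seed=3),
    FieldSpec(shape, amplitude=3.0, smoothness=6.0, seed=3),
)

cfg = TrainConfig.desk(iterations=200, seed=0,
                       loss=LossConfig(window_n=5, alpha=0.05))
params, history = train(
    [(fixed, moving)], cfg,
    progress=lambda rec: print(
        f"step {rec['step']:4d}  total {rec['total']:+.4f}  "
        f"similarity {rec['similarity']:+.4f}  smooth {rec['smooth']:.6f}")
    if rec["step"] % 50 == 0 else None,
)

field, warped = register(params, fixed, moving)
identity = DeformationField(np.zeros((3,) + shape, dtype=np.float32))
before = evaluate_pair(fixed_labels, moving_labels, identity)
after = evaluate_pair(fixed_labels, moving_labels, field)

print(f"\nloss: {history[0]['total']:+.4f} -> {history[-1]['total']:+.4f} "
      f"(-1 would be a perfect local-correlation match)")
print(f"mean Dice before registration: {before.mean_dice:.4f}")
print(f"mean Dice after registration:  {after.mean_dice:.4f}")
print(f"% non-positive Jacobian of the learned field: "
      f"{after.pct_nonpositive:.4f}")
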