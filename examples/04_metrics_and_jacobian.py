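"""Evaluate deformation quality: Dice, Jacobian determinants, folding.

Shows the closed-form behaviour of the metrics on analytic fields — a
uniform expansion has determinant 1.5^3 everywhere, a reflection folds
every voxel — and the folding ratio of a realistic smooth field.
"""

import numpy as np

from wavemorph import folding_ratio, jacobian_determinant, make_smooth_field
from wavemorph.warp import identity_grid

g = identity_grid((12, 12, 12))

for name, u in [("zero field (identity)", np.zeros((3, 12, 12, 12), np.float32)),
                ("uniform 1.5x expansion", 0.5 * g),
                ("global reflection", -2.0 * g)]:
    det = jacobian_determinant(u)
    print(f"{name:24s} det range [{det.min():+.3f}, {det.max():+.3f}]  "
          f"FR {folding_ratio(u):6.2f}%")

u = make_smooth_field(seed=5, shape=(32, 32, 32), amplitude=2.0)
det = jacobian_determinant(u)
print(f"{'smooth random field':24s} det range [{det.min():+.3f}, "
      f"{det.max():+.3f}]  FR {folding_ratio(u):6.2f}%")
# determinants near 1 mean near-volume-preserving deformation; any value
# <= 0 would mark a locally orientation-reversing (folded) voxel
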