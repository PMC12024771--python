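"""Train the registration network and refine it per pair.

The two-stage protocol of learning-based registration at desk scale:
amortized unsupervised training (windowed-NCC similarity + diffusion
regularization, Adam, batch size 1) over a few synthetic pairs gives the
network a prior and a warm start; a short label-free instance optimization
then closes the remaining gap on each held-out pair.  Takes a few minutes
on one CPU.
"""

import numpy as np

from wavemorph import LossConfig, folding_ratio, make_pair, warp
from wavemorph.metrics import dice_per_structure
from wavemorph.network import WaveMorph
from wavemorph.pipeline import RunConfig, _eval_pairs, instance_refine, train

loss = LossConfig(similarity="ncc", lam=1.0, ncc_window=5)
train_pairs = [make_pair(s, (24, 24, 24)) for s in range(4)]
val_pairs = [make_pair(100 + s, (24, 24, 24)) for s in range(2)]

pre_dice, _ = _eval_pairs(WaveMorph(seed=0), val_pairs)
print(f"before training: held-out Dice {pre_dice:.3f}")

cfg = RunConfig(loss=loss, lr=3e-3, epochs=30, seed=0, flip_augment=0.0,
                val_interval=1000)
result = train(cfg, train_pairs,
               log_fn=lambda e: print("  ", {k: round(v, 4) for k, v in e.items()})
               if e["epoch"] % 10 == 0 else None)

dices, frs = [], []
for pair in val_pairs:
    u = instance_refine(result["model"], pair.moving.intensity,
                        pair.fixed.intensity, loss, lr=3e-3, steps=40)
    frs.append(folding_ratio(u))
    warped = warp(pair.moving.labels, u, mode="nearest")
    dices.append(np.mean(list(dice_per_structure(warped,
                                                 pair.fixed.labels).values())))

print(f"after training + refinement: held-out Dice {np.mean(dices):.3f}, "
      f"FR {np.mean(frs):.2f}%")
print(f"Dice improvement over pre-registration: {np.mean(dices) - pre_dice:+.3f}")
# the held-out Dice rises well above its pre-registration value while the
# folding ratio stays at 0: the recovered fields align the anatomy without
# orientation-reversing (folded) voxels
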