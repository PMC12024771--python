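# wavemorph

Unsupervised deformable registration of 3D medical images with **lossless
wavelet downsampling** and **dynamic upsampling**, on a pure-NumPy
differentiable core.

## The problem

Deformable (non-rigid) registration estimates a dense displacement field
u: Ω → ℝ³ that aligns a moving volume *m* to a fixed volume *f* voxel by
voxel, via the deformation φ(p) = p + u(p). Unsupervised networks learn this
mapping without ground-truth fields by minimizing

```
L = L_sim(f, m∘φ) + λ · L_reg(u)
```

where `L_sim` is an intensity similarity (MSE, or windowed normalized
cross-correlation for robustness to intensity shifts), `L_reg` is diffusion
regularization (mean squared spatial gradient of u), and `m∘φ` is computed
by a differentiable spatial transformer (trilinear warping).

Conventional encoder–decoders lose high-frequency anatomy (thin boundaries,
small structures) in pooling and fixed-rule interpolation. This package's
network replaces both resampling operators:

* **Down**: an orthonormal 3D Haar DWT splits each feature map losslessly
  into 8 half-resolution subbands (LLL…HHH); each subband family is enhanced
  by ConvNeXt blocks with kernels matched to its frequency content (7³ for
  LLL, 3³ for HHH, parallel 1/3/5 for the six mixed bands), fused by
  pointwise convolution and a cross-dimension attention gate. Skip features
  are the inverse transform (IDWT) of the enhanced subbands.
* **Up**: a dynamic upsampler perturbs the trilinear ×2 sampling grid with
  learned per-group offsets (<1k extra parameters across the decoder),
  recovering detail a fixed interpolation rule cannot.

Registration quality is evaluated by per-structure Dice overlap
(2|X∩Y|/(|X|+|Y|), summarized per pair, then across pairs) and the folding
ratio — the percentage of voxels with non-positive Jacobian determinant
det(I + ∇u), i.e. locally orientation-reversing deformations.

Max-pooling / patch-merging / plain-Haar downsamplers and nearest /
trilinear upsamplers are available as drop-in ablation alternatives.

**Who it is for:** researchers who want a fully inspectable, CPU-runnable
implementation of wavelet-based registration with a first-class synthetic
test bed — every component, from the DWT to the training loop, is plain
NumPy and unit-tested against independent oracles (PyWavelets, scipy).

## Worked example

```python
import numpy as np
from wavemorph import LossConfig, make_pair, folding_ratio, warp
from wavemorph.metrics import dice_per_structure
from wavemorph.network import WaveMorph
from wavemorph.pipeline import RunConfig, _eval_pairs, instance_refine, train

loss = LossConfig(similarity="ncc", lam=1.0, ncc_window=5)
train_pairs = [make_pair(s, (24, 24, 24)) for s in range(4)]
val_pairs   = [make_pair(100 + s, (24, 24, 24)) for s in range(2)]

pre_dice, _ = _eval_pairs(WaveMorph(seed=0), val_pairs)
cfg = RunConfig(loss=loss, lr=3e-3, epochs=30, seed=0, flip_augment=0.0)
result = train(cfg, train_pairs)

dices, frs = [], []
for pair in val_pairs:  # label-free per-pair refinement of the trained model
    u = instance_refine(result["model"], pair.moving.intensity,
                        pair.fixed.intensity, loss, lr=3e-3, steps=40)
    frs.append(folding_ratio(u))
    warped = warp(pair.moving.labels, u, mode="nearest")
    dices.append(np.mean(list(dice_per_structure(warped, pair.fixed.labels).values())))
print(f"held-out Dice {pre_dice:.3f} -> {np.mean(dices):.3f}, FR {np.mean(frs):.2f}%")
```

Output (a few minutes on one CPU; `examples/03_train_miniature.py` is this
script):

```
held-out Dice 0.849 -> 0.975, FR 0.00%
```

meaning the untrained model (whose zero-initialized head predicts the
identity transform) leaves the held-out pairs at their pre-registration
overlap of 0.849, while amortized training plus a short unsupervised
per-pair refinement warps the moving labels to 0.975 mean Dice with a
topology-preserving field (no folded voxels).

The `examples/` directory holds one narrative script per capability:
wavelet decomposition, synthetic pairs, miniature training, deformation
metrics, and the sampler ablation grid. A thin CLI mirrors the pipeline:

```bash
wavemorph synth --seed 0 --shape 24 --out data/pair0
wavemorph train --data data --out runs/demo
wavemorph register runs/demo/checkpoint_best.npz m.nii.gz f.nii.gz --out out/
wavemorph evaluate runs/demo/checkpoint_best.npz --data data --out report/
```

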