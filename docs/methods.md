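# Methods

## Problem and model

WaveMorph performs unsupervised deformable registration of pre-affine-aligned
single-channel 3D volumes. Given a moving image *m* and a fixed image *f* on a
voxel domain Ω, the network predicts a dense displacement field
u: Ω → ℝ³ (voxel units, array-axis order), defining the deformation
φ(p) = p + u(p). Training minimizes

    L = L_sim(f, m∘φ) + λ · L_reg(u)

with no ground-truth fields: the spatial transformer (trilinear resampling of
*m* at the deformed positions) makes the warp differentiable, so the
similarity gradient reaches the network.

The architecture is a four-stage U-Net-style encoder–decoder whose
resampling operators are the contribution:

* **Downsampling (MSWF).** Each encoder stage applies an orthonormal 3D Haar
  DWT, splitting the feature map losslessly into 8 half-resolution subbands.
  Subbands are enhanced by ConvNeXt blocks with kernel sizes matched to their
  content — 7³ for the pure low-pass LLL (global structure), 3³ for the pure
  high-pass HHH (fine detail), and parallel 1/3/5 kernels, fused per subband,
  for the six mixed subbands — then concatenated, compressed by a pointwise
  convolution, and gated by a four-branch cross-dimension attention layer
  (CDA). Unlike pooling, no information is discarded before the network can
  weigh it.
* **Skip connections.** Each stage's enhanced subband stack is inverse-
  transformed (IDWT) back to full resolution and used as the skip feature
  (`skip_mode="reuse"`, the default); a `dedicated` mode runs a separate
  resolution-preserving MSWF pass instead. Skips enter the decoder scaled by
  a learnable scalar (init 1.0 — a plain skip at the start).
* **Bottleneck.** Two resolution-preserving MSWF blocks (DWT → enhancement →
  IDWT → pointwise → CDA → kernel-7 ConvNeXt), maximizing receptive field at
  1/16 resolution without further loss.
* **Upsampling (DySample-style).** A zero-initialized pointwise projection of
  a 4-channel slice of the decoder feature produces, per offset group, a
  3-vector offset for each ×2 sub-position. Offsets (scaled by
  scope · 0.5 = 0.125 voxels) perturb the fixed trilinear ×2 grid and each
  channel group is resampled at its own grid. At initialization the layer is
  exactly trilinear ×2 upsampling.
* **Head.** A zero-initialized 3³ convolution emits u, so an untrained model
  is exactly the identity transform — training starts from "do nothing".

The orthonormal Haar convention (taps ±1/√2) is used for both analysis and
synthesis, giving Parseval energy conservation and exact invertibility;
inputs to the transform must have even extents (no implicit padding). The
full network requires extents divisible by 32 in its default configuration:
16 from the four ×2 downsamplings, ×2 more because the wavelet bottleneck
transforms the 1/16-resolution map, which must itself be even (the
ablation bottleneck without wavelets needs only 16;
`WaveMorph.required_multiple` reports the active constraint). The
training/inference pipeline edge-pads other sizes and crops the predicted
field back.

### CDA internals

The attention layer is defined here (the name fixes only "four-branch,
cross-channel interactive"): three branches transpose the channel axis with
one spatial axis each, pool over the rotated-out axis, form a sigmoid gate
from a 3³ convolution of the pooled map, and gate the rotated view; a fourth
branch gates on channel-pooled statistics directly. The four gated views are
averaged, so the output never exceeds the input in magnitude.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `stem_channels` | 8 | channels after the 3³ stem on the 2-channel (m,f) stack |
| `stage_channels` | (12, 16, 24, 32) | encoder widths; bottleneck at 1/16 resolution |
| `convnext_expansion` | 2 | pointwise expansion ratio in ConvNeXt blocks |
| `decoder_kernels` | (7, 7, 3, 3) | ConvNeXt kernels per decoder stage, coarse→fine |
| `dysample_groups` | 2 | offset groups in the dynamic upsampler |
| `dysample_scope` | 0.25 | offset range factor (×0.5 voxel) |
| `skipscale_init` | 1.0 | initial skip-connection scale |
| loss (atlas-style) | NCC, window 9³, λ=1 | + tri-axis flip augmentation p=0.5 |
| loss (inter-patient-style) | MSE, λ=0.02 | no spatial augmentation |
| optimizer | Adam, lr 1e-4, batch 1 | the full-scale training recipe |

Channel widths are budget-calibrated, not taken from any reference: with the
per-subband (grouped) mixed-branch convolutions they put the default model at
≈ 0.44 M trainable parameters — under the 1 M class of lightweight
registration CNNs — and the dynamic upsampler's offset projections at
768 parameters total (4 input channels × 24 offset channels × 2 groups ×
4 stages), under the 1 k budget such upsamplers advertise. Wider profiles are
a config edit; nothing in the code assumes these widths.

The mixed-subband fusion is residual (raw subbands + grouped pointwise of
the three branch outputs), so zero-initialized or ablated branches leave the
decomposition untouched rather than destroying it.

## Losses and metrics

* **MSE**: mean squared voxel difference.
* **Windowed NCC**: per-voxel normalized cross-correlation over n³ windows
  (default n=9), averaged over voxels; returned negated so −1 is a perfect
  match. Window sums use a zero-padded box filter; border windows use their
  shrunken in-domain support. Both images are centred by their global means
  first (changes no window's NCC; avoids float32 cancellation). Windows with
  vanishing variance contribute 0 via an ε=1e-5 stabilizer inside the
  denominator square root — constant regions never produce NaNs.
* **Diffusion regularizer**: squared forward differences of u, averaged per
  direction over the valid stencil and the three components, summed over
  directions. Exactly 0 on constant fields.
* **Dice**: 2|X∩Y|/(|X|+|Y|) per structure; hierarchical summary = per-pair
  mean over structures, then mean ± sd over pairs. Empty-vs-empty is 1,
  empty-vs-nonempty 0.
* **Jacobian / folding ratio**: J_φ = det(I + ∇u) with central differences on
  interior voxels (boundary excluded); FR = % of evaluated voxels with
  J ≤ 0. The ≤ (rather than <) follows the convention that exactly-zero
  determinants are degenerate.

## Synthetic study conditions

The generator emulates pre-aligned, skull-stripped brain volumes at desk
scale:

* **Phantoms**: concentric smoothed ellipsoids (randomized centre and axes),
  labels 1..n nested inside each other with shells ≈ 2 voxels thick at
  24–48 voxel extents — thin enough that per-structure Dice responds to
  voxel-scale misalignment, as cortical-ribbon-like structures do. Per-label
  intensity means are spaced ≥ 0.1; additive Gaussian noise σ = 0.02;
  intensities clipped to [0,1].
* **Fields**: Gaussian-smoothed white noise (σ = 8 voxels by default),
  max-normalized so the largest displacement magnitude equals the requested
  amplitude. With max-norm scaling, the smoothness sets how much of the
  volume moves: σ = 8 gives typical displacements ≈ 1 voxel at amplitude 2
  on 24³ grids and pre-registration Dice ≈ 0.7–0.8, comparable to
  affine-only baselines on real brains; σ = 4 would leave most displacements
  sub-voxel and the labels nearly static. Fields are verified fold-free
  (FR = 0) at generation; amplitude ≤ σ/2 always is.
* **Pairs**: fixed = warp(moving, gt_field) + independent noise, labels
  nearest-warped without noise, so gt_field is the *exact* generator of the
  pair's geometry.

What passing on phantoms does and does not show: it validates the whole
mechanism (lossless downsampling, differentiable warping, loss gradients,
topology preservation) under known ground truth, but phantoms lack real
MR texture, bias fields, multi-subject anatomical variability and
partial-volume effects, so phantom Dice does not predict clinical Dice.

## Miniature recovery protocol

The end-to-end check trains on 8 synthetic pairs (24³, amplitude 2) and
evaluates on 4 held-out pairs, with NCC + diffusion at λ = 1 throughout.
Desk-scale protocol choices, fixed once:

* **NCC window 5** — the geometric scale-down of 9³ windows on 160–224-voxel
  brains; at 24³ a 9³ window spans 40% of each axis and stops responding to
  the thin structures it is supposed to align.
* **Amortize, then optimize.** The network is first trained across the
  8 pairs (lr 3e-3, no flips, 60 epochs = 480 Adam steps), then each
  held-out pair gets a short unsupervised instance refinement
  (`instance_refine`, 100 Adam steps, same loss, labels never touched) —
  the standard two-stage protocol of learning-based registration, where
  the amortized network supplies the prior and warm start and a brief
  per-pair optimization closes the remaining gap. Total ≈ 880 Adam steps.
* Labels are used only for evaluation: pre- vs post-registration held-out
  hierarchical Dice and folding ratio of the refined fields.

Success is a held-out hierarchical Dice ≥ 0.10 above the pre-registration
Dice of the same pairs, with held-out folding ratio ≤ 2%.

Eight training pairs are too few for the amortized network alone to
generalize to unseen geometry (it plateaus near the pre-registration Dice,
and flip augmentation at this data scale collapses predictions toward the
identity); the instance-refinement stage is what closes the gap, exactly as
instance-specific optimization does for amortized models on real data.
This is recorded under limitations.

## Numerical choices and degenerate inputs

* float32 arrays throughout; window sums in float64 inside the box filter.
* Out-of-domain sampling clamps to the border (no zero halo in losses); the
  clamp has zero gradient outside the domain.
* Odd extents at a wavelet stage raise (never silently pad); unknown sampler
  kinds, even kernels, non-dividing group counts raise config errors.
* Nearest-mode warping is used for label maps and cannot invent label values.
* Training aborts with a diagnostic naming the offending term if the
  similarity or regularizer goes non-finite.
* Determinism: all randomness flows from explicit seeds; single-device
  reruns are bit-identical.

## Known limitations

* No diffeomorphic integration layer: smoothness is encouraged by the
  regularizer, not guaranteed; FR can exceed 0 for weakly regularized runs.
* The autodiff core is CPU-only and sized to sub-million-parameter models;
  full-resolution (160×192×224) training is expressible but not practical on
  one CPU.
* Single-level wavelet decomposition per stage; other wavelet bases are out
  of scope.
* The CDA design is one concrete reading of a published name; alternatives
  (e.g. channel–spatial excitation variants) would be drop-in replacements.
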