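"""Synthetic brain-like phantoms and ground-truth deformations.

The generator produces the study conditions for desk-scale experiments:
multi-label phantoms of concentric smoothed ellipsoids (a stand-in for
pre-aligned, skull-stripped T1 volumes), smooth topology-preserving
displacement fields (folding ratio exactly 0), and moving/fixed training
pairs in which the fixed image is the moving image warped by a known field
plus independent Gaussian noise — so recovery experiments can compare a
predicted field against the exact generator of the pair's geometry.

Everything is deterministic under its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .metrics import folding_ratio
from .warp import warp

INTENSITY_NOISE_SD = 0.02  # additive Gaussian noise on phantom intensities


@dataclass
class Phantom:
    """Intensity volume in [0,1] plus a nested integer label map."""

    intensity: np.ndarray
    labels: np.ndarray
    seed: int


@dataclass
class SynthPair:
    """A registration pair with its exact generating displacement field."""

    moving: Phantom
    fixed: Phantom
    gt_field: np.ndarray


def _check_shape(shape):
    # even extents keep the volumes wavelet-friendly; the training pipeline
    # pads to the network's /16 requirement itself
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s % 2 for s in shape) or any(s < 8 for s in shape):
        raise ValueError(f"phantom shape must be 3D with even extents >= 8, "
                         f"got {shape}")
    return shape


def make_phantom(seed: int, shape=(32, 32, 32), n_labels: int = 3) -> Phantom:
    """Concentric smoothed-ellipsoid phantom with ``n_labels`` nested
    structures (labels 1..n_labels, 0 = background).

    Per-label mean intensities are spaced at least 0.1 apart; additive
    Gaussian noise has sigma 0.02; intensities are clipped to [0,1].
    """
    shape = _check_shape(shape)
    if n_labels < 2:
        raise ValueError(f"need at least 2 labels, got {n_labels}")
    rng = np.random.default_rng(seed)
    h, w, d = shape
    centre = np.array(shape) / 2.0 + rng.uniform(-1.5, 1.5, size=3)
    outer = np.array(shape) * 0.38 * rng.uniform(0.85, 1.0, size=3)
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                                indexing="ij"))
    labels = np.zeros(shape, dtype=np.int16)
    for k in range(n_labels):
        # strictly nested: common centre, per-axis radii shrinking with k;
        # the spacing keeps each shell ~2 voxels thick at 24-48 voxel extents
        # so per-structure Dice is sensitive to voxel-scale misalignment
        frac = 1.0 - 0.45 * k / n_labels
        axes = outer * frac * rng.uniform(0.92, 1.0, size=3)
        r2 = sum(((grid[a] - centre[a]) / axes[a]) ** 2 for a in range(3))
        labels[r2 <= 1.0] = k + 1
    spacing = 0.8 / n_labels if n_labels <= 8 else 0.1
    levels = 0.1 + spacing * np.arange(n_labels + 1)
    intensity = levels[labels]
    intensity = ndimage.gaussian_filter(intensity, sigma=0.6)
    intensity += rng.normal(0.0, INTENSITY_NOISE_SD, size=shape)
    intensity = np.clip(intensity, 0.0, 1.0).astype(np.float32)
    return Phantom(intensity=intensity, labels=labels, seed=seed)


def make_smooth_field(seed: int, shape=(32, 32, 32), amplitude: float = 2.0,
                      smoothness: float = 8.0, max_attempts: int = 5) -> np.ndarray:
    """Smooth random displacement field with max vector norm = amplitude.

    White noise is Gaussian-smoothed (kernel sigma = ``smoothness`` voxels)
    and rescaled so the largest per-voxel displacement magnitude equals
    ``amplitude``.  The result is checked to be topology-preserving
    (folding ratio 0); amplitudes up to about smoothness/2 always are.  A
    folded draw is regenerated with a warning, up to ``max_attempts`` times.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if smoothness < 1:
        raise ValueError("smoothness (Gaussian sigma) must be >= 1 voxel")
    shape = tuple(int(s) for s in shape)
    if amplitude == 0:
        return np.zeros((3,) + shape, dtype=np.float32)
    rng = np.random.default_rng(seed)
    for attempt in range(max_attempts):
        noise = rng.standard_normal(size=(3,) + shape)
        u = np.stack([ndimage.gaussian_filter(noise[c], sigma=smoothness)
                      for c in range(3)])
        mag = np.sqrt((u ** 2).sum(axis=0)).max()
        u = (u * (amplitude / mag)).astype(np.float32)
        if folding_ratio(u) == 0.0:
            return u
        warnings.warn(f"generated field folded (attempt {attempt + 1}); "
                      "regenerating", stacklevel=2)
    raise RuntimeError(
        f"could not generate a fold-free field after {max_attempts} attempts "
        f"(amplitude={amplitude}, smoothness={smoothness})")


def make_pair(seed: int, shape=(32, 32, 32), n_labels: int = 3,
              amplitude: float = 2.0, smoothness: float = 8.0) -> SynthPair:
    """Moving/fixed pair: fixed = warp(moving, gt_field) + independent noise.

    Noise is added after warping, so ``gt_field`` is the exact generator of
    the pair's geometry and ``warp(moving.labels, gt_field)`` (nearest mode)
    equals ``fixed.labels`` identically.
    """
    shape = _check_shape(shape)
    moving = make_phantom(seed, shape, n_labels)
    gt = make_smooth_field(seed + 10007, shape, amplitude, smoothness)
    rng = np.random.default_rng(seed + 20011)
    fixed_int = warp(moving.intensity, gt, mode="trilinear")
    fixed_int = np.clip(fixed_int + rng.normal(0.0, INTENSITY_NOISE_SD,
                                               size=shape), 0.0, 1.0)
    fixed_lab = warp(moving.labels, gt, mode="nearest")
    fixed = Phantom(intensity=fixed_int.astype(np.float32),
                    labels=fixed_lab.astype(np.int16), seed=seed)
    return SynthPair(moving=moving, fixed=fixed, gt_field=gt)
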