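"""Differentiable spatial transformation of volumes by displacement fields.

A displacement field ``u`` holds per-voxel 3-vectors in voxel units along
array-index axes; the deformation is ``phi(p) = p + u(p)``.  Warping
resamples the moving volume at the deformed positions by trilinear
interpolation of the eight neighbouring voxels (or nearest-neighbour for
label maps); positions outside the domain are clamped to the border, which
avoids zero-halo artefacts in similarity losses at volume edges.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, grid_sample3


def identity_grid(shape) -> np.ndarray:
    """Identity sampling grid (3,H,W,D): component c at (i,j,k) is that
    voxel's c-th index as an exact float."""
    if any(int(s) <= 0 for s in shape):
        raise ValueError(f"grid shape must be positive, got {tuple(shape)}")
    h, w, d = (int(s) for s in shape)
    grid = np.empty((3, h, w, d), dtype=np.float32)
    grid[0] = np.arange(h, dtype=np.float32).reshape(h, 1, 1)
    grid[1] = np.arange(w, dtype=np.float32).reshape(1, w, 1)
    grid[2] = np.arange(d, dtype=np.float32).reshape(1, 1, d)
    return grid


def warp_tensor(m: Tensor, u: Tensor, mode: str = "trilinear") -> Tensor:
    """Warp (N,C,H,W,D) tensor `m` by (N,3,H,W,D) displacement `u`,
    differentiably in both arguments (trilinear mode)."""
    if m.shape[2:] != u.shape[2:] or u.shape[1] != 3:
        raise ValueError(f"volume {m.shape} and field {u.shape} do not agree")
    grid = Tensor(identity_grid(m.shape[2:])[None])
    coords = grid + u
    return grid_sample3(m, coords, mode=mode)


def warp(m: np.ndarray, u: np.ndarray, mode: str = "trilinear") -> np.ndarray:
    """Warp a (H,W,D) or (C,H,W,D) numpy volume by a (3,H,W,D) field.

    ``mode='trilinear'`` for images, ``'nearest'`` for label maps (output
    values are then a subset of the input's).
    """
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    arr = np.asarray(m)
    single = arr.ndim == 3
    vol = arr[None] if single else arr
    u = np.asarray(u, dtype=np.float32)
    if u.shape != (3,) + vol.shape[1:]:
        raise ValueError(f"field shape {u.shape} does not match volume "
                         f"spatial shape {vol.shape[1:]}")
    with ad.no_grad():
        out = grid_sample3(Tensor(vol.astype(np.float32)[None]),
                           identity_grid(vol.shape[1:])[None] + u[None],
                           mode=mode).data[0]
    if np.issubdtype(arr.dtype, np.integer) and mode == "nearest":
        out = np.rint(out).astype(arr.dtype)
    return out[0] if single else out
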