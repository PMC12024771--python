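"""Unsupervised registration losses.

The training objective is ``L = L_sim(f, m o phi) + lambda * L_reg(u)``:
an intensity similarity between the fixed image and the warped moving
image, plus diffusion regularization that penalizes rough displacement
fields.  Similarity is either mean squared error (aligned intensity
profiles) or windowed normalized cross-correlation (robust to affine
intensity differences; window 9^3 by default).

All losses accept either plain numpy arrays (returning floats) or autodiff
tensors shaped (N,C,H,W,D)/(N,3,H,W,D) (returning scalar tensors for
backpropagation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, boxsum, clip_min, sqrt
from .warp import warp_tensor


@dataclass
class LossConfig:
    """similarity: 'ncc' (windowed NCC, default for atlas-style runs with
    lam=1) or 'mse' (inter-patient-style runs with lam=0.02);
    ncc_window: odd window edge n (windows of n^3 voxels);
    epsilon: stabilizer inside the NCC denominator square root."""

    similarity: str = "ncc"
    lam: float = 1.0
    ncc_window: int = 9
    epsilon: float = 1e-5

    def __post_init__(self):
        if self.similarity not in ("mse", "ncc"):
            raise ValueError(f"unknown similarity {self.similarity!r}")
        if self.ncc_window % 2 == 0 or self.ncc_window < 3:
            raise ValueError(f"ncc_window must be odd and >= 3, "
                             f"got {self.ncc_window}")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")

    def to_dict(self) -> dict:
        return {"similarity": self.similarity, "lam": self.lam,
                "ncc_window": self.ncc_window, "epsilon": self.epsilon}

    @classmethod
    def from_dict(cls, d: dict) -> "LossConfig":
        return cls(**d)


def _as5d(x) -> tuple[Tensor, bool]:
    """Lift numpy (H,W,D) / (C,H,W,D) input to an (N,C,H,W,D) tensor."""
    if isinstance(x, Tensor):
        return x, False
    a = np.asarray(x, dtype=np.float32)
    if a.ndim == 3:
        a = a[None, None]
    elif a.ndim == 4:
        a = a[None]
    return Tensor(a), True


def mse_loss(f, w):
    """Mean of squared voxel differences over the domain."""
    ft, was_np = _as5d(f)
    wt, _ = _as5d(w)
    if ft.shape != wt.shape:
        raise ValueError(f"shape mismatch: {ft.shape} vs {wt.shape}")
    d = ft - wt
    out = (d * d).mean()
    return out.item() if was_np else out


def lncc_loss(f, w, n: int = 9, epsilon: float = 1e-5):
    """Negative mean windowed normalized cross-correlation.

    Per-voxel NCC is computed over n^3 windows centred on each voxel
    (border windows use their shrunken in-domain support), then averaged
    over the domain; the value returned is the negative of that mean, so a
    perfect match gives -1.  Windows with vanishing variance contribute a
    correlation of 0.
    """
    if n % 2 == 0:
        raise ValueError(f"window size must be odd, got {n}")
    ft, was_np = _as5d(f)
    wt, _ = _as5d(w)
    if ft.shape != wt.shape:
        raise ValueError(f"shape mismatch: {ft.shape} vs {wt.shape}")
    # centring by the global means changes no window's NCC but avoids
    # float32 cancellation in the sum-of-squares terms
    ft = ft - float(ft.data.mean())
    wt = wt - float(wt.data.mean())
    ones = np.ones(ft.shape, dtype=np.float32)
    cnt = boxsum(Tensor(ones), n).data  # effective window sizes at borders
    sf = boxsum(ft, n)
    sw = boxsum(wt, n)
    sff = boxsum(ft * ft, n)
    sww = boxsum(wt * wt, n)
    sfw = boxsum(ft * wt, n)
    inv = Tensor(1.0 / cnt)
    cross = sfw - sf * sw * inv
    vf = clip_min(sff - sf * sf * inv, 0.0)
    vw = clip_min(sww - sw * sw * inv, 0.0)
    ncc = cross / sqrt(vf * vw + epsilon)
    out = -ncc.mean()
    return out.item() if was_np else out


def diffusion_reg(u):
    """Mean squared forward-difference gradient of the displacement field.

    For each spatial direction the squared forward differences are averaged
    over the valid stencil and the three vector components; the three
    direction terms are summed.  Exactly zero for constant fields and
    quadratically homogeneous in u.
    """
    ut, was_np = _as5d(u)
    total = None
    nd = ut.ndim
    for ax in (nd - 3, nd - 2, nd - 1):
        hi = [slice(None)] * nd
        lo = [slice(None)] * nd
        hi[ax] = slice(1, None)
        lo[ax] = slice(None, -1)
        d = ut[tuple(hi)] - ut[tuple(lo)]
        term = (d * d).mean()
        total = term if total is None else total + term
    return total.item() if was_np else total


def total_loss(f, m, u, cfg: LossConfig):
    """Similarity of f vs warp(m, u) plus lambda-weighted diffusion term.

    Returns ``(loss, sim, reg)``; all three are tensors when the inputs are
    tensors, floats otherwise.
    """
    ft, was_np = _as5d(f)
    mt, _ = _as5d(m)
    ut, _ = _as5d(u) if not isinstance(u, Tensor) else (u, False)
    warped = warp_tensor(mt, ut)
    if cfg.similarity == "mse":
        sim = mse_loss(ft, warped)
    else:
        sim = lncc_loss(ft, warped, cfg.ncc_window, cfg.epsilon)
    reg = diffusion_reg(ut)
    loss = sim + cfg.lam * reg
    if was_np:
        return loss.item(), sim.item(), reg.item()
    return loss, sim, reg
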