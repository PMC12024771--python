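"""Orthonormal 3D Haar wavelet analysis and synthesis.

The transform uses the orthonormal convention: the low-pass filter is
``(s, s)`` and the high-pass filter ``(s, -s)`` with ``s = 1/sqrt(2)``, so
analysis and synthesis share the same coefficients, the transform is an
isometry (Parseval), and ``idwt3(dwt3(x)) == x`` to float precision.
Subbands are named by the filter applied along each array axis in order,
``LLL`` through ``HHH``; each has half the input's extent per axis.

Inputs are processed in non-overlapping 2x2x2 blocks, so every spatial
dimension must be even; odd dimensions are rejected rather than padded.

Exposed both as pure NumPy functions (`dwt3`/`idwt3` on a `SubbandSet`) and
as differentiable layers (`DWT3`/`IDWT3`) that stack the eight subbands
along the channel axis for use inside the network.  The layers hold no
trainable state: the filter bank is frozen, but gradients flow through it
(the backward pass is the adjoint transform, which for an orthonormal bank
is the inverse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff
from .autodiff import Tensor, _haar_merge, _haar_split
from .nn import Module

SUBBAND_KEYS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

_S = 1.0 / math.sqrt(2.0)


@dataclass(frozen=True)
class HaarFilterBank:
    """The 2-tap orthonormal Haar pair and its eight separable 3D filters."""

    low: np.ndarray = field(default_factory=lambda: np.array([_S, _S]))
    high: np.ndarray = field(default_factory=lambda: np.array([_S, -_S]))

    def filters(self) -> dict[str, np.ndarray]:
        taps = {"L": self.low, "H": self.high}
        return {key: np.einsum("i,j,k->ijk", taps[key[0]], taps[key[1]], taps[key[2]])
                for key in SUBBAND_KEYS}


class SubbandSet(dict):
    """Mapping of the eight Haar subbands, keyed ``LLL`` ... ``HHH``.

    All members must share one shape; for even-sized inputs the total
    element count equals the input's (the decomposition is a lossless
    repacking).
    """

    def __init__(self, mapping):
        super().__init__()
        missing = [k for k in SUBBAND_KEYS if k not in mapping]
        if missing:
            raise KeyError(f"missing subband(s): {missing}")
        shape = np.asarray(mapping[SUBBAND_KEYS[0]]).shape
        for key in SUBBAND_KEYS:
            arr = np.asarray(mapping[key])
            if arr.shape != shape:
                raise ValueError(
                    f"subband {key!r} has shape {arr.shape}, expected {shape}")
            self[key] = arr

    @property
    def shape(self):
        return self["LLL"].shape


def _check_even(shape, what="input"):
    names = ("H", "W", "D")
    for name, dim in zip(names, shape[-3:]):
        if dim % 2:
            raise ValueError(
                f"{what} has odd size {dim} along spatial axis {name}; "
                "the Haar transform requires even extents (no implicit padding)")


def dwt3(volume: np.ndarray) -> SubbandSet:
    """Single-level orthonormal Haar DWT of a (C,H,W,D) or (H,W,D) volume."""
    x = np.asarray(volume, dtype=np.float32)
    if x.ndim not in (3, 4):
        raise ValueError(f"expected 3D or 4D array, got {x.ndim}D")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    _check_even(x.shape)
    parts = _haar_split(x)
    return SubbandSet(dict(zip(SUBBAND_KEYS, parts)))


def idwt3(subbands: SubbandSet | dict) -> np.ndarray:
    """Exact inverse of `dwt3`; output extents are double the subbands'."""
    if not isinstance(subbands, SubbandSet):
        subbands = SubbandSet(subbands)
    parts = [np.asarray(subbands[k], dtype=np.float32) for k in SUBBAND_KEYS]
    return _haar_merge(parts)


class DWT3(Module):
    """Differentiable DWT layer: (N,C,H,W,D) -> (N,8C,H/2,W/2,D/2)."""

    def forward(self, x: Tensor) -> Tensor:
        _check_even(x.shape, "feature map")
        return autodiff.haar_dwt3(x)


class IDWT3(Module):
    """Differentiable IDWT layer: (N,8C,h,w,d) -> (N,C,2h,2w,2d)."""

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] % 8:
            raise ValueError(
                f"channel count {x.shape[1]} is not divisible by 8 subbands")
        return autodiff.haar_idwt3(x)
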