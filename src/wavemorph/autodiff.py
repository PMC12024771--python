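"""Reverse-mode automatic differentiation over NumPy arrays.

A compact tape-based tensor core sized to the sub-million-parameter 3D
registration models in this package: dense float32 arrays, a handful of
structural ops (arithmetic, reductions, slicing, reshaping, concatenation),
and the domain primitives the network needs — grouped strided 3D
convolution, orthonormal Haar (I)DWT, trilinear grid sampling, 2x max
pooling, and a zero-padded box-sum filter.  Each primitive implements an
explicit adjoint; gradients are accumulated by topological traversal of the
recorded graph.

Conventions: feature maps are ``(N, C, H, W, D)``; all data is float32;
graphs are built only while gradient recording is enabled (see `no_grad`).
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np
from scipy import ndimage
from scipy.special import erf, expit

_GRAD_ENABLED = True

_ISQ2 = np.float32(1.0 / math.sqrt(2.0))


@contextmanager
def no_grad():
    """Context manager that suspends graph recording."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (the adjoint of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A float32 array plus an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = ()
        self._backward = None

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ---------------------------------------------------------
    def backward(self, grad=None, free_graph: bool = True):
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for p, g in zip(node._parents, grads):
                if g is None or not p.requires_grad:
                    continue
                p.grad = g if p.grad is None else p.grad + g
            if free_graph:
                node._backward = None
                node._parents = ()
                if node is not self:
                    node.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, Tensor):
            return _op(self.data + other.data, (self, other),
                       lambda g: (_unbroadcast(g, self.shape),
                                  _unbroadcast(g, other.shape)))
        return _op(self.data + other, (self,),
                   lambda g: (_unbroadcast(g, self.shape),))

    __radd__ = __add__

    def __neg__(self):
        return _op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -other)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, Tensor):
            a, b = self.data, other.data
            return _op(a * b, (self, other),
                       lambda g: (_unbroadcast(g * b, self.shape),
                                  _unbroadcast(g * a, other.shape)))
        return _op(self.data * other, (self,),
                   lambda g: (_unbroadcast(g * other, self.shape),))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            a, b = self.data, other.data
            return _op(a / b, (self, other),
                       lambda g: (_unbroadcast(g / b, self.shape),
                                  _unbroadcast(-g * a / (b * b), other.shape)))
        return self * (1.0 / other)

    def __rtruediv__(self, other):
        a = self.data
        return _op(other / a, (self,),
                   lambda g: (_unbroadcast(-g * other / (a * a), self.shape),))

    def __pow__(self, p):
        a = self.data
        return _op(a ** p, (self,),
                   lambda g: (g * p * a ** (p - 1),))

    # -- reductions / structure -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).astype(np.float32),)
            gg = g
            if not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(a % self.ndim for a in ax)
                gg = np.expand_dims(g, ax)
            return (np.broadcast_to(gg, self.shape).astype(np.float32),)

        return _op(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a % self.ndim] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return _op(self.data.reshape(shape), (self,),
                   lambda g: (g.reshape(old),))

    def transpose(self, axes):
        inv = tuple(np.argsort(axes))
        return _op(self.data.transpose(axes), (self,),
                   lambda g: (g.transpose(inv),))

    def swapaxes(self, a, b):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(tuple(axes))

    def __getitem__(self, idx):
        def bwd(g):
            out = np.zeros(self.shape, dtype=np.float32)
            out[idx] += g
            return (out,)

        return _op(self.data[idx], (self,), bwd)


def _op(data, parents, bwd):
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = bwd
    return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return _op(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


# -- pointwise nonlinearities ---------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    y = expit(x.data).astype(np.float32)
    return _op(y, (x,), lambda g: (g * y * (1.0 - y),))


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error-function GELU."""
    a = x.data
    phi = 0.5 * (1.0 + erf(a / math.sqrt(2.0)))
    y = (a * phi).astype(np.float32)
    dens = np.exp(-0.5 * a * a) / math.sqrt(2.0 * math.pi)
    return _op(y, (x,), lambda g: ((g * (phi + a * dens)).astype(np.float32),))


def sqrt(x: Tensor) -> Tensor:
    y = np.sqrt(x.data)
    return _op(y, (x,), lambda g: (g * 0.5 / y,))


def clip_min(x: Tensor, lo: float) -> Tensor:
    mask = x.data > lo
    return _op(np.maximum(x.data, lo), (x,), lambda g: (g * mask,))


# -- 3D convolution --------------------------------------------------------

def _conv3d_fwd(x, w, stride, pad, groups):
    n, c, _, _, _ = x.shape
    o, cg, k, _, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad,) * 2, (pad,) * 2, (pad,) * 2)) if pad else x
    hp, wp, dp = xp.shape[2:]
    s = stride
    ho, wo, do = (hp - k) // s + 1, (wp - k) // s + 1, (dp - k) // s + 1
    out = np.zeros((n, o, ho, wo, do), dtype=np.float32)
    og = o // groups
    depthwise = groups == c and cg == 1 and og == 1
    flat = out.reshape(n, groups, og, ho * wo * do)
    for dx in range(k):
        for dy in range(k):
            for dz in range(k):
                xs = xp[:, :, dx:dx + s * ho:s, dy:dy + s * wo:s, dz:dz + s * do:s]
                if depthwise:
                    out += xs * w[:, 0, dx, dy, dz].reshape(1, c, 1, 1, 1)
                else:
                    wg = w[:, :, dx, dy, dz].reshape(groups, og, cg)
                    xg = np.ascontiguousarray(xs).reshape(n, groups, cg, -1)
                    flat += np.matmul(wg, xg)
    return out


def _conv3d_bwd(x, w, grad, stride, pad, groups):
    n, c, _, _, _ = x.shape
    o, cg, k, _, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad,) * 2, (pad,) * 2, (pad,) * 2)) if pad else x
    s = stride
    _, _, ho, wo, do = grad.shape
    og = o // groups
    depthwise = groups == c and cg == 1 and og == 1
    gxp = np.zeros_like(xp)
    gw = np.zeros_like(w)
    gr = None if depthwise else grad.reshape(n, groups, og, -1)
    for dx in range(k):
        for dy in range(k):
            for dz in range(k):
                sl = (slice(None), slice(None),
                      slice(dx, dx + s * ho, s),
                      slice(dy, dy + s * wo, s),
                      slice(dz, dz + s * do, s))
                xs = xp[sl]
                if depthwise:
                    gw[:, 0, dx, dy, dz] = np.einsum("nchwd,nchwd->c", xs, grad)
                    gxp[sl] += grad * w[:, 0, dx, dy, dz].reshape(1, c, 1, 1, 1)
                else:
                    xg = np.ascontiguousarray(xs).reshape(n, groups, cg, -1)
                    gw[:, :, dx, dy, dz] = (
                        np.matmul(gr, xg.transpose(0, 1, 3, 2)).sum(axis=0)
                        .reshape(o, cg))
                    wg = w[:, :, dx, dy, dz].reshape(groups, og, cg)
                    gxp[sl] += np.matmul(wg.transpose(0, 2, 1), gr).reshape(xs.shape)
    if pad:
        gxp = gxp[:, :, pad:-pad, pad:-pad, pad:-pad]
    return gxp, gw


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped strided 3D convolution (cross-correlation) with cubic kernels."""
    out = _conv3d_fwd(x.data, w.data, stride, padding, groups)
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1, 1)

    xd, wd = x.data, w.data

    def bwd(g):
        gx, gw = _conv3d_bwd(xd, wd, g, stride, padding, groups)
        gb = g.sum(axis=(0, 2, 3, 4)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return _op(out, parents, bwd)


# -- orthonormal Haar transform --------------------------------------------

def _haar_split(x):
    """3-axis orthonormal Haar analysis into 8 arrays, L before H per axis."""
    parts = [x]
    for ax in (-3, -2, -1):
        nxt = []
        for p in parts:
            ev = np.take(p, range(0, p.shape[ax], 2), axis=ax)
            od = np.take(p, range(1, p.shape[ax], 2), axis=ax)
            nxt.append((ev + od) * _ISQ2)
            nxt.append((ev - od) * _ISQ2)
        parts = nxt
    return parts


def _haar_merge(parts):
    """Inverse of `_haar_split` (exact, by orthonormality)."""
    parts = list(parts)
    for ax in (-1, -2, -3):
        nxt = []
        for i in range(0, len(parts), 2):
            lo, hi = parts[i], parts[i + 1]
            ev = (lo + hi) * _ISQ2
            od = (lo - hi) * _ISQ2
            shape = list(lo.shape)
            shape[ax] *= 2
            out = np.empty(shape, dtype=np.float32)
            sl_ev = [slice(None)] * lo.ndim
            sl_od = [slice(None)] * lo.ndim
            sl_ev[ax] = slice(0, None, 2)
            sl_od[ax] = slice(1, None, 2)
            out[tuple(sl_ev)] = ev
            out[tuple(sl_od)] = od
            nxt.append(out)
        parts = nxt
    return parts[0]


def haar_dwt3(x: Tensor) -> Tensor:
    """DWT of (N,C,H,W,D) into (N,8C,H/2,W/2,D/2), subbands LLL..HHH stacked
    along channels.  Adjoint (= inverse, orthonormal basis) backward pass."""
    parts = _haar_split(x.data)
    out = np.concatenate(parts, axis=1)
    c = x.shape[1]

    def bwd(g):
        return (_haar_merge(np.split(g, 8, axis=1)),)

    del c
    return _op(out, (x,), bwd)


def haar_idwt3(y: Tensor) -> Tensor:
    """Inverse of `haar_dwt3` on a channel-stacked subband tensor."""
    parts = np.split(y.data, 8, axis=1)
    out = _haar_merge(parts)

    def bwd(g):
        return (np.concatenate(_haar_split(g), axis=1),)

    return _op(out, (y,), bwd)


# -- trilinear grid sampling -----------------------------------------------

def _gather(xn, i, j, k):
    return xn[:, i, j, k]


def grid_sample3(x: Tensor, coords: Tensor | np.ndarray, mode: str = "trilinear") -> Tensor:
    """Sample `x` (N,C,H,W,D) at absolute voxel coordinates (N,3,*,*,*).

    Out-of-domain coordinates are clamped to the border.  Trilinear mode is
    differentiable with respect to both the volume and the coordinates;
    nearest mode (for label maps) is not differentiable.
    """
    co = coords.data if isinstance(coords, Tensor) else np.asarray(coords, np.float32)
    n, c, h, w, d = x.shape
    hi = np.array([h - 1, w - 1, d - 1], dtype=np.float32).reshape(1, 3, 1, 1, 1)
    bad = ~np.isfinite(co)
    if bad.any():
        # propagate NaNs to the output instead of corrupting indices, so a
        # non-finite field surfaces as a non-finite loss downstream
        co = np.where(bad, 0.0, co)
        nan_mask = bad.any(axis=1, keepdims=True)
    else:
        nan_mask = None
    inside = (co >= 0) & (co <= hi)
    cc = np.clip(co, 0, hi)

    if mode == "nearest":
        idx = np.rint(cc).astype(np.intp)
        out = np.stack([_gather(x.data[b], idx[b, 0], idx[b, 1], idx[b, 2])
                        for b in range(n)])
        return _op(out, (x,) if x.requires_grad else (), lambda g: (None,))

    c0 = np.floor(cc)
    frac = cc - c0
    i0 = c0.astype(np.intp)
    lim = np.array([h - 1, w - 1, d - 1], dtype=np.intp).reshape(1, 3, 1, 1, 1)
    i1 = np.minimum(i0 + 1, lim)

    corners = []
    out = np.zeros((n,) + (c,) + cc.shape[2:], dtype=np.float32)
    for bx in (0, 1):
        for by in (0, 1):
            for bz in (0, 1):
                ii = (i1 if bx else i0)[:, 0]
                jj = (i1 if by else i0)[:, 1]
                kk = (i1 if bz else i0)[:, 2]
                wx = frac[:, 0] if bx else 1.0 - frac[:, 0]
                wy = frac[:, 1] if by else 1.0 - frac[:, 1]
                wz = frac[:, 2] if bz else 1.0 - frac[:, 2]
                wgt = (wx * wy * wz)[:, None]
                vals = np.stack([_gather(x.data[b], ii[b], jj[b], kk[b])
                                 for b in range(n)])
                out += vals * wgt
                corners.append((ii, jj, kk, wx, wy, wz, vals, (bx, by, bz)))
    if nan_mask is not None:
        out = np.where(nan_mask, np.float32(np.nan), out)

    xd = x.data
    coords_is_tensor = isinstance(coords, Tensor)

    def bwd(g):
        gx = np.zeros_like(xd) if x.requires_grad else None
        gc = np.zeros_like(cc) if coords_is_tensor and coords.requires_grad else None
        for ii, jj, kk, wx, wy, wz, vals, (bx, by, bz) in corners:
            wgt = (wx * wy * wz)[:, None]
            if gx is not None:
                contrib = g * wgt
                for b in range(n):
                    flat = (ii[b] * w + jj[b]) * d + kk[b]
                    np.add.at(gx[b].reshape(c, -1),
                              (np.arange(c)[:, None], flat.ravel()[None, :]),
                              contrib[b].reshape(c, -1))
            if gc is not None:
                gv = (g * vals).sum(axis=1)
                gc[:, 0] += gv * (1.0 if bx else -1.0) * wy * wz
                gc[:, 1] += gv * wx * (1.0 if by else -1.0) * wz
                gc[:, 2] += gv * wx * wy * (1.0 if bz else -1.0)
        if gc is not None:
            gc *= inside  # clamp has zero slope outside the domain
        if coords_is_tensor:
            return (gx, gc)
        return (gx,)

    parents = (x, coords) if coords_is_tensor else (x,)
    return _op(out, parents, bwd)


# -- pooling / box filtering ------------------------------------------------

def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2 (even spatial dims required)."""
    n, c, h, w, d = x.shape
    if h % 2 or w % 2 or d % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    xr = (x.data.reshape(n, c, h // 2, 2, w // 2, 2, d // 2, 2)
          .transpose(0, 1, 2, 4, 6, 3, 5, 7)
          .reshape(n, c, h // 2, w // 2, d // 2, 8))
    arg = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]

    def bwd(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
        gx = (gr.reshape(n, c, h // 2, w // 2, d // 2, 2, 2, 2)
              .transpose(0, 1, 2, 5, 3, 6, 4, 7)
              .reshape(n, c, h, w, d))
        return (gx,)

    return _op(out, (x,), bwd)


def nearest_up2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling; backward sums each 2x2x2 block."""
    n, c, h, w, d = x.shape
    out = np.repeat(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), 2, axis=4)

    def bwd(g):
        gr = (g.reshape(n, c, h, 2, w, 2, d, 2)
              .sum(axis=(3, 5, 7)))
        return (gr,)

    return _op(out, (x,), bwd)


def boxsum(x: Tensor, n: int) -> Tensor:
    """Sliding-window sum over n^3 spatial windows, zero-padded at borders.

    The box kernel is symmetric and the padding is zero, so the operation is
    self-adjoint: the backward pass applies the same filter to the gradient.
    """
    size = (1, 1, n, n, n) if x.ndim == 5 else (n,) * x.ndim
    scale = float(n) ** 3

    def run(a):
        return (ndimage.uniform_filter(a.astype(np.float64), size=size,
                                       mode="constant") * scale).astype(np.float32)

    return _op(run(x.data), (x,), lambda g: (run(g),))
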