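"""Module/parameter containers and the Adam optimizer for the autodiff core.

Initialization follows the package default of truncated-normal fan-in
scaling; convolutions may be zero-initialized where a block must start as an
exact identity (e.g. the displacement head and upsampler offset
projections).
"""

from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

from .autodiff import Tensor, conv3d, sqrt


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal nn-style container with recursive parameter discovery."""

    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def trunc_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    """Normal draw truncated at two standard deviations."""
    w = rng.standard_normal(shape)
    return (np.clip(w, -2.0, 2.0) * std).astype(np.float32)


class Conv3d(Module):
    """Grouped 3D convolution with cubic kernels and 'same'-style padding
    chosen by the caller."""

    def __init__(self, cin: int, cout: int, kernel: int, *, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, groups: int = 1,
                 bias: bool = True, zero_init: bool = False):
        super().__init__()
        if kernel % 2 == 0 and stride == 1:
            raise ValueError(f"even kernel size {kernel} with unit stride")
        if cin % groups or cout % groups:
            raise ValueError(f"groups={groups} must divide cin={cin}, cout={cout}")
        if padding is None:
            padding = (kernel - 1) // 2
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (cin // groups) * kernel ** 3
        shape = (cout, cin // groups, kernel, kernel, kernel)
        if zero_init:
            self.weight = Parameter(np.zeros(shape, dtype=np.float32))
        else:
            self.weight = Parameter(trunc_normal(rng, shape, math.sqrt(1.0 / fan_in)))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)


class ChannelLayerNorm(Module):
    """Layer normalization over the channel axis, per voxel (the ConvNeXt
    "channels-first" convention), with learnable per-channel scale/shift."""

    def __init__(self, channels: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        y = xc / sqrt(var + self.eps)
        c = x.shape[1]
        return y * self.gamma.reshape(1, c, 1, 1, 1) + self.beta.reshape(1, c, 1, 1, 1)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.data -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": [a.copy() for a in self.m],
                "v": [a.copy() for a in self.v]}

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        self.m = [np.asarray(a, np.float32).copy() for a in state["m"]]
        self.v = [np.asarray(a, np.float32).copy() for a in state["v"]]
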