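"""The WaveMorph registration network and its building blocks.

A U-Net-style encoder-decoder that maps a concatenated (moving, fixed)
image pair to a dense displacement field.  Downsampling is done by
multi-subband wavelet feature fusion (MSWF): an orthonormal Haar DWT splits
each feature map losslessly into eight half-resolution subbands, each
subband family is enhanced by ConvNeXt blocks whose kernel size matches its
frequency content (7 for the pure low-pass LLL, 3 for the pure high-pass
HHH, parallel 1/3/5 kernels for the six mixed subbands), and the enhanced
stack is fused by pointwise convolution and a cross-dimension attention
gate.  The decoder restores resolution with a lightweight dynamic upsampler
(learned per-group sampling offsets on top of a trilinear x2 grid) and
learnable-scale skip connections.  The displacement head is
zero-initialized so an untrained model is exactly the identity transform.

Max-pooling, patch-merging and plain Haar ("wavesample") downsamplers and
nearest/trilinear upsamplers are available as drop-in replacements for
ablation studies.

Channel widths default to a budget-calibrated profile that keeps the whole
model under one million trainable parameters and the dynamic-upsampler
offset projections under one thousand; see ``ModelConfig``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, gelu, grid_sample3, maxpool2, nearest_up2, sigmoid
from .haar import DWT3, IDWT3
from .nn import ChannelLayerNorm, Conv3d, Module, ModuleList, Parameter

MIXED_KERNELS = (1, 3, 5)  # parallel branches for the six mixed subbands
LLL_KERNEL = 7             # pure low-frequency subband
HHH_KERNEL = 3             # pure high-frequency subband

DOWNSAMPLER_KINDS = ("mswf", "maxpool", "patchmerge", "wavesample")
UPSAMPLER_KINDS = ("dysample", "nearest", "trilinear")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``stage_channels`` are the four encoder outputs (four downsamplings put
    the bottleneck at 1/16 resolution).  The defaults are calibrated so the
    full model stays under 1e6 trainable parameters and all dynamic-upsampler
    offset projections together stay under 1e3.
    """

    stem_channels: int = 8
    stage_channels: tuple = (12, 16, 24, 32)
    convnext_expansion: int = 2
    decoder_kernels: tuple = (7, 7, 3, 3)  # coarse -> fine
    downsampler_kind: str = "mswf"
    upsampler_kind: str = "dysample"
    dysample_groups: int = 2
    dysample_scope: float = 0.25
    skipscale_init: float = 1.0
    skip_mode: str = "reuse"  # "reuse" the MSWF subbands or run a "dedicated" pass

    def __post_init__(self):
        self.stage_channels = tuple(self.stage_channels)
        self.decoder_kernels = tuple(self.decoder_kernels)
        if len(self.stage_channels) != 4:
            raise ValueError("stage_channels must list exactly 4 encoder widths")
        if len(self.decoder_kernels) != 4:
            raise ValueError("decoder_kernels must list exactly 4 kernel sizes")
        if self.downsampler_kind not in DOWNSAMPLER_KINDS:
            raise ValueError(f"unknown downsampler_kind {self.downsampler_kind!r}; "
                             f"expected one of {DOWNSAMPLER_KINDS}")
        if self.upsampler_kind not in UPSAMPLER_KINDS:
            raise ValueError(f"unknown upsampler_kind {self.upsampler_kind!r}; "
                             f"expected one of {UPSAMPLER_KINDS}")
        if not (0.0 < self.dysample_scope <= 1.0):
            raise ValueError("dysample_scope must lie in (0, 1]")
        if self.skip_mode not in ("reuse", "dedicated"):
            raise ValueError(f"unknown skip_mode {self.skip_mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_channels"] = list(self.stage_channels)
        d["decoder_kernels"] = list(self.decoder_kernels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class ConvNeXtBlock(Module):
    """Depthwise k^3 conv -> channel LayerNorm -> pointwise expansion ->
    GELU -> pointwise projection, with a residual connection.

    ``pointwise_groups`` restricts the two pointwise convolutions to channel
    groups; the mixed-subband branches use one group per subband so that the
    parameter count stays linear in the subband count.
    """

    def __init__(self, channels: int, kernel: int, expansion: int, *,
                 rng: np.random.Generator, pointwise_groups: int = 1):
        super().__init__()
        if kernel not in (1, 3, 5, 7):
            raise ValueError(f"kernel must be one of 1,3,5,7, got {kernel}")
        hidden = channels * expansion
        self.dw = Conv3d(channels, channels, kernel, groups=channels, rng=rng)
        self.norm = ChannelLayerNorm(channels)
        self.pw1 = Conv3d(channels, hidden, 1, groups=pointwise_groups, rng=rng)
        self.pw2 = Conv3d(hidden, channels, 1, groups=pointwise_groups, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.pw2(gelu(self.pw1(self.norm(self.dw(x)))))
        return x + y


class CDA(Module):
    """Four-branch cross-dimension attention gate.

    Three branches rotate the tensor so the channel axis pairs with one
    spatial axis each, pool over the rotated-out axis, derive a sigmoid gate
    from a small convolution of the pooled statistics, and gate the rotated
    view; the fourth (spatial) branch gates on channel-pooled statistics
    directly.  The four gated views are averaged.  All gates lie in (0, 1),
    so no output voxel exceeds its input in magnitude.
    """

    def __init__(self, channels: int, *, rng: np.random.Generator):
        super().__init__()
        if channels < 4:
            raise ValueError(f"CDA requires at least 4 channels, got {channels}")
        self.convs = ModuleList([Conv3d(1, 1, 3, rng=rng) for _ in range(4)])

    def _gate(self, pooled: Tensor, idx: int) -> Tensor:
        return sigmoid(self.convs[idx](pooled))

    def forward(self, x: Tensor) -> Tensor:
        outs = []
        for a in range(3):  # channel <-> spatial-axis-a pairings
            t = x.swapaxes(1, 2 + a)
            pooled = t.mean(axis=1, keepdims=True)
            outs.append((t * self._gate(pooled, a)).swapaxes(1, 2 + a))
        pooled = x.mean(axis=1, keepdims=True)  # spatial branch
        outs.append(x * self._gate(pooled, 3))
        return (outs[0] + outs[1] + outs[2] + outs[3]) * 0.25


class SubbandEnhancer(Module):
    """Per-subband enhancement of a channel-stacked Haar decomposition.

    Input (N,8C,h,w,d) ordered LLL..HHH; output the same layout with LLL
    passed through a kernel-7 ConvNeXt block, HHH through kernel 3, and the
    six mixed subbands through three parallel kernel-1/3/5 ConvNeXt blocks
    (expansion 1, grouped per subband) whose outputs are fused subband-wise
    by a grouped pointwise convolution added residually to the raw mixed
    stack — so zeroed branches leave every subband unchanged.
    """

    def __init__(self, channels: int, expansion: int, *, rng: np.random.Generator):
        super().__init__()
        c = self.channels = channels
        self.lll = ConvNeXtBlock(c, LLL_KERNEL, expansion, rng=rng)
        self.hhh = ConvNeXtBlock(c, HHH_KERNEL, expansion, rng=rng)
        self.mixed = ModuleList([
            ConvNeXtBlock(6 * c, k, 1, rng=rng, pointwise_groups=6)
            for k in MIXED_KERNELS])
        self.mixed_fuse = Conv3d(len(MIXED_KERNELS) * 6 * c, 6 * c, 1,
                                 groups=6, rng=rng)

    def forward(self, subbands: Tensor) -> Tensor:
        c = self.channels
        f_lll = self.lll(subbands[:, :c])
        f_hhh = self.hhh(subbands[:, 7 * c:])
        mixed = subbands[:, c:7 * c]
        branches = [m(mixed) for m in self.mixed]
        # regroup to subband-major order so the grouped fuse sees, per group,
        # the three branch responses of one subband
        per_subband = [concat([b[:, s * c:(s + 1) * c] for b in branches], 1)
                       for s in range(6)]
        f_mixed = mixed + self.mixed_fuse(concat(per_subband, 1))
        return concat([f_lll, f_mixed, f_hhh], 1)


class MSWFDown(Module):
    """MSWF in downsampling mode: DWT -> subband enhancement -> pointwise
    channel compression -> cross-dimension attention; output at half
    resolution.  When asked, also returns the IDWT of the enhanced subbands
    as a full-resolution skip feature."""

    def __init__(self, cin: int, cout: int, expansion: int, *,
                 rng: np.random.Generator):
        super().__init__()
        self.dwt = DWT3()
        self.enhance = SubbandEnhancer(cin, expansion, rng=rng)
        self.compress = Conv3d(8 * cin, cout, 1, rng=rng)
        self.cda = CDA(cout, rng=rng)
        self.idwt = IDWT3()

    def forward(self, x: Tensor, return_skip: bool = False):
        enhanced = self.enhance(self.dwt(x))
        out = self.cda(self.compress(enhanced))
        if return_skip:
            return out, self.idwt(enhanced)
        return out


class MSWFSame(Module):
    """MSWF in resolution-preserving mode: DWT -> subband enhancement ->
    IDWT back to the input resolution -> pointwise conv -> cross-dimension
    attention -> kernel-7 ConvNeXt refinement.  Channel count preserved."""

    def __init__(self, channels: int, expansion: int, *, rng: np.random.Generator):
        super().__init__()
        self.dwt = DWT3()
        self.enhance = SubbandEnhancer(channels, expansion, rng=rng)
        self.idwt = IDWT3()
        self.pconv = Conv3d(channels, channels, 1, rng=rng)
        self.cda = CDA(channels, rng=rng)
        self.refine = ConvNeXtBlock(channels, LLL_KERNEL, expansion, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        f_idwt = self.idwt(self.enhance(self.dwt(x)))
        return self.refine(self.cda(self.pconv(f_idwt)))


class Bottleneck(Module):
    """Two sequential resolution-preserving MSWF blocks."""

    def __init__(self, channels: int, expansion: int, *, rng: np.random.Generator):
        super().__init__()
        self.block1 = MSWFSame(channels, expansion, rng=rng)
        self.block2 = MSWFSame(channels, expansion, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(x))


class ConvBottleneck(Module):
    """Two plain ConvNeXt blocks; the ablation stand-in for `Bottleneck`."""

    def __init__(self, channels: int, expansion: int, *, rng: np.random.Generator):
        super().__init__()
        self.block1 = ConvNeXtBlock(channels, LLL_KERNEL, expansion, rng=rng)
        self.block2 = ConvNeXtBlock(channels, LLL_KERNEL, expansion, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(x))


# -- alternative samplers for the ablation grid ----------------------------

class MaxPoolDown(Module):
    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator):
        super().__init__()
        self.proj = Conv3d(cin, cout, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.proj(maxpool2(x))


class PatchMergeDown(Module):
    """2x2x2 space-to-channel repacking followed by a linear projection."""

    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator):
        super().__init__()
        self.proj = Conv3d(8 * cin, cout, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w, d = x.shape
        if h % 2 or w % 2 or d % 2:
            raise ValueError("patch merging requires even spatial dimensions")
        t = x.reshape(n, c, h // 2, 2, w // 2, 2, d // 2, 2)
        t = t.transpose((0, 3, 5, 7, 1, 2, 4, 6))
        return self.proj(t.reshape(n, 8 * c, h // 2, w // 2, d // 2))


class WaveSampleDown(Module):
    """Plain Haar downsampling: DWT then pointwise projection of the
    channel-stacked subbands (no per-subband enhancement)."""

    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator):
        super().__init__()
        self.dwt = DWT3()
        self.proj = Conv3d(8 * cin, cout, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.proj(self.dwt(x))


def _up2_base_grid(h: int, w: int, d: int) -> np.ndarray:
    """Input-space sampling positions of x2 trilinear upsampling, laid out as
    (3, 2,2,2, h, w, d): output voxel 2i+di samples input coordinate
    i + (2*di - 1)/4 (the align-to-voxel-centre convention)."""
    grid = np.zeros((3, 2, 2, 2, h, w, d), dtype=np.float32)
    ii = np.arange(h, dtype=np.float32).reshape(h, 1, 1)
    jj = np.arange(w, dtype=np.float32).reshape(1, w, 1)
    kk = np.arange(d, dtype=np.float32).reshape(1, 1, d)
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                grid[0, di, dj, dk] = ii + (2 * di - 1) / 4.0
                grid[1, di, dj, dk] = jj + (2 * dj - 1) / 4.0
                grid[2, di, dj, dk] = kk + (2 * dk - 1) / 4.0
    return grid


def _interleave_coords(c8: Tensor, h: int, w: int, d: int) -> Tensor:
    """(N,3,2,2,2,h,w,d) sub-position coords -> (N,3,2h,2w,2d)."""
    t = c8.transpose((0, 1, 5, 2, 6, 3, 7, 4))
    return t.reshape(c8.shape[0], 3, 2 * h, 2 * w, 2 * d)


class DySample(Module):
    """Dynamic x2 upsampling with learned per-group sampling offsets.

    A zero-initialized pointwise projection of a 4-channel slice of the
    input produces, per offset group, a 3-vector offset for each of the
    eight x2 sub-positions.  Offsets are scaled by ``scope * 0.5`` voxels
    and added to the fixed trilinear x2 grid, and each channel group is
    trilinearly resampled at its own offset grid.  At initialization the
    offsets are exactly zero, so the layer reproduces plain trilinear x2
    upsampling.
    """

    def __init__(self, channels: int, *, rng: np.random.Generator,
                 groups: int = 2, scope: float = 0.25):
        super().__init__()
        if channels % groups:
            raise ValueError(f"dysample groups={groups} must divide "
                             f"channels={channels}")
        if channels < 4:
            raise ValueError("dysample needs at least 4 input channels")
        self.groups, self.scope, self.channels = groups, scope, channels
        self.offset_proj = Conv3d(4, 24 * groups, 1, bias=False,
                                  zero_init=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w, d = x.shape
        g = self.groups
        off = self.offset_proj(x[:, :4])
        off = off.reshape(n, g, 3, 2, 2, 2, h, w, d) * (self.scope * 0.5)
        base = Tensor(_up2_base_grid(h, w, d)[None])
        cg = c // g
        outs = []
        for gi in range(g):
            coords = _interleave_coords(base + off[:, gi], h, w, d)
            outs.append(grid_sample3(x[:, gi * cg:(gi + 1) * cg], coords))
        return concat(outs, 1) if g > 1 else outs[0]


class TrilinearUp(Module):
    """Fixed trilinear x2 upsampling (the zero-offset dynamic grid)."""

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w, d = x.shape
        coords = _interleave_coords(Tensor(_up2_base_grid(h, w, d)[None]), h, w, d)
        return grid_sample3(x, coords)


class NearestUp(Module):
    def forward(self, x: Tensor) -> Tensor:
        return nearest_up2(x)


def make_sampler(kind: str, *, rng: np.random.Generator, cin: int | None = None,
                 cout: int | None = None, channels: int | None = None,
                 expansion: int = 2, groups: int = 2, scope: float = 0.25) -> Module:
    """Build a down- or upsampling component by name.

    Downsamplers ("mswf", "maxpool", "patchmerge", "wavesample") need
    ``cin``/``cout``; upsamplers ("dysample", "nearest", "trilinear") need
    ``channels`` for the dynamic variant only.
    """
    if kind == "mswf":
        return MSWFDown(cin, cout, expansion, rng=rng)
    if kind == "maxpool":
        return MaxPoolDown(cin, cout, rng=rng)
    if kind == "patchmerge":
        return PatchMergeDown(cin, cout, rng=rng)
    if kind == "wavesample":
        return WaveSampleDown(cin, cout, rng=rng)
    if kind == "dysample":
        return DySample(channels, rng=rng, groups=groups, scope=scope)
    if kind == "nearest":
        return NearestUp()
    if kind == "trilinear":
        return TrilinearUp()
    raise ValueError(f"unknown sampler kind {kind!r}")


class DecConvBlock(Module):
    """Decoder stage: x2 upsampling -> concatenation with the (learnably
    scaled) skip feature -> pointwise fusion -> ConvNeXt refinement."""

    def __init__(self, cin: int, skip_ch: int, cout: int, kernel: int,
                 config: ModelConfig, *, rng: np.random.Generator):
        super().__init__()
        self.up = make_sampler(config.upsampler_kind, rng=rng, channels=cin,
                               groups=config.dysample_groups,
                               scope=config.dysample_scope)
        self.skipscale = Parameter(np.float32(config.skipscale_init))
        self.fuse = Conv3d(cin + skip_ch, cout, 1, rng=rng)
        self.conv = ConvNeXtBlock(cout, kernel, config.convnext_expansion, rng=rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        up = self.up(x)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"skip resolution {skip.shape[2:]} does not match upsampled "
                f"feature resolution {up.shape[2:]} (expected exactly 2x)")
        y = concat([up, skip * self.skipscale], 1)
        return self.conv(self.fuse(y))


class WaveMorph(Module):
    """Encoder-decoder mapping an image pair to a displacement field.

    ``forward`` takes the moving and fixed volumes as (N,1,H,W,D) tensors
    with spatial extents divisible by `required_multiple` (32 for the
    default wavelet bottleneck) and returns the displacement field
    ``u`` as (N,3,H,W,D) in voxel units along array axes.  The final head is
    zero-initialized, so a freshly constructed model predicts u == 0.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = cfg = config or ModelConfig()
        rng = np.random.default_rng(seed)
        stem = cfg.stem_channels
        stages = cfg.stage_channels
        exp = cfg.convnext_expansion
        self.stem = Conv3d(2, stem, 3, rng=rng)

        chans_in = (stem,) + stages[:-1]
        self.downs = ModuleList()
        self.feats = ModuleList()
        self.skip_blocks = ModuleList()
        for cin, cout in zip(chans_in, stages):
            if cfg.downsampler_kind == "mswf":
                self.downs.append(MSWFDown(cin, cout, exp, rng=rng))
                if cfg.skip_mode == "dedicated":
                    self.skip_blocks.append(MSWFSame(cin, exp, rng=rng))
            else:
                self.downs.append(make_sampler(cfg.downsampler_kind, rng=rng,
                                               cin=cin, cout=cout, expansion=exp))
            self.feats.append(ConvNeXtBlock(cout, 3, exp, rng=rng))

        if cfg.downsampler_kind == "mswf":
            self.bottleneck = Bottleneck(stages[-1], exp, rng=rng)
        else:
            self.bottleneck = ConvBottleneck(stages[-1], exp, rng=rng)

        self.decs = ModuleList()
        dec_in = stages[-1]
        for kernel, skip_ch in zip(cfg.decoder_kernels, reversed(chans_in)):
            self.decs.append(DecConvBlock(dec_in, skip_ch, skip_ch, kernel,
                                          cfg, rng=rng))
            dec_in = skip_ch
        self.head = Conv3d(dec_in, 3, 3, zero_init=True, rng=rng)

    @property
    def required_multiple(self) -> int:
        """Spatial extents must be divisible by this: 16 (= 2^4 stages), or
        32 when the wavelet bottleneck needs an even 1/16-resolution grid."""
        return 32 if self.config.downsampler_kind == "mswf" else 16

    def _check_shape(self, m: Tensor, f: Tensor):
        if m.shape != f.shape:
            raise ValueError(f"moving {m.shape} and fixed {f.shape} shapes differ")
        div = self.required_multiple
        for dim in m.shape[2:]:
            if dim % div:
                pad = div - dim % div
                raise ValueError(
                    f"spatial size {dim} is not divisible by {div}; "
                    f"pad this axis by {pad} voxels (e.g. to {dim + pad})")

    def forward(self, m: Tensor, f: Tensor) -> Tensor:
        self._check_shape(m, f)
        x = self.stem(concat([m, f], 1))
        skips = []
        for i, (down, feat) in enumerate(zip(self.downs, self.feats)):
            if isinstance(down, MSWFDown):
                if self.config.skip_mode == "dedicated":
                    skips.append(self.skip_blocks[i](x))
                    x = down(x)
                else:
                    x, skip = down(x, return_skip=True)
                    skips.append(skip)
            else:
                skips.append(x)
                x = down(x)
            x = feat(x)
        x = self.bottleneck(x)
        for dec, skip in zip(self.decs, reversed(skips)):
            x = dec(x, skip)
        return self.head(x)

    def predict(self, moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
        """Displacement field (3,H,W,D) for a single numpy volume pair.

        Unlike `forward`, inputs whose extents are not divisible by
        `required_multiple` are edge-padded and the field cropped back."""
        moving = np.asarray(moving, np.float32)
        fixed = np.asarray(fixed, np.float32)
        div = self.required_multiple
        pads = [(div - s % div) % div for s in moving.shape]
        crop = tuple(slice(0, s) for s in moving.shape)
        if any(pads):
            width = [(0, p) for p in pads]
            moving = np.pad(moving, width, mode="edge")
            fixed = np.pad(fixed, width, mode="edge")
        with ad.no_grad():
            m = Tensor(moving[None, None])
            f = Tensor(fixed[None, None])
            return self.forward(m, f).data[0][(slice(None),) + crop]

    def dysample_offset_parameter_count(self) -> int:
        """Total trainable parameters of all dynamic-upsampler offset
        projections (the advertised sub-1k budget)."""
        total = 0
        for dec in self.decs:
            if isinstance(dec.up, DySample):
                total += dec.up.offset_proj.num_parameters()
        return total


def wavemorph_forward(moving: np.ndarray, fixed: np.ndarray,
                      config: ModelConfig | None = None,
                      model: WaveMorph | None = None,
                      seed: int = 0) -> np.ndarray:
    """Convenience one-shot forward pass on numpy volumes (H,W,D).

    Enforces the strict divisibility contract of `WaveMorph.forward`; use
    `WaveMorph.predict` for automatic padding."""
    model = model or WaveMorph(config, seed=seed)
    with ad.no_grad():
        m = Tensor(np.asarray(moving, np.float32)[None, None])
        f = Tensor(np.asarray(fixed, np.float32)[None, None])
        return model(m, f).data[0]
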