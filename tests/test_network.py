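"""Network building blocks and the assembled registration model: shape
contracts, identity initializations, parameter budgets, gradient flow and
determinism."""

import numpy as np
import pytest
from scipy import ndimage

from wavemorph.autodiff import Tensor
from wavemorph.network import (CDA, Bottleneck, ConvNeXtBlock, DecConvBlock,
                               DySample, MSWFDown, MSWFSame, ModelConfig,
                               TrilinearUp, WaveMorph, make_sampler,
                               wavemorph_forward)
from wavemorph import autodiff as ad


def _rng():
    return np.random.default_rng(0)


def _zero_residual_branch(block: ConvNeXtBlock):
    block.pw2.weight.data[:] = 0
    block.pw2.bias.data[:] = 0


class TestConvNeXtBlock:
    def test_zero_branch_is_exact_identity(self, rng):
        block = ConvNeXtBlock(4, 3, 2, rng=_rng())
        _zero_residual_branch(block)
        x = Tensor(rng.standard_normal((1, 4, 6, 6, 6)).astype(np.float32))
        assert np.array_equal(block(x).data, x.data)

    @pytest.mark.parametrize("kernel", [1, 3, 5, 7])
    def test_shape_preserved_for_all_kernels(self, kernel, rng):
        block = ConvNeXtBlock(4, kernel, 2, rng=_rng())
        x = Tensor(rng.standard_normal((1, 4, 6, 6, 6)).astype(np.float32))
        assert block(x).shape == x.shape

    @pytest.mark.parametrize("c,k,r", [(4, 3, 2), (6, 5, 1), (8, 7, 4)])
    def test_parameter_count_closed_form(self, c, k, r):
        block = ConvNeXtBlock(c, k, r, rng=_rng())
        expected = (c * k ** 3 + c) + 2 * c + (c * r * c + r * c) + (r * c * c + c)
        assert block.num_parameters() == expected

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            ConvNeXtBlock(4, 4, 2, rng=_rng())


class TestCDA:
    def test_shape_preserved(self, rng):
        x = Tensor(rng.standard_normal((1, 8, 4, 4, 4)).astype(np.float32))
        assert CDA(8, rng=_rng())(x).shape == x.shape

    def test_gating_never_amplifies(self, rng):
        cda = CDA(8, rng=_rng())
        x = rng.standard_normal((1, 8, 4, 4, 4)).astype(np.float32)
        out = cda(Tensor(x)).data
        assert np.all(np.abs(out) <= np.abs(x) + 1e-6)

    def test_deterministic_forward(self, rng):
        cda = CDA(8, rng=_rng())
        x = Tensor(rng.standard_normal((1, 8, 4, 4, 4)).astype(np.float32))
        assert np.array_equal(cda(x).data, cda(x).data)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            CDA(2, rng=_rng())


class TestMSWF:
    def test_down_shape_contract(self, rng):
        block = MSWFDown(8, 16, 2, rng=_rng())
        x = Tensor(rng.standard_normal((1, 8, 8, 8, 8)).astype(np.float32))
        out = block(x)
        assert out.shape == (1, 16, 4, 4, 4)

    def test_down_skip_is_full_resolution(self, rng):
        block = MSWFDown(4, 8, 2, rng=_rng())
        x = Tensor(rng.standard_normal((1, 4, 8, 8, 8)).astype(np.float32))
        out, skip = block(x, return_skip=True)
        assert out.shape == (1, 8, 4, 4, 4) and skip.shape == x.shape

    def test_constant_input_leaves_highpass_branches_silent(self):
        # after the DWT of a constant, the seven high-pass subbands are
        # exactly zero, so the HHH/mixed branches receive zero signal
        from wavemorph.haar import dwt3, SUBBAND_KEYS
        sb = dwt3(np.full((4, 8, 8, 8), 2.5, np.float32))
        for k in SUBBAND_KEYS[1:]:
            assert np.all(sb[k] == 0.0)

    def test_down_gradient_reaches_every_parameter(self, rng):
        block = MSWFDown(4, 8, 2, rng=_rng())
        x = Tensor(rng.standard_normal((1, 4, 4, 4, 4)).astype(np.float32))
        block(x).sum().backward()
        grads = [p.grad for p in block.parameters()]
        assert all(g is not None and np.isfinite(g).all() for g in grads)

    def test_same_preserves_shape(self, rng):
        block = MSWFSame(8, 2, rng=_rng())
        x = Tensor(rng.standard_normal((1, 8, 8, 8, 8)).astype(np.float32))
        assert block(x).shape == x.shape

    def test_same_with_zeroed_branches_reconstructs_input_before_tail(self, rng):
        block = MSWFSame(4, 2, rng=_rng())
        _zero_residual_branch(block.enhance.lll)
        _zero_residual_branch(block.enhance.hhh)
        for b in block.enhance.mixed:
            _zero_residual_branch(b)
        block.enhance.mixed_fuse.weight.data[:] = 0
        block.enhance.mixed_fuse.bias.data[:] = 0
        x = Tensor(rng.standard_normal((1, 4, 8, 8, 8)).astype(np.float32))
        recon = block.idwt(block.enhance(block.dwt(x)))
        assert np.abs(recon.data - x.data).max() <= 1e-5

    def test_deterministic_repeat_forward(self, rng):
        block = MSWFSame(4, 2, rng=_rng())
        x = Tensor(rng.standard_normal((1, 4, 4, 4, 4)).astype(np.float32))
        assert np.array_equal(block(x).data, block(x).data)

    def test_odd_dims_propagate_wavelet_error(self, rng):
        block = MSWFDown(4, 8, 2, rng=_rng())
        with pytest.raises(ValueError, match="odd"):
            block(Tensor(np.zeros((1, 4, 5, 4, 4), np.float32)))


class TestBottleneck:
    def test_shape_and_parameter_doubling(self, rng):
        bn = Bottleneck(16, 2, rng=_rng())
        assert bn.num_parameters() == 2 * MSWFSame(16, 2, rng=_rng()).num_parameters()
        x = Tensor(rng.standard_normal((1, 16, 2, 2, 2)).astype(np.float32))
        assert bn(x).shape == x.shape

    def test_gradient_flows_to_both_blocks(self, rng):
        bn = Bottleneck(4, 1, rng=_rng())
        x = Tensor(rng.standard_normal((1, 4, 2, 2, 2)).astype(np.float32))
        bn(x).sum().backward()
        for sub in (bn.block1, bn.block2):
            assert any(p.grad is not None and np.abs(p.grad).max() >= 0
                       for p in sub.parameters())
            assert all(p.grad is not None for p in sub.parameters())


class TestDySample:
    def test_zero_init_equals_trilinear_upsampling(self, rng):
        up = DySample(8, rng=_rng(), groups=2)
        x = Tensor(rng.standard_normal((1, 8, 4, 4, 4)).astype(np.float32))
        ref = TrilinearUp()(x)
        assert np.abs(up(x).data - ref.data).max() <= 1e-6

    def test_trilinear_matches_map_coordinates_oracle(self, rng):
        from wavemorph.network import _up2_base_grid
        x = rng.standard_normal((1, 1, 4, 4, 4)).astype(np.float32)
        out = TrilinearUp()(Tensor(x)).data[0, 0]
        grid = _up2_base_grid(4, 4, 4)
        coords = grid.transpose(0, 4, 1, 5, 2, 6, 3).reshape(3, 8, 8, 8)
        ref = ndimage.map_coordinates(x[0, 0].astype(np.float64),
                                      np.clip(coords.reshape(3, -1), 0, 3),
                                      order=1, mode="nearest").reshape(8, 8, 8)
        assert np.abs(out - ref).max() <= 1e-5

    def test_constant_input_stays_constant_with_random_offsets(self, rng):
        up = DySample(4, rng=_rng(), groups=1)
        up.offset_proj.weight.data = rng.standard_normal(
            up.offset_proj.weight.shape).astype(np.float32)
        x = Tensor(np.full((1, 4, 4, 4, 4), 1.7, np.float32))
        assert np.allclose(up(x).data, 1.7, atol=1e-6)

    def test_group_mismatch_rejected(self):
        with pytest.raises(ValueError):
            DySample(6, rng=_rng(), groups=4)

    def test_default_decoder_offset_budget_under_1k(self):
        model = WaveMorph(seed=0)
        assert 0 < model.dysample_offset_parameter_count() < 1000


class TestSamplers:
    def test_maxpool_on_ones_is_ones(self):
        out = ad.maxpool2(Tensor(np.ones((1, 1, 4, 4, 4), np.float32)))
        assert np.array_equal(out.data, np.ones((1, 1, 2, 2, 2), np.float32))

    def test_patchmerge_shape_contract(self, rng):
        pm = make_sampler("patchmerge", rng=_rng(), cin=8, cout=16)
        x = Tensor(rng.standard_normal((1, 8, 8, 8, 8)).astype(np.float32))
        assert pm(x).shape == (1, 16, 4, 4, 4)

    def test_nearest_up_places_2x2x2_blocks(self):
        x = np.zeros((1, 1, 2, 2, 2), np.float32)
        x[0, 0, 1, 0, 1] = 1.0
        out = make_sampler("nearest", rng=_rng())(Tensor(x)).data
        expected = np.zeros((1, 1, 4, 4, 4), np.float32)
        expected[0, 0, 2:4, 0:2, 2:4] = 1.0
        assert np.array_equal(out, expected)

    def test_downsampler_shape_contracts(self, rng):
        x = Tensor(rng.standard_normal((1, 8, 8, 8, 8)).astype(np.float32))
        for kind in ("mswf", "maxpool", "patchmerge", "wavesample"):
            out = make_sampler(kind, rng=_rng(), cin=8, cout=12)(x)
            assert out.shape == (1, 12, 4, 4, 4), kind

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_sampler("bilinear", rng=_rng())


class TestDecConvBlock:
    def _block(self, cfg=None):
        return DecConvBlock(8, 4, 4, 3, cfg or ModelConfig(), rng=_rng())

    def test_shape_contract(self, rng):
        blk = self._block()
        x = Tensor(rng.standard_normal((1, 8, 2, 2, 2)).astype(np.float32))
        skip = Tensor(rng.standard_normal((1, 4, 4, 4, 4)).astype(np.float32))
        assert blk(x, skip).shape == (1, 4, 4, 4, 4)

    def test_skipscale_initialized_from_config(self):
        assert self._block().skipscale.data == pytest.approx(1.0)
        cfg = ModelConfig(skipscale_init=0.25)
        assert self._block(cfg).skipscale.data == pytest.approx(0.25)

    def test_zero_skipscale_decouples_skip_input(self, rng):
        blk = self._block()
        blk.skipscale.data = np.float32(0.0)
        x = Tensor(rng.standard_normal((1, 8, 2, 2, 2)).astype(np.float32))
        s1 = Tensor(rng.standard_normal((1, 4, 4, 4, 4)).astype(np.float32))
        s2 = Tensor(s1.data + rng.standard_normal(s1.shape).astype(np.float32))
        assert np.array_equal(blk(x, s1).data, blk(x, s2).data)

    def test_resolution_mismatch_rejected(self, rng):
        blk = self._block()
        x = Tensor(np.zeros((1, 8, 2, 2, 2), np.float32))
        with pytest.raises(ValueError, match="resolution"):
            blk(x, Tensor(np.zeros((1, 4, 6, 6, 6), np.float32)))


class TestWaveMorph:
    def test_forward_shape_contract(self, rng):
        m = rng.random((32, 32, 32)).astype(np.float32)
        f = rng.random((32, 32, 32)).astype(np.float32)
        u = wavemorph_forward(m, f, seed=0)
        assert u.shape == (3, 32, 32, 32)

    def test_zero_initialized_head_predicts_identity_transform(self, rng):
        from wavemorph.warp import warp
        model = WaveMorph(seed=1)
        m = rng.random((32, 32, 32)).astype(np.float32)
        f = rng.random((32, 32, 32)).astype(np.float32)
        u = model.predict(m, f)
        assert np.all(u == 0.0)
        assert np.array_equal(warp(m, u), m)

    def test_default_parameter_budget_under_one_million(self):
        assert WaveMorph(seed=0).num_parameters() < 1_000_000

    def test_indivisible_shape_rejected_with_padding_hint(self):
        model = WaveMorph(seed=0)
        with pytest.raises(ValueError, match="pad this axis by 8"):
            model(Tensor(np.zeros((1, 1, 24, 32, 32), np.float32)),
                  Tensor(np.zeros((1, 1, 24, 32, 32), np.float32)))

    def test_every_parameter_receives_finite_gradient(self, rng):
        model = WaveMorph(seed=0)
        m = Tensor(rng.random((1, 1, 32, 32, 32)).astype(np.float32))
        f = Tensor(rng.random((1, 1, 32, 32, 32)).astype(np.float32))
        (model(m, f) ** 2).sum().backward()
        for name, p in model.named_parameters():
            assert p.grad is not None and np.isfinite(p.grad).all(), name

    def test_bitwise_deterministic_forward(self, rng):
        m = rng.random((32, 32, 32)).astype(np.float32)
        f = rng.random((32, 32, 32)).astype(np.float32)
        u1 = WaveMorph(seed=3).predict(m, f)
        u2 = WaveMorph(seed=3).predict(m, f)
        assert np.array_equal(u1, u2)

    def test_dedicated_skip_mode_runs(self, rng):
        cfg = ModelConfig(skip_mode="dedicated")
        m = rng.random((32, 32, 32)).astype(np.float32)
        u = WaveMorph(cfg, seed=0).predict(m, m)
        assert u.shape == (3, 32, 32, 32)


class TestModelConfig:
    def test_dict_round_trip(self):
        cfg = ModelConfig(stage_channels=(8, 12, 16, 24), dysample_groups=1)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(stage_channels=(8, 12, 16))
        with pytest.raises(ValueError):
            ModelConfig(downsampler_kind="stride")
        with pytest.raises(ValueError):
            ModelConfig(upsampler_kind="bicubic")
        with pytest.raises(ValueError):
            ModelConfig(dysample_scope=1.5)
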