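"""Swap the down/upsampling components and compare short training runs.

The wavelet feature-fusion downsampler and the dynamic upsampler are
drop-in replaceable by max-pooling / patch-merging / plain Haar and
nearest / trilinear.  This runs a few steps per combination to show they
share one I/O contract; the printed losses are after identical tiny
budgets (not converged — a smoke comparison, not a benchmark).
"""

from wavemorph import LossConfig, make_pair
from wavemorph.network import ModelConfig
from wavemorph.pipeline import RunConfig, train

pair = make_pair(seed=0, shape=(32, 32, 32))

for down in ("maxpool", "patchmerge", "wavesample", "mswf"):
    for up in ("nearest", "trilinear", "dysample"):
        cfg = RunConfig(
            model=ModelConfig(downsampler_kind=down, upsampler_kind=up),
            loss=LossConfig(similarity="ncc", lam=1.0, ncc_window=5),
            lr=1e-3, epochs=5, seed=0, flip_augment=0.0)
        res = train(cfg, [pair], max_steps=5)
        print(f"down={down:10s} up={up:9s} "
              f"loss {res['history'][0]['loss']:+.4f} -> "
              f"{res['history'][-1]['loss']:+.4f}")
# every cell trains with finite losses and produces a (3,H,W,D) field —
# the grid the full method compares against its fixed-sampler variants
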