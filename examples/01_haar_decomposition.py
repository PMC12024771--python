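"""Decompose a volume into its eight Haar subbands and reconstruct it.

The transform is orthonormal: the subbands hold exactly the input's energy
(Parseval) and invert losslessly — the property that lets the network
downsample without discarding anatomy.
"""

import numpy as np

from wavemorph import dwt3, idwt3, make_phantom
from wavemorph.haar import SUBBAND_KEYS

phantom = make_phantom(seed=0, shape=(32, 32, 32), n_labels=3)
x = phantom.intensity[None]  # add a channel axis

subbands = dwt3(x)
recon = idwt3(subbands)

energy_in = float((x.astype(np.float64) ** 2).sum())
energy_sb = sum(float((subbands[k].astype(np.float64) ** 2).sum())
                for k in SUBBAND_KEYS)

print("subband energies (share of total):")
for k in SUBBAND_KEYS:
    share = float((subbands[k] ** 2).sum()) / energy_in
    print(f"  {k}: {share:8.5f}")
print(f"energy ratio (subbands/input): {energy_sb / energy_in:.8f}")
print(f"max reconstruction error:      {np.abs(recon - x).max():.2e}")
# the LLL subband carries almost all intensity energy (global structure);
# the high-pass bands hold the structure boundaries; the ratio 1.0 and the
# ~1e-7 reconstruction error show the decomposition is lossless
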