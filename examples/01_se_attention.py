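"""Squeeze-and-excitation channel attention on a toy feature map.

Builds an 8x8 map with 4 channels of very different energy, runs the SE
block and prints the per-channel gate weights: channels the excitation
network considers informative keep most of their signal, the rest are
attenuated.  Gates always lie in (0, 1), so SE can only rescale, never
amplify.
"""

import numpy as np

from goatloc import SEConfig, excite, se_block, squeeze

rng = np.random.default_rng(0)
fm = np.stack([rng.normal(0, sigma, size=(8, 8)) for sigma in (0.1, 0.5, 1.0, 3.0)],
              axis=-1)
cfg = SEConfig.random(channels=4, reduction=2, rng=1)

z = squeeze(fm)
s = excite(z, cfg)
out = se_block(fm, cfg)

print("channel means (squeeze):", np.round(z, 3))
print("gate weights (excite):  ", np.round(s, 3))
print("output/input energy:    ", np.round((out ** 2).sum((0, 1)) / (fm ** 2).sum((0, 1)), 3))
print("-> each channel is scaled by its gate squared in energy; shape preserved:",
      out.shape == fm.shape)
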