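"""Feature pyramid walkthrough: MSDRM features through MSF and MSFPN.

Pushes a three-level pyramid (strides 8/16/32) through one focusing block and
then the full neck, printing the shapes at each point.
"""

import numpy as np

from leafdet.msdrm import MSDRM
from leafdet.msfpn import MSF, MSFPN, PyramidLevels
from leafdet.nn import Tensor

rng = np.random.default_rng(0)

x = Tensor(rng.normal(size=(1, 16, 8, 8)))
block = MSDRM(16, rng=rng)
y = block(x)
print(f"MSDRM keeps width and resolution: {x.shape} -> {y.shape}")

levels = PyramidLevels(rng.normal(size=(1, 16, 32, 32)),   # stride 8
                       rng.normal(size=(1, 24, 16, 16)),   # stride 16
                       rng.normal(size=(1, 32, 8, 8)))     # stride 32
msf = MSF((16, 24, 32), width=16, rng=rng)
f = msf(levels)
print(f"MSF focuses three levels at the middle resolution: -> {f.shape} "
      "(concat width 3 x 16, kernels 5/7/9/11 fused residually)")

neck = MSFPN((16, 24, 32), width=16, rng=rng)
low, mid, high = neck(levels)
print("MSFPN detection-scale outputs:")
for name, o, s in (("low", low, 8), ("mid", mid, 16), ("high", high, 32)):
    print(f"  {name:>4s} (stride {s:>2d}): {o.shape}")
print("-> two focusing rounds plus context diffusion: every scale sees both "
      "upsampled and downsampled cross-scale context.")
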