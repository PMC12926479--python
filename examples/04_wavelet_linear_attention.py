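"""The two numerical workhorses: Haar wavelet convolution and linear attention.

Verifies perfect reconstruction of the orthonormal Haar step, the
identity configuration of WTConv, and the K-first associativity of the
kernelised attention against the explicit quadratic evaluation.
"""

import numpy as np

from dfsnet.layers.msla import (
    linear_attention,
    linear_attention_macs,
    quadratic_attention,
    quadratic_attention_macs,
)
from dfsnet.layers.wavelet import WTConv2d, haar_dwt2, haar_idwt2
from dfsnet.nn import Tensor

rng = np.random.default_rng(0)

x = rng.normal(size=(1, 3, 32, 32))
sub = haar_dwt2(Tensor(x))
err = np.abs(haar_idwt2(sub).data - x).max()
energy_in = (x ** 2).sum()
energy_sub = sum((b.data ** 2).sum() for b in sub.bands())
print(f"Haar round-trip max error: {err:.2e}; energy ratio {energy_sub/energy_in:.9f}")

wt = WTConv2d(3, levels=2)
wt.init_identity()
print(f"identity-initialised WTConv max deviation: "
      f"{np.abs(wt(Tensor(x.astype(np.float32))).data - x).max():.2e}")

n, d = 256, 32
q, k, v = (Tensor(rng.normal(size=(n, d))) for _ in range(3))
dev = np.abs(linear_attention(q, k, v).data - quadratic_attention(q, k, v).data).max()
print(f"\nK-first vs quadratic attention, N={n}, d={d}: max dev {dev:.2e}")
print(f"multiply-accumulates: K-first {linear_attention_macs(n, d):,} "
      f"vs quadratic {quadratic_attention_macs(n, d):,}")
print("Doubling N doubles the K-first cost but quadruples the quadratic one.")
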