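"""Bi-level routing attention versus dense attention.

Runs the BRA forward pass on a random 8x8x4 feature map.  With k = S^2
every region is routed and the output must equal full attention; with
k = 1 each query region attends to only its single best-matching region,
a genuinely sparser computation.
"""

import numpy as np

from uwenhance.detection import BraSpec, bra_forward, dense_attention_with_lce

rng = np.random.default_rng(0)
c = 4


def spec(s, k):
    return BraSpec(
        x=rng.standard_normal((8, 8, c)),
        regions=s,
        top_k=k,
        wq=rng.standard_normal((c, c)) * 0.5,
        wk=rng.standard_normal((c, c)) * 0.5,
        wv=rng.standard_normal((c, c)) * 0.5,
        lce_kernel=rng.standard_normal((5, 5, c)) * 0.1,
    )


full = spec(s=2, k=4)
print("k = S^2 (all regions routed):")
print("  max |BRA - dense attention| =", np.abs(bra_forward(full) - dense_attention_with_lce(full)).max())

sparse = spec(s=2, k=1)
print("k = 1 (each query region keeps its single best region):")
print("  max |BRA - dense attention| =", np.abs(bra_forward(sparse) - dense_attention_with_lce(sparse)).max())
print("\nThe first difference is at float precision; the second is large because")
print("routing really prunes three quarters of the key-value pairs.")
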