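"""Restriction-point behavior under saturating CDK4/6 inhibition.

Palbociclib (0.1 uM) is added at t = 0 to 100 asynchronously cycling cells;
each cell's cycle progress at drug addition is estimated from the composite
cyclin signal and related to its division outcome in Generations 1 and 2.
"""

import numpy as np

from lineagesim.protocols import restriction_point_protocol

out = restriction_point_protocol(dose=0.1, n0=100, seed=3)

fr, dv = out["progress"], out["divided_gen1"]
print("Gen-1 division outcome vs estimated cycle progress at drug addition:")
for lo, hi in [(0, 0.05), (0.05, 0.1), (0.1, 0.2), (0.2, 0.5), (0.5, 1.0)]:
    sel = (fr >= lo) & (fr < hi)
    if sel.any():
        print(f"  progress {lo:.2f}-{hi:.2f}: n={sel.sum():3d}  "
              f"P(divide) = {dv[sel].mean():.2f}")
print(f"\nGen-1 probability crosses 0.5 at progress "
      f"{out['gen1_crossing']:.3f} (~10% of the cycle: cells past the "
      "restriction point complete their division despite CDK4/6 inhibition)")
print(f"Gen-2 division probability max = {out['gen2_max_probability']:.2f} "
      "(daughters are born with a closed CDK4/6 gate: the response is "
      "cytostatic after one round)")
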