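"""Two-pool MT signal formation under the clinical 1.5 T protocol.

Evaluates the saturation rates and the steady-state MT-weighted signal
for white- and gray-matter-like voxels, and shows the monotone signal
loss with increasing macromolecular proton fraction that the single-point
inversion relies on.
"""

import numpy as np

from mpfmap import TwoPoolConstraints, protocol_preset, saturation_rates, two_pool_signal

protocols = protocol_preset()
mtw = protocols["mtw"]
constraints = TwoPoolConstraints()

wf, wb = saturation_rates(mtw.mt_pulse, constraints, r1=1.5)
print(f"saturation rates at R1 = 1.5 1/s: free pool {wf:.3f} 1/s, "
      f"bound pool {wb:.1f} 1/s")
print("-> the off-resonance pulse saturates the semisolid pool ~100x more "
      "strongly than water; cross-relaxation carries that saturation into "
      "the measured water signal.\n")

for label, f, r1 in (("white matter", 0.130, 1.5), ("gray matter", 0.064, 0.9)):
    s = two_pool_signal(f, r1, mtw, constraints)
    s0 = two_pool_signal(0.0, r1, mtw, constraints)
    print(f"{label}: MPF {100*f:.1f}% -> MTw signal {s:.4f} "
          f"({100*(1-s/s0):.1f}% below the MPF=0 signal)")

fs = np.linspace(0.0, 0.20, 5)
sig = two_pool_signal(fs, 1.2, mtw, constraints)
print("\nsignal vs MPF at R1 = 1.2 1/s:")
for f, s in zip(fs, sig):
    print(f"  MPF {100*f:5.1f}%  signal {s:.5f}")
print("-> strictly decreasing in MPF: the voxel-wise inversion has a "
      "unique root.")
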