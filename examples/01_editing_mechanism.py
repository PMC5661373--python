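"""The J-difference editing mechanism on a two-spin model of GABA.

A weakly coupled AX pair (3.01 / 1.89 ppm, J = 7.3 Hz) stands in for the
GABA 4-CH2/3-CH2 coupling.  At TE = 68 ms ~ 1/(2J) the 3.01 ppm doublet
has dephased almost completely in the plain echo; placing the selective
inversion on the 1.89 ppm partner refocuses the J-evolution and restores
it.  The cycle difference therefore isolates the coupled resonance.
"""

import numpy as np

from gabaedit import SequenceParams, SpinSystem, simulate_press_basing

J = 7.3
params = SequenceParams()
ax = SpinSystem("AX", (3.01, 1.89), np.array([[0.0, J], [J, 0.0]]))

ref = simulate_press_basing(ax, params.replace(te_ms=1e-9), None,
                            coupling="weak", detect=[0]).samples[0].real
plain = simulate_press_basing(ax, params, None,
                              coupling="weak", detect=[0]).samples[0].real
edited = simulate_press_basing(ax, params, 1.89,
                               coupling="weak", detect=[0]).samples[0].real

print(f"3.01 ppm in-phase amplitude, TE -> 0 reference : {ref:8.4f}")
print(f"plain echo at TE = {params.te_ms:.0f} ms               : {plain:8.4f}"
      f"   (cos(pi*J*TE) = {np.cos(np.pi * J * params.te_s):.4f})")
print(f"editing pulse on the 1.89 ppm partner          : {edited:8.4f}")
print(f"cycle difference (plain - edited)              : {plain - edited:8.4f}")
print()
print("The plain echo retains ~1% of the doublet; the editing pulse restores")
print("it fully, so the difference carries essentially the whole resonance —")
print("that is the signal J-difference editing extracts from under creatine.")
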