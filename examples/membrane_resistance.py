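"""Membrane resistance along the immature action potential.

Simulates a noise-free immature AP while recording the total ionic
current, computes the pointwise membrane resistance dV/dI, and reports
which 100-ms window of the 701-ms network input contains the
high-resistance plateau phase — the part of the AP where the net current
is nearly constant, so that small perturbations (like I_Kr block) have
their largest effect.
"""

import numpy as np

from aptrans import simulator as sim
from aptrans.ablation import default_windows, locate_high_resistance_window
from aptrans.simulator import membrane_resistance_series

protocol = sim.PacingProtocol(stim_amplitude=0.0, cycle_length_ms=982.0,
                              conditioning_beats=8, noisy_beats=4)
trace = sim.simulate_trace(sim.immature_params(), protocol, record_current=True)
ups = sim.detect_upstrokes(trace.voltage)
u = ups[-2]
v = trace.voltage[u - 5:u - 5 + 701]
i = trace.current[u - 5:u - 5 + 701]

r, capped = membrane_resistance_series(v, i)
plateau = v > v.min() + 0.25 * (v.max() - v.min())
print("median |dV/dI| per 100-ms window (capped at 1e4, plateau samples):")
for a, b in default_windows(701):
    sel = plateau[a:b]
    score = (f"{np.median(np.abs(r[a:b][sel])):10.1f}" if sel.mean() >= 0.5
             else "  diastolic")
    print(f"  [{a:3d},{b:3d}) ms : {score}")
win = locate_high_resistance_window(v, i)
print(f"\nhigh-membrane-resistance plateau window: [{win[0]}, {win[1]}) ms")
print("note: the diastolic (pacemaker) phase also has near-zero net "
      "current — its windows are excluded above")
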