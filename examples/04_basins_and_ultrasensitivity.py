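"""Basin maps and the minimal thalamic kick that flips the switch.

Just below the fold the high-firing basin already covers most of the
initial-condition plane, and a modest transient activation of the VPL
relay is enough to flip the loop permanently; deeper below the fold the
required kick shrinks further (ultrasensitivity).
"""

import numpy as np

from tcloop import ModelParams, map_basins_2d, switching_threshold

axis = np.linspace(0.0, 100.0, 41)
print("high-firing basin fraction (S0/V0 grid, T(0)=80 Hz):")
for a in (1.0, 0.26, 0.15):
    grid = map_basins_2d(ModelParams(a=a), T_init=80.0,
                         s_grid=axis, v_grid=axis)
    frac = grid.area_fraction.get("high", 0.0)
    print(f"  a={a:>4}: {frac:6.1%}")

print("\nminimal VPL activation (pure-V kick from baseline) that flips")
print("the switch:")
for a in (0.26, 0.2, 0.1):
    thr = switching_threshold(ModelParams(a=a))
    print(f"  a={a:>4}: {thr:6.2f} Hz")
thr1 = switching_threshold(ModelParams(a=1.0))
print(f"  a= 1.0: {'no switch (monostable)' if thr1 is None else thr1}")

print("\nThe basin of the pathological high-firing state widens and the")
print("switching threshold falls as GABAergic efficacy decreases.")
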