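"""Locate the saddle-node fold and sweep the equilibrium branches.

The GABAergic efficacy a is the bifurcation parameter: above the fold
a-hat the baseline is the only equilibrium; below it a stable
high-firing branch and an unstable middle branch appear.
"""

import numpy as np

from tcloop import ModelParams, find_threshold, sweep

params = ModelParams()
fold = find_threshold(params)
print(f"saddle-node fold: a_hat = {fold.a_hat:.5f} ({fold.status})")

diagram = sweep(params, np.round(np.arange(0.20, 0.30, 0.01), 3))
print("\n  a      branches (V in Hz, * = stable)")
for a, eqs in zip(diagram.a_values, diagram.branches):
    desc = "  ".join(
        f"{eq.V:6.2f}{'*' if eq.stability == 'stable' else ' '}"
        for eq in eqs)
    print(f"  {a:.2f}   {desc}")

print("\nFor each variant that freezes one inhibitory effect the fold")
print("never moves left:")
for variant in ("fixed_h", "fixed_g"):
    res = find_threshold(ModelParams(variant=variant))
    where = f"a_hat = {res.a_hat:.5f}" if res.a_hat else res.status
    print(f"  {variant:>8}: {where}")
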