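"""Locate and classify every fixed point at a given inhibition level.

Weak inhibition (a=0.2) yields three equilibria: the stable baseline,
an unstable middle state (the switching threshold) and the stable
high-firing state.  Full inhibition (a=1) leaves only the baseline.
"""

from tcloop import ModelParams, find_equilibria

for a in (0.2, 1.0):
    print(f"a = {a}:")
    for eq in find_equilibria(ModelParams(a=a)):
        lead = ", ".join(f"{ev.real:+.3f}" for ev in eq.eigenvalues)
        print(f"  {eq.label:>4}  S={eq.S:8.4f}  T={eq.T:8.4f}  "
              f"V={eq.V:8.4f} Hz  {eq.stability:>8}  Re(eig)=[{lead}] 1/s")
    print()

print("Stability follows the Jacobian eigenvalues: all negative real")
print("parts -> stable.  The unstable middle state separates the basins")
print("of the baseline and high-firing attractors.")
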