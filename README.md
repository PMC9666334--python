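# tcloop

Bistable-switch analysis of a thalamocortical pain-processing loop.

`tcloop` implements and analyses a three-variable firing-rate model of
the circuit formed by the primary somatosensory cortex (SC), the
thalamic reticular nucleus (TRN) and the ventroposterolateral thalamic
nucleus (VPL).  The hypothesis under study is that chronic widespread
pain (as in fibromyalgia) can arise as a *dynamical disease*: when the
efficacy of the TRN's GABAergic inhibition drops below a critical
level, the loop acquires a second, high-firing stable state, and a
small transient nociceptive input can then flip the circuit into that
state permanently.  The package is for computational neuroscientists
and systems biologists who want to reproduce, probe or extend that
analysis.

## Model

Mean firing rates S (cortex), T (reticular nucleus) and V (thalamic
relay), all in Hz, evolve as

    τ·dS/dt + S = f(V)
    τ·dT/dt + T = f₂(V + S)
    τ·dV/dt + V = g(aT) · Sᵖ / (Sᵖ + h(aT)ᵖ)

with Hill-type interaction functions

    f(x)  = m₁·xᵖ/(eᵖ + xᵖ)        (excitation of SC by VPL)
    f₂(x) = m₂·xᵖ/(eᵖ + xᵖ)        (excitation of TRN by VPL and SC)
    g(u)  = m₁/(1 + (u/e)ᵖ)        (TRN lowers the VPL gain)
    h(u)  = e₀ + m₂·uᵖ/(eᵖ + uᵖ)   (TRN shifts the VPL half-activation)

Nominal parameters: τ = 0.5 s, m₁ = 100 Hz, m₂ = 80 Hz, e = e₀ = 20 Hz,
p = 2.5.  The dimensionless coefficient a ∈ [0, 1] scales the strength
of GABAergic transmission and is the bifurcation parameter.  Variants:
`reversed_gaba` (TRN action turned excitatory, V-equation f(S+T)),
`fixed_g` and `fixed_h` (one inhibitory effect frozen at its basal
value).

The package integrates trajectories (adaptive Dormand–Prince or
fixed-step RK4), finds all equilibria by reducing the steady state to a
scalar root problem in V, classifies their stability from the analytic
Jacobian, locates the saddle-node fold â by bisection on the
equilibrium count, and maps basins of attraction on grids of initial
conditions.

## Worked example

```python
import numpy as np
from tcloop import ModelParams, find_threshold, find_equilibria, simulate

params = ModelParams()                    # nominal values, a = 1
print(find_threshold(params).a_hat)       # 0.2642097473144531

weak = params.with_a(0.2)                 # inhibition well below the fold
for eq in find_equilibria(weak):
    print(eq.label, round(eq.S, 2), round(eq.T, 2), round(eq.V, 2),
          eq.stability)
# zero 0.0 0.0 0.0 stable
# mid 10.72 38.2 8.57 unstable
# high 92.0 79.44 53.12 stable

traj = simulate([0, 0, 15], weak, horizon=60, dt_out=1)   # 15 Hz V-kick
print(np.round(traj.final, 3))            # [91.997 79.44  53.117]
```

The fold sits at â ≈ 0.264: for stronger inhibition the 0 Hz baseline
is the only steady state, while below it an unstable middle state
(V ≈ 8.6 Hz at a = 0.2) separates the baseline from a high-firing
attractor (S ≈ 92 Hz).  The last lines show the switch flipping: a
transient 15 Hz thalamic activation from rest ends on the high-firing
state, and stays there.

The scripts in `examples/` walk through each capability (trajectory
simulation, equilibrium analysis, bifurcation diagrams, basin maps and
the ultrasensitive switching threshold).  The same analyses are
available from the shell:

```sh
tcloop equilibria --config my.yaml
tcloop bifurcation --a-min 0 --a-max 0.5 --a-step 0.001
tcloop basins --t-init 80 --resolution 101
tcloop figure2 --out out/ --png
```

Config files (YAML or JSON) override any subset of
`tau, m1, m2, e, e0, p, a, variant` under a `params:` block.

### Output schema

CSV artifacts use 10 significant digits.  `bifurcation` writes columns
`a, branch_id, S, T, V, stability` plus a JSON summary `{a_hat}`;
`basins` writes `S0, V0, label` plus per-label area fractions;
`simulate` writes `time, S, T, V`.

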