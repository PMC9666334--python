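# Methods

## Model and assumptions

The loop couples three lumped neural populations by first-order rate
equations with a single shared time constant τ: the somatosensory
cortex S is excited by the thalamic relay V; the reticular nucleus T is
excited by both V and S; and V is excited by S while inhibited by T.
All input–output relations are Hill functions — saturating, zero at
zero input, half-maximal at the input rate e — reflecting measured
neuronal dose–response curves.  Baseline firing is taken as 0 Hz, so
the origin is an equilibrium of every variant by construction, and
(because the Hill exponent p > 1 makes every Hill derivative vanish at
zero) it is always stable, with the threefold eigenvalue −1/τ.

TRN inhibition acts on the VPL response in the two ways reported for
inhibitory modulation of neuronal input–output curves: it divisively
lowers the maximal rate (the decreasing Hill gain g) and shifts the
half-activation rightward (the increasing function h).  Both effects
are driven by a·T, where the efficacy a ∈ [0, 1] is the bifurcation
parameter.  The basal half-activation e₀ is not separately specified by
the nominal table; it is pinned to e by the requirement that at a = 0
the V-equation reduce exactly to the same Hill form that drives S.  It
remains an independent config field for exploration.

The model has no external input term: a nociceptive volley is
represented as an initial-condition perturbation (a displacement along
a ray from the baseline state), which is what `switching_threshold`
quantifies.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| τ | population response lag | 0.5 | s |
| m₁ | max rate of excitatory fibers | 100 | Hz |
| m₂ | max rate of inhibitory fibers | 80 | Hz |
| e | half-activation input rate | 20 | Hz |
| e₀ | basal half-activation in h | e | Hz |
| p | Hill coefficient | 2.5 | — |
| a | GABAergic efficacy | 1.0 | — |

Parameter validation is eager: `ModelParams` rejects non-positive
rates, p ≤ 0 or a outside [0, 1] at construction, so the numerics never
see invalid values.  m₂ = 0 is allowed (it severs the TRN branch and is
a useful degenerate case: a then has no effect at all).

## Equilibrium analysis

At steady state, S* = f(V) and T* = f₂(V + f(V)) are explicit in V, so
every fixed point of the 3-D system is a root of a scalar residual
R(V).  `find_equilibria` scans R on a 5000-point grid over
[0, 1.05·m₁] (no equilibrium can exceed the Hill ceiling m₁), brackets
sign changes and refines each by plain bisection to a 1e-10 Hz
interval; the origin, where R(V) ≈ −V locally, is appended explicitly.
Roots closer than 1e-6 Hz are merged.  If the non-origin sign-change
count comes out odd (possible only by tangency at a fold), the grid is
refined 4× up to three times before a `ResolutionError` is raised.
Stability comes from the eigenvalues of the analytic Jacobian; real
parts within ±1e-9 of zero trigger a "marginal" warning instead of a
silent call, which matters only exactly at the fold.

The fold â is located by bisection on the indicator "at least three
equilibria", to an interval width of 1e-5 in a.  Because the scalar
reduction makes per-a equilibrium counting cheap, this is both simpler
and more robust than continuation with fold detection; the computed
value is invariant to 1e-4 under doubling of the scan resolution and
was cross-checked against a direct double-root solve (R = R' = 0).
With nominal parameters â = 0.26421.

In branch sweeps, a count-preserving step in a inherits branch ids by
V-rank (equilibria are componentwise ordered and branches cannot
cross); distance-based nearest-neighbour matching is used only when the
count changes.  Pure distance matching with a fixed cap breaks at
coarse grid steps because the middle branch's T-component moves by
~20 Hz per 0.01 of a.

## Integration and attractor classification

Trajectories use scipy's adaptive Dormand–Prince RK45 at rtol 1e-8 /
atol 1e-10 (stiffness is mild — one shared τ); a fixed-step RK4 mode
exists for byte-identical reruns.  States are clamped to the
non-negative orthant after each step: adaptive steps can undershoot
zero by floating-point amounts, and Hill terms are undefined for
negative arguments at non-integer p.

`settle` declares convergence only when the state is within 0.5 Hz
(max-norm) of a stable equilibrium *and* the local speed is below
1e-3 Hz/s, so a slow passage near the unstable saddle is never
mislabelled; the fallback after 200 s is the explicit label
`unresolved`, expected only within a cell-width of the separatrix.

Basin maps integrate all grid cells at once as a single vectorised
fixed-step RK4 batch (dt = 0.01 s, convergence re-checked every 0.5 s,
converged cells retired).  With τ = 0.5 s the step is deep inside the
stability and accuracy region, and the batch formulation keeps a
101×101 map in the seconds range on one core.  The batch classifier
applies the same proximity+speed rule as the scalar `settle` and is
validated against it on random cells in the test suite.  2-D maps fix
the *initial* T and integrate the full 3-D flow — they are
initial-condition sections, not frozen-T dynamics — though a frozen-T
mode is exposed for comparison.

## Design choices that were genuinely open

- **Fold by count-bisection, not continuation.**  See above; a
  pseudo-arclength continuation would add machinery without adding
  robustness here.
- **e₀ = e.**  Forced by the a = 0 reduction; kept overridable.
- **The reversed-GABA variant reuses f with (m₁, e).**  The variant's
  V-equation is written with the same symbol f as the S-equation and no
  separate constants, so the same Hill function is used.  Note that a
  then disappears from the dynamics entirely, which is why bistability
  over the whole of [0, 1] is exact for this variant rather than
  approximate.
- **Default basin grid 101×101 over [0, 100] Hz², T(0) = 80 Hz.**  The
  TRN ceiling m₂ = 80 Hz maximises initial inhibition and hence gives
  the most conservative (widest-baseline) basin estimate; the fixed
  grid makes area fractions comparable across runs.
- **Representative bistable exemplars a = 0.26 and a = 0.15** for basin
  panels, chosen just below and well below the fold.

## Findings the tests pin down

- â = 0.26421 (nominal parameters).  The high equilibrium at a = 0.26
  sits at (S, T, V) = (72.24, 78.65, 29.32) Hz; the often-quoted
  "V ≈ 40 Hz, S ≈ 80 Hz just below the fold" corresponds under these
  equations to a ≈ 0.24 rather than 0.26.  The package reports what the
  equations give.
- Freezing the half-activation shift (fixed_h) moves the fold right, to
  â = 0.547.  Freezing the gain at m₁ (fixed_g) removes so much
  inhibition that bistability persists over the entire interval — the
  fold leaves [0, 1] altogether rather than merely shifting right.
- The reversed-GABA variant is bistable at every a, with a high-firing
  basin at least as large as the standard variant's at matched a.
- The switch is hysteretic and one-way: raising a above â collapses the
  high state to baseline, and lowering a again does not re-excite it
  without a new perturbation.

## What the numerics do and do not show

All results are properties of the stated ODE model at the stated
parameters.  The model lumps each brain area into one scalar rate, has
no noise, no conduction delays, no receptor kinetics and no explicit
nociceptive input pathway; passing tests therefore demonstrate the
internal consistency and robustness claims of the *model*, not clinical
facts about pain circuits.  Boundaries of basins are resolved only to
one grid cell; fractions quoted on the default grid change by under two
percentage points when the resolution is doubled.
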