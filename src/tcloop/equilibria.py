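"""Fixed-point location via scalar reduction, plus stability classification.

At steady state the S- and T-equations give explicit closed forms
S* = f(V) and T* = f2(V + S*), so every equilibrium of the 3-D system is
a root of the scalar residual

    R(V) = drive_V(S*(V), T*(V)) - V

where drive_V is the right side of the V-equation for the chosen model
variant.  Roots are bracketed by a sign-change scan on a fine grid and
refined by bisection; stability comes from the eigenvalues of the
analytic Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import jacobian, rhs, vpl_drive
from .kinetics import ModelParams, hill_f

__all__ = [
    "Equilibrium",
    "ResolutionError",
    "reduce_to_scalar",
    "find_equilibria",
    "stable_equilibria",
]

#: Real-part threshold separating stable from unstable eigenvalues (1/s).
STABILITY_TOL = 1e-9
#: Roots closer than this (Hz) are treated as duplicates.
DEDUP_TOL = 1e-6
#: Bisection refinement width on V (Hz).
ROOT_TOL = 1e-10


class ResolutionError(RuntimeError):
    """Scan resolution insufficient to separate roots (near-tangency)."""


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the loop system with its linear stability."""

    state: np.ndarray          # (S, T, V) in Hz
    stability: str             # "stable" | "unstable"
    eigenvalues: np.ndarray    # three complex rates, 1/s
    label: str                 # "zero" | "mid" | "high" | ...

    @property
    def S(self) -> float:
        return float(self.state[0])

    @property
    def T(self) -> float:
        return float(self.state[1])

    @property
    def V(self) -> float:
        return float(self.state[2])

    def to_dict(self) -> dict:
        return {
            "S": self.S,
            "T": self.T,
            "V": self.V,
            "stability": self.stability,
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "label": self.label,
        }


def _steady_ST(V, params: ModelParams):
    """Closed-form steady-state S and T for a given V."""
    S = hill_f(V, params.m1, params.e, params.p)
    T = hill_f(np.asarray(V) + np.asarray(S), params.m2, params.e, params.p)
    return S, T


def reduce_to_scalar(V, params: ModelParams):
    """Steady-state residual R(V); zeros are exactly the equilibria.

    Vectorised over V (Hz); the residual is in Hz.
    """
    arr = np.asarray(V, dtype=float)
    if np.any(arr < 0):
        raise ValueError("V must be non-negative")
    S, T = _steady_ST(arr, params)
    out = vpl_drive(S, T, params) - arr
    return float(out) if np.ndim(V) == 0 else out


def _bisect_root(lo: float, hi: float, params: ModelParams) -> float:
    """Plain bisection of R on a sign-change bracket, to ROOT_TOL in V."""
    f_lo = reduce_to_scalar(lo, params)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hi - lo < ROOT_TOL:
            return mid
        f_mid = reduce_to_scalar(mid, params)
        if f_mid == 0.0:
            return mid
        if (f_lo < 0) != (f_mid < 0):
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


def _scan_roots(params: ModelParams, n_grid: int, v_max: float) -> list[float]:
    """Sign-change scan of R on (0, v_max]; the origin root is implicit."""
    # R(V) ~ -V near 0 (p > 1 keeps the drive sub-linear), so start a
    # hair above zero to avoid re-detecting the exact origin root.
    grid = np.linspace(v_max / n_grid * 1e-3, v_max, n_grid)
    res = reduce_to_scalar(grid, params)
    sign = np.sign(res)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    roots = [_bisect_root(grid[i], grid[i + 1], params) for i in idx]
    roots += [float(grid[i]) for i in np.nonzero(res == 0.0)[0]]
    return sorted(roots)


def _classify(state: np.ndarray, params: ModelParams) -> tuple[str, np.ndarray]:
    eig = np.linalg.eigvals(jacobian(state, params))
    re = eig.real
    if np.any(np.abs(re) <= STABILITY_TOL):
        warnings.warn(
            "marginal eigenvalue (|Re| <= 1e-9); parameters sit at or "
            "numerically indistinguishable from a fold",
            RuntimeWarning,
            stacklevel=3,
        )
    stability = "stable" if np.all(re < -STABILITY_TOL) else "unstable"
    return stability, eig


def _assign_labels(equilibria: list[Equilibrium]) -> list[Equilibrium]:
    from dataclasses import replace as dc_replace

    n = len(equilibria)
    labelled = []
    for i, eq in enumerate(equilibria):
        if i == 0:
            label = "zero"
        elif i == n - 1:
            label = "high"
        else:
            label = "mid" if n == 3 else f"mid{i}"
        labelled.append(dc_replace(eq, label=label))
    return labelled


def find_equilibria(
    params: ModelParams,
    n_grid: int = 5000,
    v_max: float | None = None,
    max_refinements: int = 3,
) -> list[Equilibrium]:
    """All fixed points of the system, sorted by increasing V.

    Scans the scalar residual on ``n_grid`` points over [0, v_max]
    (default 1.05*m1, above the Hill ceiling no equilibrium can exceed),
    brackets sign changes, bisects each to ~1e-10 Hz, reconstructs the
    full (S, T, V) state and classifies stability from the Jacobian
    eigenvalues.  The origin — always an equilibrium — is always in the
    returned list.  If the scan finds an even number of non-origin sign
    changes (a near-tangency at a fold), the grid is refined up to
    ``max_refinements`` times before raising :class:`ResolutionError`.
    """
    if v_max is None:
        v_max = 1.05 * params.m1

    grid_n = n_grid
    for _ in range(max_refinements + 1):
        roots = _scan_roots(params, grid_n, v_max)
        # with the origin, the total count must be odd
        if len(roots) % 2 == 0:
            break
        grid_n *= 4
    else:
        raise ResolutionError(
            f"odd non-origin root count persists at n_grid={grid_n // 4}; "
            "parameters are likely at a tangency (fold)"
        )

    all_v = [0.0] + roots
    dedup: list[float] = []
    for v in all_v:
        if not dedup or v - dedup[-1] > DEDUP_TOL:
            dedup.append(v)

    out = []
    for v in dedup:
        S, T = _steady_ST(v, params)
        state = np.array([float(S), float(T), float(v)])
        resid = float(np.max(np.abs(rhs(state, params))))
        if resid > 1e-7:  # Hz/s; generous vs the 1e-10 Hz root width
            warnings.warn(
                f"equilibrium residual {resid:.2e} Hz/s exceeds tolerance",
                RuntimeWarning,
                stacklevel=2,
            )
        stability, eig = _classify(state, params)
        out.append(Equilibrium(state=state, stability=stability,
                               eigenvalues=eig, label=""))
    return _assign_labels(out)


def stable_equilibria(params: ModelParams, **kwargs) -> list[Equilibrium]:
    """The stable subset of :func:`find_equilibria`."""
    return [eq for eq in find_equilibria(params, **kwargs)
            if eq.stability == "stable"]
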