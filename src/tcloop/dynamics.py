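"""Right-hand side and analytic Jacobian of the loop ODE system.

State ordering is (S, T, V) throughout:

    tau*dS/dt + S = f(V)            f: increasing Hill, max m1
    tau*dT/dt + T = f2(V + S)       f2: increasing Hill, max m2
    tau*dV/dt + V = g(aT) * S**p / (S**p + h(aT)**p)

with g decreasing and h increasing in the inhibitory drive a*T.  The
``reversed_gaba`` variant replaces the V-equation by
tau*dV/dt + V = f(S + T); ``fixed_g`` freezes g at m1 and ``fixed_h``
freezes h at e0.
"""

from __future__ import annotations

import numpy as np

from .kinetics import ModelParams, dhill, gain_g, hill_f, shift_h

__all__ = ["rhs", "jacobian", "vpl_drive"]


def vpl_drive(S, T, params: ModelParams):
    """Steady-state input to V, i.e. the right side of the V-equation.

    Vectorised over S and T.
    """
    p = params.p
    v = params.variant
    if v == "reversed_gaba":
        return hill_f(np.asarray(S) + np.asarray(T), params.m1, params.e, p)
    aT = params.a * np.asarray(T, dtype=float)
    if v == "fixed_g":
        g = params.m1
    else:
        g = gain_g(aT, params)
    if v == "fixed_h":
        h = params.e0
    else:
        h = shift_h(aT, params)
    Sp = np.power(np.asarray(S, dtype=float), p)
    return g * Sp / (Sp + np.power(h, p))


def _rates(S, T, V, params: ModelParams):
    """Componentwise time derivatives; broadcasts over array states."""
    f_of_V = hill_f(V, params.m1, params.e, params.p)
    f2 = hill_f(np.asarray(V) + np.asarray(S), params.m2, params.e, params.p)
    drive = vpl_drive(S, T, params)
    inv_tau = 1.0 / params.tau
    return (
        (f_of_V - S) * inv_tau,
        (f2 - T) * inv_tau,
        (drive - V) * inv_tau,
    )


def rhs(state, params: ModelParams) -> np.ndarray:
    """Time derivative (dS, dT, dV) in Hz/s at a non-negative state.

    Raises ValueError for negative components (Hill terms are undefined
    there for non-integer p).
    """
    arr = np.asarray(state, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"state must be componentwise non-negative, got {state}")
    dS, dT, dV = _rates(arr[0], arr[1], arr[2], params)
    return np.array([dS, dT, dV], dtype=float)


def rhs_clamped(state, params: ModelParams) -> np.ndarray:
    """rhs with tiny negative floating-point undershoots clamped to 0.

    Used inside integrators, where adaptive steps may momentarily poke
    below the invariant boundary.
    """
    arr = np.maximum(np.asarray(state, dtype=float), 0.0)
    dS, dT, dV = _rates(arr[0], arr[1], arr[2], params)
    return np.array([dS, dT, dV], dtype=float)


def jacobian(state, params: ModelParams) -> np.ndarray:
    """Analytic 3x3 Jacobian of :func:`rhs` at a non-negative state.

    At the origin with p > 1 every Hill derivative vanishes and the
    Jacobian is diag(-1/tau); with p < 1 the Hill derivatives diverge
    there and the formula is evaluated as written.
    """
    arr = np.asarray(state, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"state must be componentwise non-negative, got {state}")
    S, T, V = arr
    m1, m2, e, e0, p, a, tau = (
        params.m1, params.m2, params.e, params.e0, params.p, params.a, params.tau,
    )
    inv_tau = 1.0 / tau

    J = np.zeros((3, 3))
    # S-row: dS/dt = (f(V) - S)/tau
    J[0, 0] = -inv_tau
    J[0, 2] = dhill(V, m1, e, p) * inv_tau
    # T-row: dT/dt = (f2(V+S) - T)/tau
    df2 = dhill(V + S, m2, e, p)
    J[1, 0] = df2 * inv_tau
    J[1, 1] = -inv_tau
    J[1, 2] = df2 * inv_tau

    variant = params.variant
    if variant == "reversed_gaba":
        df = dhill(S + T, m1, e, p)
        J[2, 0] = df * inv_tau
        J[2, 1] = df * inv_tau
        J[2, 2] = -inv_tau
        return J

    aT = a * T
    if variant == "fixed_g":
        g, dg = m1, 0.0
    else:
        g = gain_g(aT, params)
        # g = m1*e^p/(e^p + u^p) => g' = -m1*p*e^p*u^(p-1)/(e^p+u^p)^2
        dg = -dhill(aT, m1, e, p)
    if variant == "fixed_h":
        h, dh = e0, 0.0
    else:
        h = shift_h(aT, params)
        dh = dhill(aT, m2, e, p)

    Sp = S**p
    hp = h**p
    D = Sp + hp
    dG_dS = g * p * S ** (p - 1.0) * hp / D**2 if S > 0 else (
        0.0 if p > 1 else np.inf)
    dG_dT = a * (dg * Sp / D - g * Sp * p * h ** (p - 1.0) * dh / D**2)
    J[2, 0] = dG_dS * inv_tau
    J[2, 1] = dG_dT * inv_tau
    J[2, 2] = -inv_tau
    return J
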