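"""Trajectory integration and attractor classification.

The workhorse is scipy's adaptive Dormand-Prince integrator at tight
tolerances (rtol 1e-8, atol 1e-10); a fixed-step RK4 mode is available
for bit-reproducible output across platforms.  ``settle`` integrates
until the state is simultaneously close to a stable equilibrium and
nearly stationary, which avoids mislabelling slow passages near the
unstable saddle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import rhs_clamped
from .equilibria import Equilibrium, stable_equilibria
from .kinetics import ModelParams

__all__ = ["Trajectory", "IntegrationError", "simulate", "settle", "rk4_march"]

log = logging.getLogger(__name__)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: Max-norm proximity to an equilibrium for convergence (Hz).
TOL_ATTRACT = 0.5
#: Max-norm speed bound for convergence (Hz/s).
TOL_SPEED = 1e-3
#: Default settling horizon (s).
MAX_HORIZON = 200.0


class IntegrationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """A sampled solution of the loop ODEs."""

    times: np.ndarray                 # seconds, strictly increasing
    states: np.ndarray                # shape (len(times), 3), columns S, T, V
    params: ModelParams
    converged_to: Equilibrium | None = None

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "S": self.states[:, 0],
             "T": self.states[:, 1], "V": self.states[:, 2]}
        )


def rk4_march(state: np.ndarray, params: ModelParams, duration: float,
              dt: float) -> np.ndarray:
    """Fixed-step classical RK4 over ``duration``; vectorised over columns.

    ``state`` has shape (3,) or (3, n); negatives from floating-point
    undershoot are clamped to the invariant boundary each step.
    """
    y = np.maximum(np.asarray(state, dtype=float), 0.0)
    n_steps = max(1, int(round(duration / dt)))
    h = duration / n_steps

    from .dynamics import _rates

    def f(y):
        yc = np.maximum(y, 0.0)
        dS, dT, dV = _rates(yc[0], yc[1], yc[2], params)
        return np.array([dS, dT, dV])

    for _ in range(n_steps):
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        y = np.maximum(y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
    return y


def simulate(
    initial,
    params: ModelParams,
    horizon: float,
    dt_out: float = 0.1,
    method: str = "adaptive",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    dt_fixed: float = 0.01,
) -> Trajectory:
    """Integrate the loop ODEs from ``initial`` over ``horizon`` seconds.

    ``method="adaptive"`` uses Dormand-Prince RK45 with the given
    tolerances; ``method="rk4"`` uses fixed steps of ``dt_fixed`` for
    byte-identical reruns.  Output is sampled every ``dt_out`` seconds.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if dt_out <= 0:
        raise ValueError("dt_out must be > 0")
    y0 = np.asarray(initial, dtype=float)
    if y0.shape != (3,):
        raise ValueError("initial state must have three components (S, T, V)")
    if np.any(y0 < 0):
        raise ValueError("initial state must be componentwise non-negative")

    t_eval = np.arange(0.0, horizon + 0.5 * dt_out, dt_out)
    t_eval = t_eval[t_eval <= horizon]

    if method == "rk4":
        states = [y0]
        y = y0.copy()
        for t_prev, t_next in zip(t_eval[:-1], t_eval[1:]):
            y = rk4_march(y, params, t_next - t_prev, dt_fixed)
            states.append(y.copy())
        return Trajectory(times=t_eval, states=np.array(states), params=params)

    sol = solve_ivp(
        lambda t, y: rhs_clamped(y, params),
        (0.0, horizon),
        y0,
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed: {sol.message}; last state {sol.y[:, -1]}"
        )
    return Trajectory(times=sol.t, states=np.maximum(sol.y.T, 0.0),
                      params=params)


def settle(
    initial,
    params: ModelParams,
    equilibria: list[Equilibrium] | None = None,
    tol_attract: float = TOL_ATTRACT,
    tol_speed: float = TOL_SPEED,
    max_horizon: float = MAX_HORIZON,
    chunk: float = 5.0,
) -> str:
    """Label of the stable equilibrium the trajectory converges to.

    Integrates in chunks; convergence requires the state to be within
    ``tol_attract`` (max-norm, Hz) of a stable equilibrium AND the local
    speed below ``tol_speed`` (Hz/s).  Returns the equilibrium's label,
    or ``"unresolved"`` if neither condition is met within
    ``max_horizon`` seconds (expected only for states practically on the
    separatrix).
    """
    if equilibria is None:
        equilibria = stable_equilibria(params)
    stables = [eq for eq in equilibria if eq.stability == "stable"]
    if not stables:
        raise ValueError("no stable equilibrium supplied")

    y = np.asarray(initial, dtype=float)
    targets = np.array([eq.state for eq in stables])

    t = 0.0
    while t < max_horizon:
        dists = np.max(np.abs(targets - y), axis=1)
        i = int(np.argmin(dists))
        if dists[i] < tol_attract:
            speed = float(np.max(np.abs(rhs_clamped(y, params))))
            if speed < tol_speed:
                return stables[i].label
        step = min(chunk, max_horizon - t)
        sol = solve_ivp(
            lambda tt, yy: rhs_clamped(yy, params),
            (0.0, step),
            y,
            method="RK45",
            rtol=DEFAULT_RTOL,
            atol=DEFAULT_ATOL,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed during settle: {sol.message}"
            )
        y = np.maximum(sol.y[:, -1], 0.0)
        t += step

    dists = np.max(np.abs(targets - y), axis=1)
    i = int(np.argmin(dists))
    if dists[i] < tol_attract and \
            float(np.max(np.abs(rhs_clamped(y, params)))) < tol_speed:
        return stables[i].label
    log.info("settle: unresolved after %.0f s from %s (nearest %s at %.3g Hz)",
             max_horizon, np.asarray(initial, float), stables[i].label, dists[i])
    return "unresolved"
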