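"""Basin-of-attraction mapping on initial-condition grids.

A 2-D basin map fixes the initial TRN rate T(0) and varies the initial
S and V over a grid; each cell is integrated under the full 3-D flow
until it settles at a stable equilibrium (this is an initial-condition
section of the 3-D flow, not a dynamics with T frozen — though a
frozen-T mode is available for comparison).  Classification runs all
cells in one vectorised fixed-step RK4 march, retiring cells as they
converge, which keeps a 101x101 grid in the seconds range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import _rates
from .equilibria import Equilibrium, stable_equilibria
from .integrate import MAX_HORIZON, TOL_ATTRACT, TOL_SPEED, settle
from .kinetics import ModelParams

__all__ = ["BasinGrid", "map_basins_2d", "basin_area_fraction",
           "switching_threshold"]

log = logging.getLogger(__name__)

UNRESOLVED = "unresolved"


@dataclass
class BasinGrid:
    """Attractor labels over a grid of (S0, V0) initial conditions."""

    s_values: np.ndarray          # initial S grid (Hz)
    v_values: np.ndarray          # initial V grid (Hz)
    T_init: float                 # shared initial T (Hz)
    labels: np.ndarray            # shape (len(s), len(v)), dtype str
    params: ModelParams
    attractors: list[Equilibrium]

    @property
    def area_fraction(self) -> dict[str, float]:
        """Per-label fraction of grid cells; fractions sum to 1."""
        total = self.labels.size
        uniq, counts = np.unique(self.labels, return_counts=True)
        return {str(u): c / total for u, c in zip(uniq, counts)}

    def to_dataframe(self) -> pd.DataFrame:
        ss, vv = np.meshgrid(self.s_values, self.v_values, indexing="ij")
        return pd.DataFrame({"S0": ss.ravel(), "V0": vv.ravel(),
                             "label": self.labels.ravel()})


def _batch_rhs(y: np.ndarray, params: ModelParams, frozen_T: bool) -> np.ndarray:
    yc = np.maximum(y, 0.0)
    dS, dT, dV = _rates(yc[0], yc[1], yc[2], params)
    if frozen_T:
        dT = np.zeros_like(dT)
    return np.array([dS, dT, dV])


def _classify_batch(
    starts: np.ndarray,
    params: ModelParams,
    attractors: list[Equilibrium],
    tol_attract: float,
    tol_speed: float,
    max_horizon: float,
    dt: float,
    check_every: float,
    frozen_T: bool,
) -> np.ndarray:
    """Vectorised settle: RK4-march all columns of ``starts`` (3, n)."""
    n = starts.shape[1]
    y = np.maximum(starts.astype(float), 0.0)
    active = np.arange(n)
    out = np.full(n, UNRESOLVED, dtype=object)
    targets = np.array([eq.state for eq in attractors])   # (k, 3)
    labels = [eq.label for eq in attractors]

    steps_per_check = max(1, int(round(check_every / dt)))
    t = 0.0
    while t < max_horizon and active.size:
        for _ in range(steps_per_check):
            k1 = _batch_rhs(y, params, frozen_T)
            k2 = _batch_rhs(y + 0.5 * dt * k1, params, frozen_T)
            k3 = _batch_rhs(y + 0.5 * dt * k2, params, frozen_T)
            k4 = _batch_rhs(y + dt * k3, params, frozen_T)
            y = np.maximum(y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
        t += steps_per_check * dt
        # distance of each active cell to each attractor, max-norm
        d = np.max(np.abs(targets[:, :, None] - y[None, :, :]), axis=1)  # (k, n_act)
        nearest = np.argmin(d, axis=0)
        close = d[nearest, np.arange(y.shape[1])] < tol_attract
        if np.any(close):
            speed = np.max(np.abs(_batch_rhs(y, params, frozen_T)), axis=0)
            done = close & (speed < tol_speed)
            if np.any(done):
                for j in np.nonzero(done)[0]:
                    out[active[j]] = labels[nearest[j]]
                keep = ~done
                y = y[:, keep]
                active = active[keep]
    n_unres = int(np.sum(out == UNRESOLVED))
    if n_unres:
        log.info("basin classification: %d of %d cells unresolved after "
                 "%.0f s (separatrix-adjacent cells expected)", n_unres, n,
                 max_horizon)
    return out.astype(str)


def map_basins_2d(
    params: ModelParams,
    T_init: float,
    s_grid=None,
    v_grid=None,
    tol_attract: float = TOL_ATTRACT,
    tol_speed: float = TOL_SPEED,
    max_horizon: float = MAX_HORIZON,
    dt: float = 0.01,
    frozen_T: bool = False,
) -> BasinGrid:
    """Label every (S0, V0) cell with the attractor it converges to.

    Default grid: S0 and V0 each on 101 points over [0, 100] Hz, so
    area fractions are comparable across runs.  T(0) = ``T_init`` for
    every cell; ``frozen_T=True`` holds T at that value for the whole
    integration instead of letting it evolve.
    """
    s_grid = np.linspace(0.0, 100.0, 101) if s_grid is None \
        else np.asarray(s_grid, dtype=float)
    v_grid = np.linspace(0.0, 100.0, 101) if v_grid is None \
        else np.asarray(v_grid, dtype=float)
    if T_init < 0:
        raise ValueError("T_init must be non-negative")

    attractors = stable_equilibria(params)
    ss, vv = np.meshgrid(s_grid, v_grid, indexing="ij")
    starts = np.stack([ss.ravel(),
                       np.full(ss.size, float(T_init)),
                       vv.ravel()])
    flat = _classify_batch(starts, params, attractors, tol_attract,
                           tol_speed, max_horizon, dt,
                           check_every=0.5, frozen_T=frozen_T)
    labels = flat.reshape(len(s_grid), len(v_grid))
    return BasinGrid(s_values=s_grid, v_values=v_grid, T_init=float(T_init),
                     labels=labels, params=params, attractors=attractors)


def basin_area_fraction(grid: BasinGrid, label: str) -> float:
    """Fraction of grid cells carrying ``label`` (0.0 if absent)."""
    return grid.area_fraction.get(label, 0.0)


def switching_threshold(
    params: ModelParams,
    direction=(0.0, 0.0, 1.0),
    amp_max: float | None = None,
    tol: float = 1e-2,
    equilibria: list[Equilibrium] | None = None,
) -> float | None:
    """Minimal perturbation along a ray from baseline that flips the switch.

    Bisects the amplitude along the (normalised) ``direction`` ray from
    the origin for the boundary between the zero basin and the
    high-firing basin.  Returns the threshold amplitude in Hz, or None
    when no switch occurs within the state box (e.g. the monostable
    regime) — the "no switch" outcome is a value, not an error.
    """
    d = np.asarray(direction, dtype=float)
    if np.any(d < 0) or not np.any(d > 0):
        raise ValueError("direction must be non-negative and non-zero")
    d = d / np.max(np.abs(d))
    if amp_max is None:
        box = np.array([params.m1, params.m2, params.m1])
        amp_max = float(np.min(box[d > 0] / d[d > 0]))

    if equilibria is None:
        equilibria = stable_equilibria(params)
    if len(equilibria) < 2:
        return None

    def label_at(amp: float) -> str:
        return settle(amp * d, params, equilibria)

    hi = amp_max
    if label_at(hi) != "high":
        return None
    lo = 0.0  # the origin itself is in the zero basin
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        lab = label_at(mid)
        if lab == "high":
            hi = mid
        else:  # zero or unresolved: keep pushing up
            lo = mid
    return 0.5 * (lo + hi)
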