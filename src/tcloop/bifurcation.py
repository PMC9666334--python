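"""Equilibrium branches versus the GABAergic efficacy a, and the fold.

Lowering a weakens TRN inhibition of VPL; below a critical value
(a-hat) the single baseline equilibrium is joined by an unstable middle
state and a stable high-firing state through a saddle-node fold.  The
fold is located by bisection on the equilibrium count, which the scalar
reduction makes cheap and robust — no continuation machinery needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibria import Equilibrium, find_equilibria
from .kinetics import ModelParams

__all__ = ["BifurcationDiagram", "FoldResult", "sweep", "find_threshold",
           "count_equilibria"]


@dataclass
class BifurcationDiagram:
    a_values: np.ndarray
    branches: list[list[Equilibrium]]   # per-a equilibria, V-ascending
    branch_ids: list[list[int]]         # matched branch id per equilibrium
    a_hat: float | None
    variant: str

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for a, eqs, ids in zip(self.a_values, self.branches, self.branch_ids):
            for eq, bid in zip(eqs, ids):
                rows.append({"a": a, "branch_id": bid, "S": eq.S, "T": eq.T,
                             "V": eq.V, "stability": eq.stability})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FoldResult:
    """Outcome of the fold search on [a_min, a_max].

    status is "fold" (a_hat set), "bistable_throughout" (three
    equilibria at both ends, e.g. the reversed-GABA variant or m2=0) or
    "monostable_throughout".
    """

    a_hat: float | None
    status: str


def count_equilibria(params: ModelParams, n_grid: int = 5000) -> int:
    return len(find_equilibria(params, n_grid=n_grid))


def sweep(params: ModelParams, a_grid) -> "BifurcationDiagram":
    """Equilibria for every a in ``a_grid``, with branches matched across
    adjacent grid points by nearest neighbour in state space."""
    a_grid = np.asarray(a_grid, dtype=float)
    if np.any(np.diff(a_grid) <= 0):
        raise ValueError("a_grid must be strictly increasing")
    if a_grid.min() < 0 or a_grid.max() > 1:
        raise ValueError("a_grid must lie within [0, 1]")

    branches: list[list[Equilibrium]] = []
    branch_ids: list[list[int]] = []
    next_id = 0
    prev: list[tuple[int, np.ndarray]] = []
    for a in a_grid:
        eqs = find_equilibria(params.with_a(a))
        ids: list[int] = []
        if len(prev) == len(eqs):
            # equilibria are V-ordered and branches cannot cross, so a
            # count-preserving step inherits ids by rank
            ids = [bid for bid, _ in prev]
        else:
            taken: set[int] = set()
            for eq in eqs:
                best, best_d = None, np.inf
                for bid, state in prev:
                    if bid in taken:
                        continue
                    d = float(np.max(np.abs(state - eq.state)))
                    if d < best_d:
                        best, best_d = bid, d
                if best is not None and best_d < 10.0:  # Hz
                    ids.append(best)
                    taken.add(best)
                else:
                    ids.append(next_id)
                    next_id += 1
        branches.append(eqs)
        branch_ids.append(ids)
        prev = list(zip(ids, (eq.state for eq in eqs)))

    fold = find_threshold(params)
    return BifurcationDiagram(a_values=a_grid, branches=branches,
                              branch_ids=branch_ids, a_hat=fold.a_hat,
                              variant=params.variant)


def find_threshold(
    params: ModelParams,
    tol: float = 1e-5,
    a_min: float = 0.0,
    a_max: float = 1.0,
    n_grid: int = 5000,
) -> FoldResult:
    """Saddle-node location a-hat by bisection on the equilibrium count.

    The indicator is "at least three equilibria" (bistable).  If the
    indicator is identical at both interval ends there is no fold to
    find and the status says which side the whole interval is on.
    """
    def bistable(a: float) -> bool:
        return count_equilibria(params.with_a(a), n_grid=n_grid) >= 3

    lo_b, hi_b = bistable(a_min), bistable(a_max)
    if lo_b and hi_b:
        return FoldResult(a_hat=None, status="bistable_throughout")
    if not lo_b and not hi_b:
        return FoldResult(a_hat=None, status="monostable_throughout")
    lo, hi = a_min, a_max  # lo side bistable, hi side monostable
    if hi_b:  # fold the other way round (not expected for this loop)
        lo, hi = a_max, a_min
    while abs(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        if bistable(mid):
            lo = mid
        else:
            hi = mid
    return FoldResult(a_hat=0.5 * (lo + hi), status="fold")
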