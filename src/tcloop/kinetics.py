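"""Hill-type interaction functions and the shared parameter model.

The loop couples three neural populations — somatosensory cortex (S),
thalamic reticular nucleus (T) and the ventroposterolateral thalamic
nucleus (V) — through saturating Hill-function firing-rate responses.
All rates are in Hz, the GABAergic efficacy ``a`` is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

__all__ = [
    "ModelParams",
    "VARIANTS",
    "hill_f",
    "gain_g",
    "shift_h",
    "dhill",
]

ArrayLike = Union[float, np.ndarray]

#: Recognised right-hand-side variants.
#: standard      — full model: TRN inhibition lowers the VPL gain and
#:                 raises its half-activation.
#: reversed_gaba — TRN action turned excitatory (chloride-gradient
#:                 inversion): the V-equation becomes tau*dV/dt + V = f(S+T).
#: fixed_g       — the gain Hill function is frozen at its basal value m1.
#: fixed_h       — the half-activation Hill function is frozen at e0.
VARIANTS = ("standard", "reversed_gaba", "fixed_g", "fixed_h")


@dataclass(frozen=True)
class ModelParams:
    """Parameter vector of the thalamocortical loop model.

    Defaults are the nominal values used throughout: ``tau=0.5`` s,
    ``m1=100`` Hz, ``m2=80`` Hz, ``e=20`` Hz, ``p=2.5``.  ``e0`` is the
    basal half-activation of the VPL response; it defaults to ``e`` so
    that at ``a=0`` the V-equation collapses to the same increasing Hill
    form that drives S.  ``a`` scales the strength of TRN's GABAergic
    action and lives in [0, 1].
    """

    tau: float = 0.5
    m1: float = 100.0
    m2: float = 80.0
    e: float = 20.0
    e0: float | None = None
    p: float = 2.5
    a: float = 1.0
    variant: str = "standard"

    def __post_init__(self) -> None:
        if self.e0 is None:
            object.__setattr__(self, "e0", float(self.e))
        for name in ("tau", "m1", "m2", "e", "e0", "p", "a"):
            object.__setattr__(self, name, float(getattr(self, name)))
        for name in ("tau", "m1", "e", "e0", "p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.m2 < 0:
            raise ValueError(f"m2 must be >= 0, got {self.m2}")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"a must lie in [0, 1], got {self.a}")
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )

    def with_a(self, a: float) -> "ModelParams":
        """Copy of this parameter set with a different GABAergic efficacy."""
        return replace(self, a=a)

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "m1": self.m1,
            "m2": self.m2,
            "e": self.e,
            "e0": self.e0,
            "p": self.p,
            "a": self.a,
            "variant": self.variant,
        }


def _check_nonneg(x: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative (Hill functions are "
                         f"defined on x >= 0 for non-integer exponents)")
    return arr


def hill_f(x: ArrayLike, m: float, e: float, p: float) -> ArrayLike:
    """Increasing Hill function ``m * x**p / (e**p + x**p)``.

    Strictly increasing on x >= 0, bounded in [0, m), half-maximal at
    ``x = e``.  ``0**p`` is taken as 0 for p > 0, so hill_f(0) == 0
    exactly.
    """
    arr = _check_nonneg(x, "x")
    xp = np.power(arr, p)
    out = m * xp / (e**p + xp)
    return float(out) if out.ndim == 0 else out


def gain_g(aT: ArrayLike, params: ModelParams) -> ArrayLike:
    """Decreasing Hill gain ``m1 / (1 + (aT/e)**p)``.

    Models the suppression of the VPL maximal output rate by TRN
    inhibition; g(0) = m1.
    """
    arr = _check_nonneg(aT, "aT")
    out = params.m1 / (1.0 + np.power(arr / params.e, params.p))
    return float(out) if out.ndim == 0 else out


def shift_h(aT: ArrayLike, params: ModelParams) -> ArrayLike:
    """Increasing half-activation shift ``e0 + m2 * aT**p / (e**p + aT**p)``.

    Models the rightward shift of the VPL input-output curve under TRN
    inhibition; h(0) = e0.
    """
    arr = _check_nonneg(aT, "aT")
    xp = np.power(arr, params.p)
    out = params.e0 + params.m2 * xp / (params.e**params.p + xp)
    return float(out) if out.ndim == 0 else out


def dhill(x: ArrayLike, m: float, e: float, p: float) -> ArrayLike:
    """Derivative of :func:`hill_f` with respect to x.

    ``m * p * e**p * x**(p-1) / (e**p + x**p)**2``.  At x = 0 this is 0
    when p > 1 (the case of interest here), m*p/e when p == 1, and
    divergent when p < 1; the formula is evaluated directly.
    """
    arr = _check_nonneg(x, "x")
    ep = e**p
    with np.errstate(divide="ignore"):
        num = m * p * ep * np.power(arr, p - 1.0)
    out = num / (ep + np.power(arr, p)) ** 2
    return float(out) if out.ndim == 0 else out
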