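import numpy as np
import pytest

from tcloop import ModelParams


@pytest.fixture
def defaults() -> ModelParams:
    """Nominal parameter set (tau=0.5, m1=100, m2=80, e=20, p=2.5, e0=e)."""
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def reference_rhs(y, params):
    """Loop ODE right-hand side written out independently of the package.

    Used as the oracle side of dual-route checks; kept deliberately
    separate from tcloop.dynamics.
    """
    m1, m2, e, e0, p, a, tau = (params.m1, params.m2, params.e, params.e0,
                                params.p, params.a, params.tau)
    S, T, V = [max(float(x), 0.0) for x in y]

    def f(x, m):
        return m * x**p / (e**p + x**p)

    if params.variant == "reversed_gaba":
        drive = f(S + T, m1)
    else:
        aT = a * T
        g = m1 if params.variant == "fixed_g" else m1 / (1 + (aT / e) ** p)
        h = e0 if params.variant == "fixed_h" else \
            e0 + m2 * aT**p / (e**p + aT**p)
        drive = g * S**p / (S**p + h**p) if S > 0 else 0.0
    return [(f(V, m1) - S) / tau, (f(V + S, m2) - T) / tau, (drive - V) / tau]
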