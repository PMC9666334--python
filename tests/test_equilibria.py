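"""Fixed-point location and stability classification."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tcloop import ModelParams, find_equilibria, reduce_to_scalar, rhs

from conftest import reference_rhs


def brute_force_root_count(params, n=50000, v_max=None):
    """Dense sign-change scan of the steady-state residual (oracle)."""
    v_max = 1.05 * params.m1 if v_max is None else v_max
    grid = np.linspace(1e-9, v_max, n)
    res = reduce_to_scalar(grid, params)
    sign = np.sign(res)
    return 1 + int(np.sum(sign[:-1] * sign[1:] < 0))  # +1 for the origin


class TestScalarReduction:
    def test_origin_residual_is_zero(self, defaults):
        for a in (0.0, 0.3, 1.0):
            assert reduce_to_scalar(0.0, defaults.with_a(a)) == 0.0

    def test_three_roots_bracketed_at_weak_inhibition(self, defaults):
        # fine-grid scan over [0, 105] at a = 0.2
        grid = np.linspace(1e-9, 105.0, 5000)
        res = reduce_to_scalar(grid, defaults.with_a(0.2))
        sign_changes = int(np.sum(np.sign(res[:-1]) * np.sign(res[1:]) < 0))
        assert sign_changes == 2  # plus the origin root = 3 equilibria

    def test_single_root_at_full_inhibition(self, defaults):
        grid = np.linspace(1e-9, 105.0, 5000)
        res = reduce_to_scalar(grid, defaults.with_a(1.0))
        assert np.all(res < 0)  # only the origin root remains

    def test_roots_are_fixed_points_of_full_system(self, defaults):
        p = defaults.with_a(0.26)
        for eq in find_equilibria(p):
            assert np.max(np.abs(rhs(eq.state, p))) < 1e-8


class TestFindEquilibria:
    def test_full_inhibition_is_monostable(self, defaults):
        eqs = find_equilibria(defaults.with_a(1.0))
        assert len(eqs) == 1
        assert eqs[0].label == "zero" and eqs[0].stability == "stable"
        assert np.allclose(eqs[0].state, 0.0)

    def test_weak_inhibition_gives_three_ordered_states(self, defaults):
        eqs = find_equilibria(defaults.with_a(0.2))
        assert [eq.label for eq in eqs] == ["zero", "mid", "high"]
        assert [eq.stability for eq in eqs] == ["stable", "unstable", "stable"]

    def test_high_state_coordinates_near_fold(self, defaults):
        # frozen from an independent scipy integration (see
        # test_high_state_confirmed_by_independent_integration)
        eqs = find_equilibria(defaults.with_a(0.26))
        high = eqs[-1]
        assert high.label == "high" and high.stability == "stable"
        assert high.V == pytest.approx(29.318822661, abs=1e-6)
        assert high.S == pytest.approx(72.236908521, abs=1e-6)

    def test_high_state_confirmed_by_independent_integration(self, defaults):
        # dual route: long scipy integration of an independently written
        # RHS from inside the high basin must land on the same point
        p = defaults.with_a(0.26)
        high = find_equilibria(p)[-1]
        sol = solve_ivp(lambda t, y: reference_rhs(y, p), (0, 300.0),
                        [100.0, 0.0, 100.0], rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(sol.y[:, -1] - high.state)) < 1e-5

    def test_origin_always_present_stable_with_decay_eigenvalues(self):
        # eigenvalues at the origin are exactly -1/tau (threefold) since
        # p > 1 kills every Hill derivative there
        for variant in ("standard", "reversed_gaba", "fixed_g", "fixed_h"):
            for a in (0.0, 0.5, 1.0):
                p = ModelParams(variant=variant, a=a)
                zero = find_equilibria(p)[0]
                assert zero.label == "zero" and zero.stability == "stable"
                assert np.allclose(zero.state, 0.0)
                assert np.allclose(zero.eigenvalues, -1.0 / p.tau)

    def test_odd_count_and_componentwise_ordering_across_a(self, defaults):
        for a in np.linspace(0.0, 1.0, 200):
            eqs = find_equilibria(defaults.with_a(a), n_grid=2000)
            assert len(eqs) in (1, 3)
            states = np.array([eq.state for eq in eqs])
            assert np.all(np.diff(states, axis=0) > 0) or len(eqs) == 1

    def test_matches_brute_force_scan_on_random_parameters(self, rng):
        # oracle equivalence at 10x the scan resolution
        for _ in range(50):
            params = ModelParams(
                tau=rng.uniform(0.1, 2.0),
                m1=rng.uniform(50, 150),
                m2=rng.uniform(20, 120),
                e=rng.uniform(10, 40),
                p=rng.uniform(1.5, 4.0),
                a=rng.uniform(0.0, 1.0),
            )
            eqs = find_equilibria(params)
            assert len(eqs) == brute_force_root_count(params)

    def test_reversed_gaba_bistable_over_full_a_range(self):
        # TRN action turned excitatory: the high state survives any a
        for a in np.linspace(0.0, 1.0, 101):
            eqs = find_equilibria(ModelParams(variant="reversed_gaba", a=a),
                                  n_grid=2000)
            stable = [eq for eq in eqs if eq.stability == "stable"]
            assert len(stable) == 2
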