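"""Basin-of-attraction maps and the ultrasensitive switching threshold."""

import numpy as np
import pytest

from tcloop import (ModelParams, basin_area_fraction, map_basins_2d, settle,
                    switching_threshold)

COARSE = np.linspace(0.0, 100.0, 21)


class TestMapBasins2d:
    def test_monostable_regime_single_basin(self, defaults):
        grid = map_basins_2d(defaults.with_a(1.0), T_init=80.0,
                             s_grid=COARSE, v_grid=COARSE)
        assert set(np.unique(grid.labels)) == {"zero"}
        assert basin_area_fraction(grid, "high") == 0.0

    def test_bistable_regime_two_nonempty_basins(self, defaults):
        grid = map_basins_2d(defaults.with_a(0.26), T_init=80.0,
                             s_grid=COARSE, v_grid=COARSE)
        assert basin_area_fraction(grid, "zero") > 0.0
        assert basin_area_fraction(grid, "high") > 0.0

    def test_origin_cell_is_always_baseline(self, defaults):
        for a in (0.15, 0.26, 1.0):
            grid = map_basins_2d(defaults.with_a(a), T_init=80.0,
                                 s_grid=np.array([0.0, 50.0]),
                                 v_grid=np.array([0.0, 50.0]))
            assert grid.labels[0, 0] == "zero"

    def test_fractions_partition_unity(self, defaults):
        grid = map_basins_2d(defaults.with_a(0.2), T_init=80.0,
                             s_grid=COARSE, v_grid=COARSE)
        assert sum(grid.area_fraction.values()) == pytest.approx(1.0)

    def test_agrees_with_scalar_settle_on_sample(self, defaults, rng):
        # the vectorised RK4 classifier and the adaptive scalar settle
        # must agree away from the separatrix
        p = defaults.with_a(0.2)
        grid = map_basins_2d(p, T_init=80.0, s_grid=COARSE, v_grid=COARSE)
        for _ in range(10):
            i, j = rng.integers(0, len(COARSE), size=2)
            expected = settle([COARSE[i], 80.0, COARSE[j]], p)
            if expected != "unresolved":
                assert grid.labels[i, j] == expected

    def test_stable_under_grid_refinement(self, defaults):
        p = defaults.with_a(0.2)
        f1 = basin_area_fraction(
            map_basins_2d(p, 80.0, np.linspace(0, 100, 26),
                          np.linspace(0, 100, 26)), "high")
        f2 = basin_area_fraction(
            map_basins_2d(p, 80.0, np.linspace(0, 100, 51),
                          np.linspace(0, 100, 51)), "high")
        assert abs(f1 - f2) < 0.02

    def test_high_basin_grows_as_inhibition_weakens(self, defaults):
        fracs = []
        for a in (0.25, 0.15):
            grid = map_basins_2d(defaults.with_a(a), T_init=80.0,
                                 s_grid=COARSE, v_grid=COARSE)
            fracs.append(basin_area_fraction(grid, "high"))
        assert fracs[1] >= fracs[0]

    def test_reversed_gaba_high_basin_at_least_standard(self):
        kw = dict(T_init=80.0, s_grid=COARSE, v_grid=COARSE)
        f_std = basin_area_fraction(
            map_basins_2d(ModelParams(a=0.2), **kw), "high")
        f_rev = basin_area_fraction(
            map_basins_2d(ModelParams(a=0.2, variant="reversed_gaba"), **kw),
            "high")
        assert f_rev >= f_std

    def test_max_trn_start_widest_baseline_basin(self, defaults):
        # T(0) = m2 = 80 Hz maximises initial inhibition, hence the
        # baseline basin is at least as wide as with T(0) = 0
        p = defaults.with_a(0.2)
        f80 = basin_area_fraction(
            map_basins_2d(p, 80.0, COARSE, COARSE), "zero")
        f0 = basin_area_fraction(
            map_basins_2d(p, 0.0, COARSE, COARSE), "zero")
        assert f80 >= f0

    def test_frozen_T_mode_runs_and_differs_in_principle(self, defaults):
        p = defaults.with_a(0.26)
        grid = map_basins_2d(p, T_init=80.0, s_grid=COARSE, v_grid=COARSE,
                             frozen_T=True)
        assert sum(grid.area_fraction.values()) == pytest.approx(1.0)


class TestSwitchingThreshold:
    def test_monostable_has_no_switch(self, defaults):
        assert switching_threshold(defaults.with_a(1.0)) is None

    def test_threshold_decreases_as_inhibition_weakens(self, defaults):
        # ultrasensitivity: a smaller VPL kick suffices at smaller a
        thr = [switching_threshold(defaults.with_a(a))
               for a in (0.25, 0.2, 0.1)]
        assert all(t is not None for t in thr)
        assert thr[0] >= thr[1] >= thr[2]

    def test_threshold_small_relative_to_high_state_near_fold(self, defaults):
        from tcloop import find_equilibria

        p = defaults.with_a(0.26)
        thr = switching_threshold(p)
        high_V = find_equilibria(p)[-1].V
        assert thr is not None and thr < high_V

    def test_rejects_bad_direction(self, defaults):
        with pytest.raises(ValueError):
            switching_threshold(defaults.with_a(0.2), direction=(0, 0, 0))
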