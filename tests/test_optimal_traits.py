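"""Fitness proxy, diurnal scheme, and the weekly trait optimization."""

import numpy as np
import pytest
from scipy.integrate import quad

from canopyopt import optimal_traits as ot
from canopyopt import photosynthesis as ph
from canopyopt.params import CostParams, ModelParams
from canopyopt.photosynthesis import AcclimationState

from conftest import make_day


@pytest.fixture
def acc_week(benign_week, params):
    accs = [ph.init_acclimation(benign_week[0].T_mean, params.photo)]
    for d in benign_week[1:]:
        accs.append(ph.update_acclimation(accs[-1].S_t, d.T_mean, params.photo))
    return accs


class TestFitness:
    def test_dark_leaf_pays_pure_maintenance(self, params, active_acc, benign_day):
        seg = ot.day_segments(benign_day, params.P_atm)[0]
        env = seg.env
        env.I_inc = 0.0
        G = ot.fitness(0.05, 0.02, env, active_acc, params, H=21.0)
        J_max = ph.jmax(
            ph.LeafEnv(I_inc=0.0, T_a=env.T_a, c_a=env.c_a, N_mf=0.02),
            active_acc, params.photo,
        )
        expected = -(params.costs.N_r + params.costs.N_u) * J_max
        assert G == pytest.approx(expected, rel=1e-12)
        assert G < 0.0

    def test_nitrogen_free_leaf_is_cost_free(self, params, active_acc, benign_day):
        seg = ot.day_segments(benign_day, params.P_atm)[0]
        assert ot.fitness(0.05, 0.0, seg.env, active_acc, params, H=21.0) == 0.0

    def test_uptake_cost_lowers_fitness_pointwise(self, active_acc, benign_day):
        seg = ot.day_segments(benign_day, 101325.0)[0]
        free = ModelParams(costs=CostParams(N_u=0.0))
        costly = ModelParams(costs=CostParams(N_u=0.012))
        for gs in (0.01, 0.05, 0.1):
            G0 = ot.fitness(gs, 0.02, seg.env, active_acc, free, H=21.0)
            G1 = ot.fitness(gs, 0.02, seg.env, active_acc, costly, H=21.0)
            assert G0 >= G1


class TestDiurnalDrivers:
    def test_radiation_integral_conserves_daily_total(self, benign_day):
        total, _ = quad(
            lambda t: ot.diurnal_drivers(benign_day, t).I_inc * 3600.0,
            0.0, benign_day.dt_g, epsrel=1e-10,
        )
        assert total == pytest.approx(benign_day.I0, rel=1e-9)

    def test_temperature_spans_daily_range(self, benign_day):
        t = np.linspace(0.0, benign_day.dt_g, 241)
        T = np.array([ot.diurnal_drivers(benign_day, x).T_a for x in t])
        assert T.min() >= benign_day.T_min - 1e-12
        assert T.max() <= benign_day.T_max + 1e-12
        # afternoon peak: maximum in the second half of daylight
        assert t[np.argmax(T)] > 0.5 * benign_day.dt_g

    def test_segment_midpoints_match_closed_forms(self):
        day = make_day(I0=30.0, dt_g=18.0, T_min=8.0, T_max=22.0)
        segs = ot.day_segments(day)
        am, pm = segs
        I_peak = np.pi * 30.0 / (2.0 * 18.0 * 3600.0)
        assert am.env.I_inc == pytest.approx(I_peak * np.sin(np.pi * 0.25), rel=1e-12)
        assert pm.env.I_inc == pytest.approx(I_peak * np.sin(np.pi * 0.75), rel=1e-12)
        assert pm.env.T_a == pytest.approx(22.0, rel=1e-12)  # sine peak at 0.75
        assert am.env.T_a == pytest.approx(
            8.0 + 14.0 * np.sin(np.pi * 0.25 / 1.5), rel=1e-12
        )
        assert am.duration == pm.duration == 9.0

    def test_vpd_never_negative(self):
        day = make_day(T_min=2.0, T_max=30.0, VPD_mean=1400.0)
        for t in np.linspace(0.0, day.dt_g, 49):
            assert ot.diurnal_drivers(day, t).VPD >= 0.0


class TestDailyFitness:
    def test_dark_day_cost_is_integrated_maintenance(self, params):
        day = make_day(I0=0.0, VPD_mean=400.0)
        acc = AcclimationState(S_t=20.0, X_t=1.0)
        val = ot.daily_fitness((0.001, 0.001), 0.007, day, acc, params, H=21.0)
        segs = ot.day_segments(day, params.P_atm)
        expected = 0.0
        for seg in segs:
            env = ph.LeafEnv(I_inc=0.0, T_a=seg.env.T_a, c_a=seg.env.c_a, N_mf=0.007)
            Jm = ph.jmax(env, acc, params.photo)
            expected -= (params.costs.N_r + params.costs.N_u) * Jm * seg.duration * 3600.0
        assert val == pytest.approx(expected, rel=1e-10)
        assert val < 0.0

    def test_night_cost_flag_subtracts_dark_hour_maintenance(self, params,
                                                             active_acc):
        day = make_day(dt_g=16.0)
        base = ot.daily_fitness((0.05, 0.05), 0.02, day, active_acc, params,
                                H=21.0)
        with_night = ot.daily_fitness((0.05, 0.05), 0.02, day, active_acc,
                                      params, H=21.0, include_night_cost=True)
        night_env = ph.LeafEnv(I_inc=0.0, T_a=day.T_min, c_a=day.c_a, N_mf=0.02)
        expected_extra = ((params.costs.N_r + params.costs.N_u)
                          * ph.jmax(night_env, active_acc, params.photo)
                          * 8.0 * 3600.0)
        assert base - with_night == pytest.approx(expected_extra, rel=1e-12)

    def test_two_segment_sum_tracks_dense_quadrature(self, params, active_acc):
        """SDM-2 vs a 1000-point trapezoid of G(t): logged approximation gap."""
        day = make_day()
        sdm2 = ot.daily_fitness((0.06, 0.05), 0.015, day, active_acc, params, H=21.0)
        t = np.linspace(1e-6, day.dt_g - 1e-6, 1000)
        G = np.empty_like(t)
        for i, x in enumerate(t):
            env = ot.diurnal_drivers(day, x, params.P_atm)
            gs = 0.06 if x < day.dt_g / 2 else 0.05
            G[i] = ot.fitness(gs, 0.015, env, active_acc, params, H=21.0)
        dense = np.trapezoid(G, t) * 3600.0
        rel_gap = abs(sdm2 - dense) / abs(dense)
        print(f"SDM-2 vs dense quadrature relative gap: {rel_gap:.3%}")
        assert sdm2 == pytest.approx(dense, rel=0.25)  # coarse sanity, not equality


class TestOptimizeWeek:
    def test_identical_days_reuse_the_step1_pair(self, params):
        days = [make_day(day_of_season=i, T_min=15.0, T_mean=15.0, T_max=15.0)
                for i in range(7)]
        accs = [AcclimationState(S_t=20.0, X_t=1.0)] * 7
        sol = ot.optimize_week(days, accs, params, H=21.0)
        for pair in sol.gs_pairs:
            assert pair[0] == pytest.approx(sol.gs_pairs[0][0], rel=1e-4)
            assert pair[1] == pytest.approx(sol.gs_pairs[0][1], rel=1e-4)

    def test_symmetric_day_gives_symmetric_pair(self, params):
        days = [make_day(day_of_season=i, T_min=15.0, T_mean=15.0, T_max=15.0,
                         VPD_mean=500.0) for i in range(7)]
        accs = [AcclimationState(S_t=20.0, X_t=1.0)] * 7
        sol = ot.optimize_week(days, accs, params, H=21.0)
        am, pm = sol.gs_pairs[0]
        assert am == pytest.approx(pm, rel=1e-3)

    def test_traits_respect_printed_bounds(self, params, benign_week, acc_week):
        sol = ot.optimize_week(benign_week, acc_week, params, H=21.0)
        assert 0.007 <= sol.N_mf <= 0.05
        for (am, pm), day in zip(sol.gs_pairs, benign_week):
            for seg, g in zip(ot.day_segments(day, params.P_atm), (am, pm)):
                gc = ot._segment_gs_bound(seg, params, 21.0, 50)
                assert 0.001 - 1e-12 <= g <= gc + 1e-9

    def test_week_fitness_beats_grid_oracle(self, fertilized_params, benign_week,
                                            acc_week):
        sol = ot.optimize_week(benign_week, acc_week, fertilized_params, H=21.0)
        grid_best = grid_search_week(benign_week, acc_week, fertilized_params,
                                     H=21.0, n=40)
        assert sol.fitness_step1 >= grid_best - 0.005 * abs(grid_best)

    def test_uptake_cost_suppresses_optimal_nitrogen(self, benign_week, acc_week):
        free = ModelParams(costs=CostParams(N_u=0.0))
        costly = ModelParams(costs=CostParams(N_u=0.012))
        n_free = ot.optimize_week(benign_week, acc_week, free, H=21.0).N_mf
        n_costly = ot.optimize_week(benign_week, acc_week, costly, H=21.0).N_mf
        assert n_costly < n_free

    def test_interior_optimum_has_vanishing_gradient(self, fertilized_params,
                                                     benign_week, acc_week):
        sol = ot.optimize_week(benign_week, acc_week, fertilized_params, H=21.0)
        nmf, ga, gp = sol.step1_traits
        assert 0.007 < nmf < 0.05  # interior in N for the free-uptake stand
        avg = ot._mean_day(benign_week)
        aacc = AcclimationState(
            S_t=np.mean([a.S_t for a in acc_week]),
            X_t=np.mean([a.X_t for a in acc_week]),
        )

        def f(x):
            return 7.0 * ot.daily_fitness((x[1], x[2]), x[0], avg, aacc,
                                          fertilized_params, H=21.0)

        x0 = np.array([nmf, ga, gp])
        scale = abs(f(x0))
        for i in range(3):
            hstep = 1e-6 * max(abs(x0[i]), 1e-3)
            xp, xm = x0.copy(), x0.copy()
            xp[i] += hstep
            xm[i] -= hstep
            grad = (f(xp) - f(xm)) / (2.0 * hstep)
            # gradient scaled by the coordinate magnitude vs fitness scale
            assert abs(grad) * max(abs(x0[i]), 1e-3) < 1e-3 * scale


def grid_search_week(days, accs, params, H, n=40):
    """Separable grid oracle for the step-1 objective.

    The weekly objective splits into morning and afternoon parts that share
    only N_mf, so the (N, g_am, g_pm) grid max is, exactly, the max over N
    of the two per-segment maxima — evaluated at full n**3 coverage cost
    O(n**2).
    """
    avg = ot._mean_day(days)
    aacc = AcclimationState(
        S_t=float(np.mean([a.S_t for a in accs])),
        X_t=float(np.mean([a.X_t for a in accs])),
    )
    segs = ot.day_segments(avg, params.P_atm)
    best = -np.inf
    n_days = len(days)
    for nmf in np.linspace(0.007, 0.05, n):
        total = 0.0
        for seg in segs:
            g_hi = ot._segment_gs_bound(seg, params, H, 50)
            seg_best = -np.inf
            for g in np.linspace(0.001, g_hi, n):
                G = ot.fitness(g, nmf, seg.env, aacc, params, H)
                seg_best = max(seg_best, G * seg.duration * 3600.0)
            total += seg_best
        best = max(best, n_days * total)
    return best
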