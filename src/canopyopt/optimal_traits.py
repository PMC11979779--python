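"""Fitness proxy, two-segment diurnal scheme, and weekly trait optimization.

The instantaneous fitness proxy of a top-canopy leaf is

    G = A * k_cost - (N_r + N_u) * J_max

— assimilation discounted by the hydraulic-risk factor, minus the respiratory
and N-uptake costs of maintaining photosynthetic capacity. Daily fitness is
approximated by a two-segment daily model (SDM-2): daylight is split at solar
noon into a morning and an afternoon segment, each represented by its
midpoint drivers and its own stomatal conductance.

Traits optimize on two time scales: leaf N concentration (``N_mf``) once per
week, stomatal conductance twice per day. The two-step routine first
maximizes weekly fitness over ``(N_mf, g_s_am, g_s_pm)`` on the week-average
day, then fine-tunes each day's conductance pair with ``N_mf`` fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from canopyopt import hydraulics, photosynthesis
from canopyopt.params import ModelParams, OptimizerOptions
from canopyopt.photosynthesis import AcclimationState, LeafEnv
from canopyopt.weatherlab import ClimateDay, saturated_vapor_pressure

__all__ = [
    "DiurnalSegment",
    "TraitSolution",
    "fitness",
    "diurnal_drivers",
    "day_segments",
    "daily_fitness",
    "optimize_week",
]

NMF_BOUNDS = (0.007, 0.05)
GS_LOWER = 0.001


@dataclass
class DiurnalSegment:
    """One representative slice of the daylight period."""

    t_mid: float  # hours from sunrise
    duration: float  # hours
    env: LeafEnv  # instantaneous drivers at the segment midpoint


@dataclass
class TraitSolution:
    """Optimized plastic traits for one week block."""

    N_mf: float  # kg N per kg leaf, fixed for the week
    gs_pairs: list[tuple[float, float]]  # per-day (morning, afternoon)
    fitness_weekly: float  # mol C m^-2 (leaf) per block, after fine-tuning
    fitness_step1: float = math.nan  # week-average-day objective at optimum
    step1_traits: tuple[float, float, float] | None = None  # (N_mf, gs_am, gs_pm)
    flags: list[str] = field(default_factory=list)


def diurnal_drivers(
    day: ClimateDay, t: float, P_atm: float = 101325.0, i_factor: float = 1.0
) -> LeafEnv:
    """Instantaneous above-canopy drivers at ``t`` hours after sunrise.

    Radiation follows a half-sine whose integral over daylight equals the
    daily total; temperature follows a sine peaking at 0.75 of the daylight
    period (mid-afternoon) and spanning [T_min, T_max]; VPD is rebuilt from
    the instantaneous saturation vapor pressure and a constant daily actual
    vapor pressure recovered from the daily-mean VPD; CO2 and soil water are
    held constant over the day.

    ``i_factor`` converts the above-canopy flux ``I0(t)`` to irradiance
    incident on a top-canopy leaf (Beer-law interception per leaf area,
    transmittance-corrected: ``k_ext / (1 - m_leaf)``); the default 1.0
    leaves the above-canopy flux untouched.
    """
    dt = day.dt_g
    if not (0.0 <= t <= dt):
        raise ValueError("t must lie within the daylight period")
    I0_inst = math.pi * day.I0 / (2.0 * dt * 3600.0) * math.sin(math.pi * t / dt)
    # temperature sine with maximum at 0.75 * dt
    T_t = day.T_min + (day.T_max - day.T_min) * math.sin(
        math.pi * t / (1.5 * dt)
    )
    T_t = min(max(T_t, day.T_min), day.T_max)
    e_a = max(saturated_vapor_pressure(day.T_mean) - day.VPD_mean, 0.0)
    vpd_t = max(saturated_vapor_pressure(T_t) - e_a, 0.0)
    return LeafEnv(
        I_inc=i_factor * I0_inst,
        T_a=T_t,
        c_a=day.c_a,
        VPD=vpd_t,
        theta=day.theta,
        P_atm=P_atm,
    )


def day_segments(
    day: ClimateDay, P_atm: float = 101325.0, i_factor: float = 1.0
) -> list[DiurnalSegment]:
    """The two SDM-2 segments of a day: symmetric halves of daylight."""
    half = day.dt_g / 2.0
    return [
        DiurnalSegment(
            t_mid=0.25 * day.dt_g,
            duration=half,
            env=diurnal_drivers(day, 0.25 * day.dt_g, P_atm, i_factor),
        ),
        DiurnalSegment(
            t_mid=0.75 * day.dt_g,
            duration=half,
            env=diurnal_drivers(day, 0.75 * day.dt_g, P_atm, i_factor),
        ),
    ]


def fitness(
    g_s: float,
    N_mf: float,
    env: LeafEnv,
    acc: AcclimationState,
    params: ModelParams,
    H: float,
    n_panels: int = 50,
) -> float:
    """Instantaneous fitness proxy G (mol C m^-2 leaf s^-1)."""
    env = LeafEnv(
        I_inc=env.I_inc,
        T_a=env.T_a,
        c_a=env.c_a,
        VPD=env.VPD,
        theta=env.theta,
        P_atm=env.P_atm,
        N_mf=N_mf,
    )
    J_max = photosynthesis.jmax(env, acc, params.photo)
    if N_mf == 0.0:
        return 0.0
    A = photosynthesis.assimilation(g_s, env, acc, params.photo)
    state = hydraulics.solve_canopy_state(
        g_s, env.VPD, env.theta, H, params.hydro, env.P_atm, n_panels=n_panels
    )
    kc = hydraulics.k_cost(state.k_sc, params.hydro)
    return A * kc - (params.costs.N_r + params.costs.N_u) * J_max


def daily_fitness(
    gs_pair: tuple[float, float],
    N_mf: float,
    day: ClimateDay,
    acc: AcclimationState,
    params: ModelParams,
    H: float,
    segments: list[DiurnalSegment] | None = None,
    n_panels: int = 50,
    i_factor: float = 1.0,
    include_night_cost: bool = False,
) -> float:
    """Daily fitness (mol C m^-2 leaf day^-1): SDM-2 sum of G over daylight.

    With ``include_night_cost`` the capacity-maintenance term
    ``(N_r + N_u) J_max`` also accrues over the dark hours, evaluated at the
    night temperature (T_min); by default fitness covers daylight only.
    """
    if segments is None:
        segments = day_segments(day, params.P_atm, i_factor)
    total = 0.0
    for seg, g_s in zip(segments, gs_pair):
        G = fitness(g_s, N_mf, seg.env, acc, params, H, n_panels=n_panels)
        total += G * seg.duration * 3600.0
    if include_night_cost and day.dt_g < 24.0:
        night_env = LeafEnv(I_inc=0.0, T_a=day.T_min, c_a=day.c_a, N_mf=N_mf)
        J_max_night = photosynthesis.jmax(night_env, acc, params.photo)
        total -= ((params.costs.N_r + params.costs.N_u) * J_max_night
                  * (24.0 - day.dt_g) * 3600.0)
    return total


def _segment_gs_bound(
    seg: DiurnalSegment, params: ModelParams, H: float, n_panels: int
) -> float:
    """Per-segment stomatal upper bound at the critical conductivity loss."""
    try:
        g_crit = hydraulics.critical_gs(
            seg.env.VPD, seg.env.theta, H, params.hydro, params.P_atm,
            n_panels=n_panels,
        )
    except hydraulics.NoSolutionError:
        return GS_LOWER
    return max(g_crit, GS_LOWER)


def _mean_day(days: list[ClimateDay]) -> ClimateDay:
    """Arithmetic week-average day (driver-wise mean)."""
    n = len(days)
    return ClimateDay(
        date=days[0].date,
        T_mean=sum(d.T_mean for d in days) / n,
        T_min=sum(d.T_min for d in days) / n,
        T_max=sum(d.T_max for d in days) / n,
        I0=sum(d.I0 for d in days) / n,
        c_a=sum(d.c_a for d in days) / n,
        VPD_mean=sum(d.VPD_mean for d in days) / n,
        theta=sum(d.theta for d in days) / n,
        dt_g=sum(d.dt_g for d in days) / n,
    )


def optimize_week(
    days: list[ClimateDay],
    acc_series: list[AcclimationState],
    params: ModelParams,
    H: float,
    opts: OptimizerOptions | None = None,
    i_factor: float = 1.0,
) -> TraitSolution:
    """Two-step trait optimization for a week block (1–7 days).

    Step 1 maximizes the block fitness over ``(N_mf, g_s_am, g_s_pm)`` using
    the week-average day and the block-mean acclimation state. Step 2 fixes
    ``N_mf`` and re-optimizes each day's stomatal pair starting from the
    step-1 values. Each conductance is capped at its segment's critical
    value; if every start fails hydraulically the block falls back to the
    stomatal floor with a diagnostic flag.
    """
    if not days:
        raise ValueError("week block must contain at least one day")
    if opts is None:
        opts = OptimizerOptions()
    n_days = len(days)
    npan = opts.n_panels
    lo_n, hi_n = opts.nmf_bounds
    gs_lo = opts.gs_lower

    avg_day = _mean_day(days)
    avg_acc = AcclimationState(
        S_t=sum(a.S_t for a in acc_series) / n_days,
        X_t=sum(a.X_t for a in acc_series) / n_days,
    )
    avg_segments = day_segments(avg_day, params.P_atm, i_factor)
    gs_hi = [
        _segment_gs_bound(seg, params, H, npan) for seg in avg_segments
    ]
    flags: list[str] = []
    if all(hi <= gs_lo for hi in gs_hi):
        flags.append("hydraulic-floor")
        pair = (gs_lo, gs_lo)
        fit = n_days * daily_fitness(pair, lo_n, avg_day, avg_acc, params, H,
                                     segments=avg_segments, n_panels=npan,
                                     include_night_cost=opts.include_night_cost)
        return TraitSolution(
            N_mf=lo_n, gs_pairs=[pair] * n_days, fitness_weekly=fit,
            fitness_step1=fit, step1_traits=(lo_n, *pair), flags=flags,
        )
    bounds1 = [
        (lo_n, hi_n),
        (gs_lo, max(gs_hi[0], gs_lo * (1 + 1e-9))),
        (gs_lo, max(gs_hi[1], gs_lo * (1 + 1e-9))),
    ]

    def neg_week(x: np.ndarray) -> float:
        nmf, ga, gp = x
        return -n_days * daily_fitness(
            (ga, gp), nmf, avg_day, avg_acc, params, H,
            segments=avg_segments, n_panels=npan,
            include_night_cost=opts.include_night_cost,
        )

    mid = [0.5 * (lo + hi) for lo, hi in bounds1]
    starts = [mid]
    if opts.fidelity == "full":
        starts += [
            [mid[0], gs_lo * 2, gs_lo * 2],  # conservative stomata
            [0.9 * hi_n, mid[1], mid[2]],  # high-N start
        ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg_week, x0, method="L-BFGS-B", bounds=bounds1,
            options={"maxiter": opts.maxiter, "gtol": opts.gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    nmf, ga, gp = best.x
    step1_fit = -best.fun
    step1 = (float(nmf), float(ga), float(gp))

    if opts.fidelity == "fast":
        return TraitSolution(
            N_mf=step1[0], gs_pairs=[(step1[1], step1[2])] * n_days,
            fitness_weekly=step1_fit, fitness_step1=step1_fit,
            step1_traits=step1, flags=flags,
        )

    # Step 2: per-day fine-tuning of the stomatal pair at fixed N_mf
    gs_pairs: list[tuple[float, float]] = []
    total = 0.0
    for day, acc in zip(days, acc_series):
        segs = day_segments(day, params.P_atm, i_factor)
        hi = [_segment_gs_bound(s, params, H, npan) for s in segs]
        if all(b <= gs_lo for b in hi):
            flags.append("hydraulic-floor-day")
            pair = (gs_lo, gs_lo)
            gs_pairs.append(pair)
            total += daily_fitness(pair, step1[0], day, acc, params, H,
                                   segments=segs, n_panels=npan,
                                   include_night_cost=opts.include_night_cost)
            continue
        bounds2 = [
            (gs_lo, max(hi[0], gs_lo * (1 + 1e-9))),
            (gs_lo, max(hi[1], gs_lo * (1 + 1e-9))),
        ]
        x0 = [
            min(max(step1[1], bounds2[0][0]), bounds2[0][1]),
            min(max(step1[2], bounds2[1][0]), bounds2[1][1]),
        ]

        def neg_day(x: np.ndarray) -> float:
            return -daily_fitness(
                (x[0], x[1]), step1[0], day, acc, params, H,
                segments=segs, n_panels=npan,
                include_night_cost=opts.include_night_cost,
            )

        res = optimize.minimize(
            neg_day, x0, method="L-BFGS-B", bounds=bounds2,
            options={"maxiter": opts.maxiter, "gtol": opts.gtol},
        )
        gs_pairs.append((float(res.x[0]), float(res.x[1])))
        total += -res.fun
    return TraitSolution(
        N_mf=step1[0], gs_pairs=gs_pairs, fitness_weekly=total,
        fitness_step1=step1_fit, step1_traits=step1, flags=flags,
    )
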