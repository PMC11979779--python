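"""Big-leaf upscaling to stand GPP and transpiration, and season simulation.

Photosynthetic capacity and stomatal conductance are assumed to acclimate
proportionally to irradiance down the canopy, so the vertical integral of
any leaf rate reduces to the top-leaf rate times the Beer-law scale factor
``(1 - exp(-k LAI)) / k``. Canopy GPP is upscaled to ecosystem GPP (which
includes the understory) with a multiplicative factor ``zeta``.

:func:`run_simulation` chains the full pipeline: daily acclimation update,
weekly trait optimization, SDM-2 upscaling, and a tidy per-day output table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from canopyopt import hydraulics, photosynthesis, optimal_traits
from canopyopt.optimal_traits import TraitSolution, day_segments
from canopyopt.params import (
    ModelParams,
    MOLAR_MASS_C,
    MOLAR_MASS_H2O,
    OptimizerOptions,
    StandParams,
)
from canopyopt.photosynthesis import AcclimationState, LeafEnv
from canopyopt.weatherlab import ClimateDay

__all__ = [
    "CanopyFluxDay",
    "canopy_scale_factor",
    "top_leaf_irradiance_factor",
    "ecosystem_gpp",
    "canopy_transpiration_day",
    "run_simulation",
    "trait_weather_correlations",
]


@dataclass
class CanopyFluxDay:
    """Daily stand-level outputs plus water-status diagnostics."""

    date: object
    GPP_c: float  # g C m^-2 ground day^-1, canopy (trees)
    GPP_e: float  # g C m^-2 ground day^-1, ecosystem (incl. understory)
    E_c: float  # mm day^-1, canopy transpiration
    WUE: float  # g C per kg H2O (GPP_c / E_c)
    psi_c_min: float  # MPa, most negative canopy potential of the day
    k_cost_min: float  # lowest hydraulic cost factor of the day
    N_mf: float
    gs_am: float
    gs_pm: float
    flag: str = ""


def canopy_scale_factor(LAI: float, k_ext: float) -> float:
    """Beer-law integral of a top-leaf-proportional rate over the canopy.

    ``(1 - exp(-k LAI)) / k`` — tends to LAI as k -> 0, saturates at 1/k.
    """
    if LAI < 0.0:
        raise ValueError("LAI must be >= 0")
    if k_ext == 0.0:
        return LAI
    return (1.0 - np.exp(-k_ext * LAI)) / k_ext


def top_leaf_irradiance_factor(stand: StandParams) -> float:
    """Above-canopy flux to top-leaf incident irradiance, per leaf area.

    Beer-law interception at the canopy top corrected for leaf
    transmittance: ``k_ext / (1 - m_leaf)``.
    """
    return stand.k_ext / (1.0 - stand.m_leaf)


def ecosystem_gpp(GPP_c: float, zeta: float) -> float:
    """Ecosystem GPP from canopy GPP via the understory upscale factor."""
    if zeta < 1.0:
        raise ValueError("zeta must be >= 1")
    return zeta * GPP_c


def canopy_transpiration_day(
    gs_pair: tuple[float, float],
    day: ClimateDay,
    stand: StandParams,
    P_atm: float = 101325.0,
) -> float:
    """Daily canopy transpiration (mm day^-1) for a stomatal pair.

    Per SDM-2 segment the canopy conductance is
    ``g_C = 1.6 g_s_top (1 - exp(-k LAI)) / k`` and the instantaneous flux
    ``E_c = g_C VPD / P`` (boundary-layer conductance neglected); segment
    fluxes are integrated over their durations and converted from moles to
    liquid water depth (1 kg m^-2 = 1 mm).
    """
    scale = canopy_scale_factor(stand.LAI, stand.k_ext)
    total_mol = 0.0
    for seg, g_s in zip(day_segments(day, P_atm), gs_pair):
        g_C = 1.6 * g_s * scale
        total_mol += g_C * seg.env.VPD / P_atm * seg.duration * 3600.0
    return total_mol * MOLAR_MASS_H2O * 1e-3  # mol -> kg m^-2 == mm


def _day_fluxes(
    day: ClimateDay,
    gs_pair: tuple[float, float],
    N_mf: float,
    acc: AcclimationState,
    params: ModelParams,
    stand: StandParams,
    n_panels: int,
) -> CanopyFluxDay:
    """Upscale one optimized day to stand fluxes and diagnostics."""
    i_fac = top_leaf_irradiance_factor(stand)
    scale = canopy_scale_factor(stand.LAI, stand.k_ext)
    segs = day_segments(day, params.P_atm, i_fac)
    gpp_mol = 0.0
    ec_mol = 0.0
    psi_min = 0.0
    kcost_min = 1.0
    for seg, g_s in zip(segs, gs_pair):
        env = LeafEnv(
            I_inc=seg.env.I_inc, T_a=seg.env.T_a, c_a=seg.env.c_a,
            VPD=seg.env.VPD, theta=seg.env.theta, P_atm=params.P_atm,
            N_mf=N_mf,
        )
        A_top = photosynthesis.assimilation(g_s, env, acc, params.photo)
        try:
            state = hydraulics.solve_canopy_state(
                g_s, env.VPD, env.theta, stand.H, params.hydro, params.P_atm,
                n_panels=n_panels,
            )
            psi_min = min(psi_min, state.psi_c)
            kcost_min = min(
                kcost_min, hydraulics.k_cost(state.k_sc, params.hydro)
            )
        except hydraulics.NoSolutionError:
            pass
        gpp_mol += A_top * scale * seg.duration * 3600.0
        ec_mol += (
            1.6 * g_s * scale * seg.env.VPD / params.P_atm
            * seg.duration * 3600.0
        )
    gpp_c = gpp_mol * MOLAR_MASS_C
    e_c = ec_mol * MOLAR_MASS_H2O * 1e-3
    wue = gpp_c / e_c if e_c > 0.0 else np.nan
    return CanopyFluxDay(
        date=day.date,
        GPP_c=gpp_c,
        GPP_e=ecosystem_gpp(gpp_c, stand.zeta),
        E_c=e_c,
        WUE=wue,
        psi_c_min=psi_min,
        k_cost_min=kcost_min,
        N_mf=N_mf,
        gs_am=gs_pair[0],
        gs_pm=gs_pair[1],
    )


def run_simulation(
    weather: list[ClimateDay],
    stand: StandParams,
    params: ModelParams,
    opts: OptimizerOptions | None = None,
    static_nmf: float | None = None,
) -> pd.DataFrame:
    """Simulate a growing season: optimize traits weekly, upscale daily.

    The acclimation state advances each day from the daily mean temperature
    (initialized at the first day's temperature); trait optimization runs
    per 7-day block (a trailing partial week is its own block). Days whose
    hydraulic solution fails are clamped to the stomatal floor and flagged,
    never aborted. ``static_nmf`` freezes leaf N at a prescribed value (for
    ablation runs) while stomatal optimization proceeds normally.

    Returns a tidy DataFrame with one row per day.
    """
    if not weather:
        raise ValueError("weather series is empty")
    if opts is None:
        opts = OptimizerOptions()
    accs: list[AcclimationState] = []
    acc = photosynthesis.init_acclimation(weather[0].T_mean, params.photo)
    accs.append(acc)
    for day in weather[1:]:
        acc = photosynthesis.update_acclimation(acc.S_t, day.T_mean, params.photo)
        accs.append(acc)

    i_fac = top_leaf_irradiance_factor(stand)
    rows: list[CanopyFluxDay] = []
    for i0 in range(0, len(weather), 7):
        block = weather[i0 : i0 + 7]
        block_acc = accs[i0 : i0 + 7]
        if static_nmf is None:
            sol = optimal_traits.optimize_week(
                block, block_acc, params, stand.H, opts, i_factor=i_fac
            )
        else:
            sol = _optimize_week_fixed_nmf(
                block, block_acc, params, stand.H, opts, i_fac, static_nmf
            )
        for day, acc_d, pair in zip(block, block_acc, sol.gs_pairs):
            out = _day_fluxes(
                day, pair, sol.N_mf, acc_d, params, stand, opts.n_panels
            )
            if sol.flags:
                out.flag = ";".join(sorted(set(sol.flags)))
            rows.append(out)
    df = pd.DataFrame([vars(r) for r in rows])
    df["date"] = pd.to_datetime(df["date"])
    return df


def _optimize_week_fixed_nmf(
    block, block_acc, params, H, opts, i_fac, nmf
) -> TraitSolution:
    """Weekly optimization with leaf N frozen (static-N ablation)."""
    from scipy import optimize as _opt

    gs_pairs = []
    total = 0.0
    flags: list[str] = []
    for day, acc in zip(block, block_acc):
        segs = day_segments(day, params.P_atm, i_fac)
        his = [
            optimal_traits._segment_gs_bound(s, params, H, opts.n_panels)
            for s in segs
        ]
        if all(h <= opts.gs_lower for h in his):
            flags.append("hydraulic-floor-day")
            gs_pairs.append((opts.gs_lower, opts.gs_lower))
            continue
        bounds = [(opts.gs_lower, max(h, opts.gs_lower * (1 + 1e-9))) for h in his]

        def neg(x):
            return -optimal_traits.daily_fitness(
                (x[0], x[1]), nmf, day, acc, params, H,
                segments=segs, n_panels=opts.n_panels,
                include_night_cost=opts.include_night_cost,
            )

        x0 = [0.5 * (b[0] + b[1]) for b in bounds]
        res = _opt.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": opts.maxiter, "gtol": opts.gtol})
        gs_pairs.append((float(res.x[0]), float(res.x[1])))
        total += -res.fun
    return TraitSolution(
        N_mf=nmf, gs_pairs=gs_pairs, fitness_weekly=total, flags=flags
    )


def trait_weather_correlations(
    outputs: pd.DataFrame, weather: list[ClimateDay]
) -> pd.DataFrame:
    """Pearson correlations of daily traits/WUE against weather drivers.

    Rows: mean daily stomatal conductance, leaf N, and WUE; columns carry
    the correlation coefficient and two-sided p-value against daily PAR,
    mean temperature, VPD and soil water. Constant series yield an
    ``undefined`` flag instead of a coefficient.
    """
    if len(outputs) < 3:
        raise ValueError("need at least 3 days for correlations")
    drivers = {
        "I0": np.array([d.I0 for d in weather]),
        "T_a": np.array([d.T_mean for d in weather]),
        "VPD": np.array([d.VPD_mean for d in weather]),
        "theta": np.array([d.theta for d in weather]),
    }
    traits = {
        "g_s": 0.5 * (outputs["gs_am"] + outputs["gs_pm"]).to_numpy(),
        "N_mf": outputs["N_mf"].to_numpy(),
        "WUE": outputs["WUE"].to_numpy(),
    }
    records = []
    for tname, tvals in traits.items():
        for dname, dvals in drivers.items():
            ok = ~(np.isnan(tvals) | np.isnan(dvals))
            t, d = tvals[ok], dvals[ok]
            if t.size < 3 or np.ptp(t) == 0.0 or np.ptp(d) == 0.0:
                records.append(
                    {"trait": tname, "driver": dname, "r": np.nan,
                     "p": np.nan, "undefined": True}
                )
                continue
            r, p = stats.pearsonr(t, d)
            records.append(
                {"trait": tname, "driver": dname, "r": r, "p": p,
                 "undefined": False}
            )
    return pd.DataFrame(records)
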