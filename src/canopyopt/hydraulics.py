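"""Soil water retention, xylem vulnerability, and the soil–canopy water solver.

Transpiration drawn through the soil–canopy pathway depresses canopy water
potential below its pre-dawn value; the pathway conductance in turn declines
with water potential along a sigmoidal vulnerability curve. The two are
coupled: Darcy's law gives the potential drop for a given conductance, and
the effective conductance is the maximum conductance times the mean of the
vulnerability curve over the traversed potential interval (Simpson's 1/3
rule). The solver iterates this pair to a fixed point.

Sign convention: water potentials are negative (MPa); the vulnerability
function is evaluated on the magnitude ratio ``psi / psi50`` so signs cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from canopyopt.params import HydraulicParams

__all__ = [
    "CanopyWaterState",
    "NoSolutionError",
    "SoilMoistureRangeError",
    "leaf_transpiration",
    "soil_water_potential",
    "vulnerability",
    "solve_canopy_state",
    "critical_gs",
    "k_cost",
]


class NoSolutionError(RuntimeError):
    """The requested transpiration exceeds the runaway-cavitation supply limit."""


class SoilMoistureRangeError(ValueError):
    """Soil water content outside the domain of the retention curve."""


@dataclass
class CanopyWaterState:
    """Solved canopy water status for one instantaneous driver set."""

    psi_c: float  # MPa, canopy water potential
    psi_c_pd: float  # MPa, pre-dawn canopy water potential
    k_sc: float  # mol m^-2 leaf s^-1 MPa^-1, effective conductance
    E_leaf: float  # mol m^-2 leaf s^-1, leaf-area transpiration


def leaf_transpiration(g_s: float, VPD: float, P_atm: float) -> float:
    """Leaf-area transpiration ``E = 1.6 g_s VPD / P`` (mol m^-2 s^-1)."""
    if VPD < 0.0:
        raise ValueError("VPD must be >= 0")
    return 1.6 * g_s * VPD / P_atm


def soil_water_potential(theta: float, h: HydraulicParams) -> float:
    """Brooks–Corey soil water potential (MPa) at volumetric content ``theta``.

    ``psi_s = psi_a * S_e**(-1/lambda)`` with effective saturation
    ``S_e = (theta - theta_r) / (theta_s - theta_r)``.
    """
    if theta <= h.theta_r:
        raise SoilMoistureRangeError(
            f"theta={theta} at or below residual water content {h.theta_r}"
        )
    if theta > h.theta_s:
        raise SoilMoistureRangeError(
            f"theta={theta} above saturation {h.theta_s}"
        )
    S_e = (theta - h.theta_r) / (h.theta_s - h.theta_r)
    return h.psi_a * S_e ** (-1.0 / h.lambda_pore)


def vulnerability(psi, h: HydraulicParams):
    """Fraction of maximum soil–canopy conductance remaining at ``psi`` (MPa).

    ``P(psi) = 0.5 ** ((psi/psi50)**b)``; equals 1 at zero potential and 0.5
    at ``psi50``. Accepts scalars or arrays.
    """
    ratio = np.abs(np.asarray(psi) / h.psi50_sc)
    out = 0.5 ** (ratio**h.b_sc)
    return float(out) if np.isscalar(psi) or np.ndim(psi) == 0 else out


def k_cost(k_sc: float, h: HydraulicParams) -> float:
    """Linear hydraulic-risk discount on assimilation.

    1 at maximum conductance, 0 at the critical conductance
    ``f_crit * k_sc_max`` (the lethal 88 % conductivity loss). May be
    negative below the critical point; the optimizer never accepts such
    states.
    """
    k_crit = h.f_crit * h.k_sc_max
    return (k_sc - k_crit) / (h.k_sc_max - k_crit)


def predawn_potential(theta: float, H: float, h: HydraulicParams) -> float:
    """Pre-dawn canopy water potential: soil potential minus gravity head."""
    return soil_water_potential(theta, h) - H * h.rho_w * h.g_grav * 1e-6


def _simpson_mean_P(psi_c: float, psi_pd: float, h: HydraulicParams, n_panels: int) -> float:
    """Mean of the vulnerability curve over [psi_c, psi_pd], Simpson 1/3 rule."""
    if psi_c == psi_pd:
        return vulnerability(psi_pd, h)
    x = np.linspace(psi_c, psi_pd, 2 * n_panels + 1)
    y = 0.5 ** (np.abs(x / h.psi50_sc) ** h.b_sc)
    w = np.ones_like(y)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    # Simpson integral / interval length == weighted mean with weight sum 6n
    return float(np.dot(w, y) / (6.0 * n_panels))


def solve_canopy_state(
    g_s: float,
    VPD: float,
    theta: float,
    H: float,
    h: HydraulicParams,
    P_atm: float,
    n_panels: int = 50,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> CanopyWaterState:
    """Solve the coupled canopy potential / conductance fixed point.

    Iterates ``k_sc -> k_sc_max * mean(P; psi_c(k_sc), psi_pd)`` with
    ``psi_c = psi_pd - E / k_sc`` from Darcy's law, starting from the
    zero-flux limit ``k_sc_max * P(psi_pd)``. A 0.5 damping factor is applied
    when the iterates oscillate. Raises :class:`NoSolutionError` on runaway
    embolism (transpiration beyond the supply maximum).
    """
    E = leaf_transpiration(g_s, VPD, P_atm)
    psi_pd = predawn_potential(theta, H, h)
    k = h.k_sc_max * vulnerability(psi_pd, h)
    if E == 0.0:
        return CanopyWaterState(psi_c=psi_pd, psi_c_pd=psi_pd, k_sc=k, E_leaf=0.0)

    # Supply maximum: E_sup(psi_c) = k_sc_max * mean_P * (psi_pd - psi_c) is
    # bounded; divergence shows up as psi_c racing to -inf / k collapsing.
    psi_floor = h.psi50_sc * (80.0 ** (1.0 / h.b_sc))  # P ~ 0.5**80, k ~ 0
    prev_step = 0.0
    for _ in range(max_iter):
        psi_c = psi_pd - E / k
        if psi_c < psi_floor:
            raise NoSolutionError(
                "runaway embolism: transpiration exceeds hydraulic supply"
            )
        k_new = h.k_sc_max * _simpson_mean_P(psi_c, psi_pd, h, n_panels)
        step = k_new - k
        if step * prev_step < 0.0:  # oscillation -> damp
            k_new = k + 0.5 * step
            step = k_new - k
        prev_step = step
        if abs(step) <= tol * max(abs(k_new), 1e-300):
            k = k_new
            psi_c = psi_pd - E / k
            resid = k - h.k_sc_max * _simpson_mean_P(psi_c, psi_pd, h, n_panels)
            if abs(resid) > 1e-6 * h.k_sc_max:
                raise NoSolutionError("fixed point did not satisfy residual")
            return CanopyWaterState(psi_c=psi_c, psi_c_pd=psi_pd, k_sc=k, E_leaf=E)
        k = k_new
    raise NoSolutionError("fixed-point iteration did not converge")


def critical_gs(
    VPD: float,
    theta: float,
    H: float,
    h: HydraulicParams,
    P_atm: float,
    n_panels: int = 50,
    gs_upper: float = 10.0,
) -> float:
    """Largest stomatal conductance keeping ``P(psi_c)`` at ``f_crit``.

    At the critical state the canopy potential is known in closed form from
    inverting the vulnerability curve, so the critical transpiration — and
    hence ``g_s`` — follows directly from Darcy's law without root finding.
    Returns ``gs_upper`` when VPD is (near) zero, where transpiration cost
    vanishes.
    """
    psi_pd = predawn_potential(theta, H, h)
    if vulnerability(psi_pd, h) <= h.f_crit:
        raise NoSolutionError(
            "pre-dawn potential already beyond the critical conductance loss"
        )
    # invert P(psi) = f_crit: (psi/psi50)**b = log2(1/f_crit)
    psi_crit = h.psi50_sc * (np.log2(1.0 / h.f_crit)) ** (1.0 / h.b_sc)
    k_at_crit = h.k_sc_max * _simpson_mean_P(psi_crit, psi_pd, h, n_panels)
    E_crit = k_at_crit * (psi_pd - psi_crit)
    if VPD <= 0.0:
        return gs_upper
    g_crit = E_crit * P_atm / (1.6 * VPD)
    return min(g_crit, gs_upper)
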