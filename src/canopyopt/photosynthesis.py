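"""Leaf-level co-limited carbon assimilation.

Assimilation is the balance between biochemical demand — the electron-
transport-limited rate under the coordination (co-limitation) hypothesis —
and CO2 supply through the lumped stomatal+mesophyll conductance
``g = g_ratio * g_s``. Short-term temperature responses use an Arrhenius
form for the CO2 compensation point and a peaked activation/deactivation
form for J_max; seasonal acclimation scales both J_max and the quantum
yield by an activation factor X_t driven by a first-order delayed
temperature S_t.

All public interfaces take temperatures in degrees Celsius; the conversion
to Kelvin happens inside the temperature-response functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from canopyopt.params import PhotoParams, R_GAS

__all__ = [
    "AcclimationState",
    "LeafEnv",
    "gamma_star",
    "f_jmax_temp",
    "update_acclimation",
    "init_acclimation",
    "jmax",
    "electron_transport",
    "solve_ci",
    "assimilation",
]

_C_TO_K = 273.15


class DegenerateInputError(ValueError):
    """Raised when a physically meaningless input makes a solve undefined."""


@dataclass
class AcclimationState:
    """Seasonal acclimation state: delayed temperature and activation factor.

    ``X_t`` is the piecewise-linear image of ``S_t``: 0 at or below
    ``S_min``, 1 at or above ``S_min + delta_S``, linear in between.
    """

    S_t: float  # deg C
    X_t: float  # in [0, 1]


@dataclass
class LeafEnv:
    """Instantaneous environment of a top-of-canopy leaf."""

    I_inc: float  # mol m^-2 s^-1, irradiance incident on the leaf
    T_a: float  # deg C
    c_a: float  # Pa, ambient CO2 partial pressure
    VPD: float = 0.0  # Pa (used by the hydraulics coupling)
    theta: float = 0.2  # soil volumetric water content fraction
    P_atm: float = 101325.0  # Pa
    N_mf: float = 0.02  # kg N per kg leaf


def gamma_star(T_a: float, p: PhotoParams) -> float:
    """CO2 compensation point (Pa) at leaf temperature ``T_a`` (deg C).

    Arrhenius response anchored at ``gamma_star_ref`` for ``T_ref``.
    """
    T = T_a + _C_TO_K
    if T <= 0.0:
        raise ValueError("temperature below absolute zero")
    return p.gamma_star_ref * math.exp(
        p.E_A_gamma * (T - p.T_ref) / (T * R_GAS * p.T_ref)
    )


def f_jmax_temp(T_a: float, p: PhotoParams) -> float:
    """Short-term temperature multiplier of J_max (1 at the optimum).

    Peaked activation/deactivation response: rises with an Arrhenius term in
    the activation energy and is pulled down by the deactivation term above
    ``T_opt``.
    """
    T = T_a + _C_TO_K
    if T <= 0.0:
        raise ValueError("temperature below absolute zero")
    arg = (T - p.T_opt) / (T * R_GAS * p.T_opt)
    denom = p.E_D_J - p.E_A_J * (1.0 - math.exp(p.E_D_J * arg))
    if denom <= 0.0:
        raise ValueError(
            "invalid parameters: deactivation denominator non-positive at "
            f"T={T_a} degC"
        )
    return p.E_D_J * math.exp(p.E_A_J * arg) / denom


def _activation(S_t: float, p: PhotoParams) -> float:
    if S_t <= p.S_min:
        return 0.0
    if p.delta_S == 0.0 or S_t >= p.S_min + p.delta_S:
        return 1.0
    return (S_t - p.S_min) / p.delta_S


def init_acclimation(T_0: float, p: PhotoParams) -> AcclimationState:
    """Initialize the delayed temperature at the first day's temperature."""
    return AcclimationState(S_t=T_0, X_t=_activation(T_0, p))


def update_acclimation(S_prev: float, T_t: float, p: PhotoParams) -> AcclimationState:
    """One daily step of the first-order temperature-delay recursion.

    ``S_t = (1 - 1/tau) * S_prev + (1/tau) * T_t``; the activation factor is
    the piecewise-linear ramp between ``S_min`` and ``S_min + delta_S``.
    """
    S_t = (1.0 - 1.0 / p.tau) * S_prev + T_t / p.tau
    return AcclimationState(S_t=S_t, X_t=_activation(S_t, p))


def jmax(env: LeafEnv, acc: AcclimationState, p: PhotoParams) -> float:
    """Potential electron-transport rate (mol m^-2 s^-1).

    Product of the seasonal activation factor, the N-proportional seasonal
    apex ``a_Jmax * N_mf``, and the short-term temperature multiplier.
    """
    if env.N_mf < 0.0:
        raise ValueError("N_mf must be >= 0")
    return acc.X_t * p.a_Jmax * env.N_mf * f_jmax_temp(env.T_a, p)


def _smaller_quad_root(a: float, b: float, c: float) -> float:
    """Smaller root of a x^2 + b x + c = 0, cancellation-safe (b < 0 here)."""
    disc = b * b - 4.0 * a * c
    disc = max(disc, 0.0)
    q = -0.5 * (b + math.copysign(math.sqrt(disc), b))
    r1 = q / a
    r2 = c / q if q != 0.0 else 0.0
    return min(r1, r2)


def electron_transport(
    I_inc: float, J_max: float, X_t: float, p: PhotoParams
) -> float:
    """Realized electron-transport rate J (mol m^-2 s^-1).

    Smaller root of the non-rectangular hyperbola
    ``theta_J J^2 - (alpha I + J_max) J + alpha I J_max = 0`` with effective
    quantum yield ``alpha = X_t * alpha_season``; ``J_max`` is the fully
    acclimated (X_t-scaled) capacity from :func:`jmax`. The result never
    exceeds ``min(alpha I, J_max)``.
    """
    if I_inc < 0.0 or J_max < 0.0:
        raise ValueError("I_inc and J_max must be >= 0")
    aI = X_t * p.alpha_season * I_inc
    if aI == 0.0 or J_max == 0.0:
        return 0.0
    return _smaller_quad_root(p.theta_J, -(aI + J_max), aI * J_max)


def solve_ci(
    g_s: float, env: LeafEnv, J: float, gamma: float, g_ratio: float = 0.42
) -> float:
    """Intercellular CO2 partial pressure (Pa) balancing supply and demand.

    Greater root of the supply/demand quadratic
    ``c_i^2 + [JP/(4g) + 2 gamma - c_a] c_i - [JP/(4g) gamma + 2 c_a gamma] = 0``
    with ``g = g_ratio * g_s``. With no demand (J = 0) the root is ``c_a``.
    """
    if env.c_a <= 0.0:
        raise DegenerateInputError("c_a must be > 0")
    if g_s <= 0.0:
        raise ValueError("g_s must be > 0")
    g = g_ratio * g_s  # lumped stomatal+mesophyll conductance
    jp4g = J * env.P_atm / (4.0 * g)
    b = jp4g + 2.0 * gamma - env.c_a
    c = -(jp4g * gamma + 2.0 * env.c_a * gamma)
    # greater root, cancellation-safe
    disc = b * b - 4.0 * c
    disc = max(disc, 0.0)
    q = -0.5 * (b + math.copysign(math.sqrt(disc), b)) if b != 0.0 else 0.5 * math.sqrt(disc)
    if q == 0.0:
        return 0.0
    r1 = q
    r2 = c / q
    return max(r1, r2)


def assimilation(
    g_s: float, env: LeafEnv, acc: AcclimationState, p: PhotoParams
) -> float:
    """Net CO2 assimilation rate A (mol m^-2 s^-1) of a top-canopy leaf.

    Computed from Fick's law at the solved intercellular CO2; identical to
    the co-limited demand expression evaluated at the same point.
    """
    J_max = jmax(env, acc, p)
    J = electron_transport(env.I_inc, J_max, acc.X_t, p)
    gamma = gamma_star(env.T_a, p)
    if J == 0.0:
        return 0.0
    c_i = solve_ci(g_s, env, J, gamma, p.g_ratio)
    g = p.g_ratio * g_s
    return g * (env.c_a - c_i) / env.P_atm


def assimilation_demand(J: float, c_i: float, gamma: float) -> float:
    """Co-limited (electron-transport) assimilation at a given c_i.

    Exposed for supply/demand consistency checks.
    """
    return J / 4.0 * (c_i - gamma) / (c_i + 2.0 * gamma)
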