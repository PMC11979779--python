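"""Parameter containers and config-file (de)serialization.

Three parameter groups drive the model: photosynthesis, hydraulics (including
soil retention), and trait-maintenance costs. Defaults are the published
estimates for a long-term fertilization experiment in a boreal Scots pine
stand; every field can be overridden from a YAML config with top-level keys
``photosynthesis``, ``hydraulics``, ``soil``, ``costs``, ``stand`` and
``optimizer``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any

import yaml

#: Universal gas constant, J K^-1 mol^-1.
R_GAS = 8.314
#: Conversion from mol CO2 to g C.
MOLAR_MASS_C = 12.011
#: Molar mass of water, g mol^-1.
MOLAR_MASS_H2O = 18.015
#: Default atmospheric pressure, Pa.
P_ATM_DEFAULT = 101325.0


@dataclass
class PhotoParams:
    """Leaf photosynthesis parameters.

    Temperature-sensitive quantities follow an Arrhenius form for the CO2
    compensation point and a peaked (activation/deactivation) form for the
    potential electron-transport rate J_max. Seasonal acclimation enters
    through a delayed-temperature activation factor, and photosynthetic
    capacity scales linearly with mass-based leaf N concentration.
    """

    gamma_star_ref: float = 4.17  # Pa, CO2 compensation point at T_ref
    E_A_gamma: float = 23.42e3  # J mol^-1, activation energy of gamma*
    E_A_J: float = 47.4e3  # J mol^-1, activation energy of J_max
    E_D_J: float = 200.0e3  # J mol^-1, deactivation energy of J_max
    T_opt: float = 305.0  # K, optimum temperature of J_max
    theta_J: float = 0.7  # curvature of the light response
    alpha_season: float = 0.19  # seasonal apex quantum yield
    a_Jmax: float = 0.02  # mol m^-2 s^-1 per (kg N kg^-1 leaf)
    S_min: float = 0.0  # deg C, activation threshold for photosynthesis
    delta_S: float = 18.29  # deg C, ramp width to full seasonal capacity
    tau: float = 14.87  # days, first-order temperature-delay constant
    g_ratio: float = 0.42  # lumped (stomatal+mesophyll)/stomatal conductance
    T_ref: float = 298.0  # K, reference temperature (printed as 298, not 298.15)

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_J < 1.0):
            raise ValueError("theta_J must be in (0, 1)")
        if self.tau < 1.0:
            raise ValueError("tau must be >= 1 day")
        if self.delta_S < 0.0:
            raise ValueError("delta_S must be >= 0")
        if not (0.0 < self.g_ratio <= 1.0):
            raise ValueError("g_ratio must be in (0, 1]")
        for name in ("E_A_gamma", "E_A_J", "E_D_J"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class HydraulicParams:
    """Soil–canopy hydraulics and Brooks–Corey soil retention parameters.

    The vulnerability curve gives the fraction of maximum soil–canopy
    conductance remaining at water potential psi; ``f_crit`` is the fraction
    at the lethal 88 % loss of conductivity, below which the hydraulic cost
    factor is exhausted.
    """

    k_sc_max: float = 0.00067  # mol m^-2 leaf s^-1 MPa^-1 (control stand)
    psi50_sc: float = -2.7  # MPa, 50 % conductivity-loss potential
    b_sc: float = 2.15  # vulnerability shape parameter
    f_crit: float = 0.12  # remaining-conductance fraction at lethal loss
    theta_s: float = 0.41  # saturated volumetric water content
    theta_r: float = 0.006  # residual volumetric water content
    psi_a: float = -0.098  # MPa, air-entry tension
    lambda_pore: float = 1.0  # pore-size distribution index
    rho_w: float = 997.0  # kg m^-3, water density
    g_grav: float = 9.82  # m s^-2, gravitational acceleration

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_r < self.theta_s <= 1.0):
            raise ValueError("require 0 <= theta_r < theta_s <= 1")
        if self.psi50_sc >= 0.0 or self.psi_a >= 0.0:
            raise ValueError("psi50_sc and psi_a must be negative")
        if not (0.0 < self.f_crit < 1.0):
            raise ValueError("f_crit must be in (0, 1)")
        if self.k_sc_max <= 0.0:
            raise ValueError("k_sc_max must be > 0")


@dataclass
class CostParams:
    """Carbon costs of maintaining photosynthetic capacity.

    ``N_r`` is the ratio of dark respiration to J_max (leaf plus supporting
    tissue respiration); ``N_u`` is the treatment-specific carbon cost of N
    uptake (fine roots, mycorrhiza, exudation) per unit J_max.
    """

    N_r: float = 0.0056
    N_u: float = 0.012  # control-stand estimate; fertilized stand: 0.0

    def __post_init__(self) -> None:
        if self.N_r < 0.0 or self.N_u < 0.0:
            raise ValueError("N_r and N_u must be >= 0")


@dataclass
class StandParams:
    """Stand descriptors and canopy radiation parameters."""

    H: float = 21.1  # m, canopy height
    LAI: float = 2.25  # m^2 m^-2, projected leaf area index
    k_ext: float = 0.52  # canopy light extinction coefficient
    m_leaf: float = 0.05  # leaf transmittance
    zeta: float = 1.13  # ecosystem/canopy GPP upscale factor

    def __post_init__(self) -> None:
        if self.LAI < 0.0:
            raise ValueError("LAI must be >= 0")
        if not (0.0 < self.k_ext < 1.5):
            raise ValueError("k_ext must be in (0, 1.5)")
        if self.zeta < 1.0:
            raise ValueError("zeta must be >= 1")


@dataclass
class OptimizerOptions:
    """Knobs for the trait-optimization routine.

    ``fidelity='full'`` runs three deterministic multistarts and the per-day
    fine-tuning step; ``fidelity='fast'`` runs a single start and applies the
    week-average stomatal pair to every day — used inside calibration loops
    where the optimization is re-run thousands of times.
    """

    fidelity: str = "full"  # 'full' or 'fast'
    n_panels: int = 50  # Simpson panels in the hydraulic solver
    gtol: float = 1e-8
    maxiter: int = 200
    gs_lower: float = 0.001  # mol m^-2 s^-1, stomatal search floor
    nmf_bounds: tuple[float, float] = (0.007, 0.05)
    include_night_cost: bool = False  # fitness integrated over daylight only


@dataclass
class ModelParams:
    """Bundle of all parameter groups plus physical constants."""

    photo: PhotoParams = field(default_factory=PhotoParams)
    hydro: HydraulicParams = field(default_factory=HydraulicParams)
    costs: CostParams = field(default_factory=CostParams)
    P_atm: float = P_ATM_DEFAULT

    def replace(self, **kwargs: Any) -> "ModelParams":
        return replace(self, **kwargs)


_SOIL_FIELDS = ("theta_s", "theta_r", "psi_a", "lambda_pore")


def params_to_dict(params: ModelParams, stand: StandParams | None = None) -> dict:
    """Serialize parameter groups to a plain dict (YAML-ready)."""
    hydro = asdict(params.hydro)
    soil = {k: hydro.pop(k) for k in _SOIL_FIELDS}
    out = {
        "photosynthesis": asdict(params.photo),
        "hydraulics": hydro,
        "soil": soil,
        "costs": asdict(params.costs),
        "P_atm": params.P_atm,
    }
    if stand is not None:
        out["stand"] = asdict(stand)
    return out


def params_from_dict(cfg: dict) -> ModelParams:
    """Build :class:`ModelParams` from a (possibly partial) config dict."""
    hydro_cfg = dict(cfg.get("hydraulics", {}))
    hydro_cfg.update(cfg.get("soil", {}))
    return ModelParams(
        photo=PhotoParams(**cfg.get("photosynthesis", {})),
        hydro=HydraulicParams(**hydro_cfg),
        costs=CostParams(**cfg.get("costs", {})),
        P_atm=float(cfg.get("P_atm", P_ATM_DEFAULT)),
    )


def load_params(path: str | Path) -> ModelParams:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return params_from_dict(cfg)


def load_stand(path: str | Path) -> StandParams:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return StandParams(**cfg.get("stand", cfg))


def save_params(params: ModelParams, path: str | Path, stand: StandParams | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params, stand), fh, sort_keys=False)
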