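"""Shared fixtures: default parameter sets and small synthetic forcings."""

from __future__ import annotations

from datetime import date

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from canopyopt.params import (
    CostParams,
    HydraulicParams,
    ModelParams,
    PhotoParams,
    StandParams,
)
from canopyopt.photosynthesis import AcclimationState
from canopyopt.weatherlab import ClimateDay


@pytest.fixture
def photo() -> PhotoParams:
    return PhotoParams()


@pytest.fixture
def hydro() -> HydraulicParams:
    return HydraulicParams()


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def fertilized_params() -> ModelParams:
    """Fertilized-stand parameter estimates: free N uptake, lower conductance."""
    return ModelParams(
        costs=CostParams(N_u=0.0),
        hydro=HydraulicParams(k_sc_max=0.00057),
    )


@pytest.fixture
def stand() -> StandParams:
    return StandParams()


@pytest.fixture
def active_acc() -> AcclimationState:
    """Fully activated mid-season acclimation state."""
    return AcclimationState(S_t=20.0, X_t=1.0)


def make_day(
    T_mean: float = 15.0,
    T_min: float = 9.0,
    T_max: float = 21.0,
    I0: float = 35.0,
    c_a: float = 40.0,
    VPD_mean: float = 600.0,
    theta: float = 0.20,
    dt_g: float = 18.0,
    day_of_season: int = 0,
) -> ClimateDay:
    """A benign mid-season day, individually overridable."""
    from datetime import timedelta

    return ClimateDay(
        date=date(2017, 6, 15) + timedelta(days=day_of_season),
        T_mean=T_mean, T_min=T_min, T_max=T_max, I0=I0, c_a=c_a,
        VPD_mean=VPD_mean, theta=theta, dt_g=dt_g,
    )


@pytest.fixture
def benign_day() -> ClimateDay:
    return make_day()


@pytest.fixture
def benign_week() -> list[ClimateDay]:
    return [make_day(day_of_season=i) for i in range(7)]
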