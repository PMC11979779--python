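"""Weather I/O, derived drivers, and a seeded synthetic weather generator.

The model is forced by daily weather: min/mean/max air temperature, daily
photosynthetically active radiation (PAR), ambient CO2 partial pressure,
daily-mean vapor pressure deficit, soil volumetric water content, and
daylight hours. This module reads and writes that table as CSV, derives the
secondary drivers (PAR from solar radiation, VPD from vapor pressure, day
length from latitude, growing-season masks, CO2 gap-filling) and generates
realistic synthetic seasons for testing and experimentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date as _date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClimateDay",
    "SynthConfig",
    "par_from_solar",
    "saturated_vapor_pressure",
    "day_length",
    "growing_season",
    "gapfill_co2",
    "synthesize_weather",
    "read_weather_csv",
    "write_weather_csv",
    "interpolate_gaps",
]

#: Conversion 1000 W m^-2 of solar radiation ~ 2300 umol m^-2 s^-1 PAR.
PAR_PER_WATT = 2.3

#: Driver bounds observed at the study site during the growth periods:
#: (T_a degC, I0 mol m^-2 d^-1, VPD Pa, theta fraction, c_a Pa, daylight h).
SITE_RANGES = {
    "T_a": (-5.1, 30.8),
    "I0": (1.8, 63.5),
    "VPD": (45.5, 1420.0),
    "theta": (0.067, 0.298),
    "c_a": (38.5, 40.9),
    "dt_g": (10.2, 20.3),
}

SITE_LATITUDE = 64.17  # degrees N


@dataclass
class ClimateDay:
    """One day of (observed or synthetic) model forcing."""

    date: _date
    T_mean: float  # deg C
    T_min: float  # deg C
    T_max: float  # deg C
    I0: float  # mol m^-2 day^-1 PAR above the canopy
    c_a: float  # Pa, ambient CO2 partial pressure
    VPD_mean: float  # Pa, daily-mean vapor pressure deficit
    theta: float  # volumetric soil water content, fraction
    dt_g: float  # h, daylight hours

    def __post_init__(self) -> None:
        if not (self.T_min <= self.T_mean <= self.T_max):
            raise ValueError("require T_min <= T_mean <= T_max")
        if not (0.0 < self.dt_g <= 24.0):
            raise ValueError("daylight hours must be in (0, 24]")
        for name in ("I0", "VPD_mean", "theta"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")


def par_from_solar(W_m2: float) -> float:
    """Convert solar radiation (W m^-2) to PAR photon flux (umol m^-2 s^-1)."""
    if W_m2 < 0.0:
        raise ValueError("radiation must be >= 0")
    return PAR_PER_WATT * W_m2


def daily_par_from_mean_solar(W_m2_mean: float, dt_g: float) -> float:
    """Daily PAR total (mol m^-2 day^-1) from daily-mean solar radiation.

    Converts with 2.3 umol J^-1 and integrates over the daylight period.
    """
    return par_from_solar(W_m2_mean) * dt_g * 3600.0 * 1e-6


def saturated_vapor_pressure(T_a: float) -> float:
    """Saturation vapor pressure (Pa) over water, Magnus/Tetens form.

    ``e_sat = 610.78 * exp(17.27 T / (T + 237.3))`` with T in deg C.
    """
    return 610.78 * math.exp(17.27 * T_a / (T_a + 237.3))


def day_length(latitude: float, day_of_year: int | np.ndarray) -> float | np.ndarray:
    """Astronomical day length (h) from latitude and day of year.

    CBM model (solar declination + hour angle, sun-center crossing, no
    twilight allowance); saturates at 0/24 h for polar night/day.
    """
    if np.any(np.abs(latitude) > 90.0):
        raise ValueError("latitude must be within [-90, 90] degrees")
    doy = np.asarray(day_of_year, dtype=float)
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.00860 * (doy - 186.0)))
    phi = np.arcsin(0.39795 * np.cos(theta))
    lat = math.radians(latitude)
    cos_arg = (np.sin(lat) * np.sin(phi)) / (np.cos(lat) * np.cos(phi))
    cos_arg = np.clip(cos_arg, -1.0, 1.0)
    D = 24.0 - (24.0 / math.pi) * np.arccos(cos_arg)
    return float(D) if np.ndim(day_of_year) == 0 else D


def growing_season(T_mean: np.ndarray, threshold: float = 5.0, run: int = 5):
    """Growing-season indices from a daily mean-temperature series.

    The season starts on the first day of the first ``run``-day stretch at or
    above ``threshold`` and ends the day before the first subsequent
    ``run``-day stretch strictly below it. Returns ``(start, end)`` inclusive
    indices, or ``None`` when no season exists.
    """
    T = np.asarray(T_mean, dtype=float)
    if T.size < 2 * run:
        raise ValueError("series too short to diagnose a growing season")
    warm = T >= threshold
    start = _first_run(warm, run)
    if start is None:
        return None
    cold = ~warm
    cold[: start + run] = False
    end_run = _first_run(cold, run)
    end = T.size - 1 if end_run is None else end_run - 1
    return (start, end)


def _first_run(mask: np.ndarray, run: int) -> int | None:
    count = 0
    for i, flag in enumerate(mask):
        count = count + 1 if flag else 0
        if count == run:
            return i - run + 1
    return None


def gapfill_co2(
    level1: np.ndarray,
    level2: np.ndarray,
    slope: float = 0.783,
    intercept: float = 781.0,
) -> np.ndarray:
    """Fill gaps (NaN) in a primary CO2 series from a companion series.

    Gaps are filled by the linear map ``level1 = slope * level2 + intercept``
    (coefficients in as-recorded instrument units); non-gap values are left
    untouched. Raises when a gap has no companion value.
    """
    l1 = np.asarray(level1, dtype=float).copy()
    l2 = np.asarray(level2, dtype=float)
    gaps = np.isnan(l1)
    if np.any(gaps & np.isnan(l2)):
        raise ValueError("gap without a companion (level-2) value")
    l1[gaps] = slope * l2[gaps] + intercept
    return l1


def fit_co2_map(level1: np.ndarray, level2: np.ndarray) -> tuple[float, float]:
    """Least-squares (slope, intercept) of level1 on level2 over their overlap."""
    l1 = np.asarray(level1, dtype=float)
    l2 = np.asarray(level2, dtype=float)
    ok = ~(np.isnan(l1) | np.isnan(l2))
    if ok.sum() < 2:
        raise ValueError("need at least two overlapping points")
    slope, intercept = np.polyfit(l2[ok], l1[ok], 1)
    return float(slope), float(intercept)


# ---------------------------------------------------------------------------
# Synthetic weather
# ---------------------------------------------------------------------------


@dataclass
class SynthConfig:
    """Configuration of the synthetic season generator.

    Defaults emulate the boreal study site: a 150-day growth season at
    64.17 deg N with a seasonal temperature wave, AR(1) weather noise,
    cloudiness-modulated radiation, humidity-derived VPD, and a slowly
    drifting soil-moisture regime. All generated series are clipped to
    ``bounds`` (site-observed driver ranges by default).
    """

    n_days: int = 150
    start_doy: int = 121  # ~1 May
    latitude: float = SITE_LATITUDE
    seed: int = 0
    year: int = 2017
    T_season_mean: float = 11.0  # deg C, mid-season mean
    T_season_amp: float = 8.0  # deg C, seasonal half-range
    T_ar1: float = 0.65
    T_noise_sd: float = 2.2  # deg C, day-to-day innovation
    T_diurnal_range: float = 9.0  # deg C, mean T_max - T_min
    clear_sky_peak: float = 58.0  # mol m^-2 d^-1 PAR at solstice, clear sky
    cloud_ar1: float = 0.5
    rh_mean: float = 0.72  # mean relative humidity
    rh_ar1: float = 0.7
    rh_sd: float = 0.10
    theta_mean: float = 0.18
    theta_ar1: float = 0.92
    theta_sd: float = 0.012
    drought: tuple[int, int, float] | None = None  # (start, end, theta_low)
    c_a_start: float = 40.5  # Pa
    c_a_end: float = 39.0  # Pa
    bounds: dict = field(default_factory=lambda: dict(SITE_RANGES))


def synthesize_weather(cfg: SynthConfig) -> list[ClimateDay]:
    """Generate a seeded, reproducible synthetic growth season.

    Temperature is a seasonal sinusoid plus AR(1) noise; radiation is a
    clear-sky envelope tied to day length times an AR(1) cloudiness
    fraction; VPD comes from the Magnus saturation pressure and an AR(1)
    relative humidity (so bright days carry higher VPD); soil moisture is a
    persistent AR(1) regime with an optional scheduled drought dip; CO2
    ramps slowly downward over the season. All series are clipped to the
    configured driver bounds.
    """
    if cfg.n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not (0.0 < cfg.rh_mean < 1.0):
        raise ValueError("rh_mean must be in (0, 1)")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_days
    doy = cfg.start_doy + np.arange(n)
    lo, hi = {}, {}
    for key, (a, b) in cfg.bounds.items():
        lo[key], hi[key] = a, b

    dt_g = np.clip(day_length(cfg.latitude, doy), lo["dt_g"], hi["dt_g"])

    # seasonal temperature wave peaking ~mid July (doy 200)
    season = np.cos((doy - 200.0) / 365.25 * 2.0 * math.pi)
    T_base = cfg.T_season_mean + cfg.T_season_amp * season
    noise = np.empty(n)
    x = 0.0
    innov = rng.normal(0.0, cfg.T_noise_sd, n)
    for i in range(n):
        x = cfg.T_ar1 * x + innov[i]
        noise[i] = x
    T_mean = np.clip(T_base + noise, lo["T_a"] + 2.0, hi["T_a"] - 3.0)
    half_range = 0.5 * cfg.T_diurnal_range * rng.uniform(0.7, 1.3, n)
    T_min = np.clip(T_mean - half_range, lo["T_a"], None)
    T_max = np.clip(T_mean + half_range, None, hi["T_a"])

    # cloudiness: AR(1) latent variable mapped to a [0.25, 1] clear fraction
    z = np.empty(n)
    x = 0.0
    innov = rng.normal(0.0, 1.0, n)
    for i in range(n):
        x = cfg.cloud_ar1 * x + math.sqrt(1.0 - cfg.cloud_ar1**2) * innov[i]
        z[i] = x
    clear_frac = 0.25 + 0.75 / (1.0 + np.exp(-z))
    envelope = cfg.clear_sky_peak * (dt_g / dt_g.max()) ** 2
    I0 = np.clip(envelope * clear_frac, lo["I0"], hi["I0"])

    # relative humidity AR(1); sunnier days are drier (cloud coupling)
    x = 0.0
    innov = rng.normal(0.0, 1.0, n)
    rh = np.empty(n)
    for i in range(n):
        x = cfg.rh_ar1 * x + math.sqrt(1.0 - cfg.rh_ar1**2) * innov[i]
        rh[i] = x
    rh = cfg.rh_mean + cfg.rh_sd * rh - 0.08 * (clear_frac - clear_frac.mean())
    rh = np.clip(rh, 0.35, 0.98)
    e_sat = np.array([saturated_vapor_pressure(t) for t in T_mean])
    VPD = np.clip((1.0 - rh) * e_sat, lo["VPD"], hi["VPD"])

    # soil moisture: persistent AR(1) around the regime mean
    x = 0.0
    innov = rng.normal(0.0, 1.0, n)
    theta = np.empty(n)
    for i in range(n):
        x = cfg.theta_ar1 * x + math.sqrt(1.0 - cfg.theta_ar1**2) * innov[i]
        theta[i] = cfg.theta_mean + cfg.theta_sd * x
    if cfg.drought is not None:
        d0, d1, theta_low = cfg.drought
        if not (0 <= d0 <= d1 < n):
            raise ValueError("drought window outside the season")
        window = np.arange(d0, d1 + 1)
        shape = np.sin(math.pi * (window - d0) / max(d1 - d0, 1))
        theta[window] = np.minimum(
            theta[window], cfg.theta_mean - (cfg.theta_mean - theta_low) * shape
        )
    theta = np.clip(theta, lo["theta"], hi["theta"])

    c_a = np.clip(
        np.linspace(cfg.c_a_start, cfg.c_a_end, n), lo["c_a"], hi["c_a"]
    )

    start = _date(cfg.year, 1, 1) + timedelta(days=int(cfg.start_doy) - 1)
    return [
        ClimateDay(
            date=start + timedelta(days=i),
            T_mean=float(T_mean[i]),
            T_min=float(min(T_min[i], T_mean[i])),
            T_max=float(max(T_max[i], T_mean[i])),
            I0=float(I0[i]),
            c_a=float(c_a[i]),
            VPD_mean=float(VPD[i]),
            theta=float(theta[i]),
            dt_g=float(dt_g[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_COLUMNS = [
    "date", "T_mean", "T_min", "T_max", "I0", "c_a", "VPD_mean", "theta", "dt_g",
]
#: Units of each weather column (documented in the CSV header comment).
COLUMN_UNITS = {
    "date": "ISO-8601",
    "T_mean": "degC", "T_min": "degC", "T_max": "degC",
    "I0": "mol m-2 day-1 (PAR)",
    "c_a": "Pa", "VPD_mean": "Pa",
    "theta": "fraction (percent values are divided by 100 at ingest)",
    "dt_g": "h",
}


def weather_to_frame(days: list[ClimateDay]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(d) for d in days])
    return df[_COLUMNS]


def frame_to_weather(df: pd.DataFrame) -> list[ClimateDay]:
    days = []
    for row in df.itertuples(index=False):
        theta = row.theta
        if theta > 1.0:  # given as percent
            theta = theta / 100.0
        d = row.date
        if isinstance(d, str):
            d = _date.fromisoformat(d)
        elif isinstance(d, pd.Timestamp):
            d = d.date()
        days.append(
            ClimateDay(
                date=d, T_mean=row.T_mean, T_min=row.T_min, T_max=row.T_max,
                I0=row.I0, c_a=row.c_a, VPD_mean=row.VPD_mean,
                theta=theta, dt_g=row.dt_g,
            )
        )
    return days


def write_weather_csv(days: list[ClimateDay], path: str | Path) -> None:
    """Write the forcing table with a units line in a leading comment."""
    units = "# units: " + ", ".join(f"{c}={COLUMN_UNITS[c]}" for c in _COLUMNS)
    df = weather_to_frame(days)
    with open(path, "w") as fh:
        fh.write(units + "\n")
        df.to_csv(fh, index=False)


def read_weather_csv(path: str | Path) -> list[ClimateDay]:
    df = pd.read_csv(path, comment="#")
    return frame_to_weather(df)


def interpolate_gaps(df: pd.DataFrame, max_gap: int = 2) -> pd.DataFrame:
    """Linearly fill short runs of missing values (never applied silently).

    Raises when any gap is longer than ``max_gap`` days.
    """
    out = df.copy()
    for col in out.columns:
        if col == "date":
            continue
        s = out[col]
        if not s.isna().any():
            continue
        gap_runs = (s.isna().astype(int).groupby(s.notna().cumsum()).sum()).max()
        if gap_runs > max_gap:
            raise ValueError(f"column {col!r} has a gap longer than {max_gap} days")
        out[col] = s.interpolate(limit=max_gap, limit_direction="both")
    return out
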