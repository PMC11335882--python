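"""Canadian Fire Weather Index System on grids.

Implements the standard daily moisture codes (FFMC, DMC, DC), the
behaviour indices (ISI, BUI, FWI), fire-season startup/shutdown from
consecutive-day temperature rules, and Drought Code overwintering via
the moisture-equivalent carryover.  All update functions are written
vectorised over numpy arrays so a whole grid advances one day per call;
the scalar dataclass wrappers delegate to the same code paths.

Constants below are the published system constants.  Day-length (DMC)
and seasonal day-length adjustment (DC) factors are the conventional
mid-latitude monthly tables:

month        J     F     M     A     M     J     J     A     S     O     N     D
DMC  L_e   6.5   7.5   9.0  12.8  13.9  13.9  12.4  10.9   9.4   8.0   7.0   6.0
DC   L_f  -1.6  -1.6  -1.6   0.9   3.8   5.8   6.4   5.0   2.4   0.4  -1.6  -1.6
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "WeatherObs",
    "CodeState",
    "FwiIndices",
    "SeasonRules",
    "OverwinterParams",
    "DEFAULT_STARTUP",
    "ffmc_update",
    "dmc_update",
    "dc_update",
    "initial_spread_index",
    "buildup_index",
    "fire_weather_index",
    "update_codes",
    "compute_indices",
    "season_mask",
    "overwinter_dc",
    "run_fwi_grid",
]

# day-length factors for the DMC log-drying rate, by month
DAY_LENGTH_DMC = np.array(
    [6.5, 7.5, 9.0, 12.8, 13.9, 13.9, 12.4, 10.9, 9.4, 8.0, 7.0, 6.0]
)
# seasonal day-length adjustment for the DC potential evapotranspiration
DAY_LENGTH_DC = np.array(
    [-1.6, -1.6, -1.6, 0.9, 3.8, 5.8, 6.4, 5.0, 2.4, 0.4, -1.6, -1.6]
)


@dataclass(frozen=True)
class WeatherObs:
    """Noon surface weather for one day: °C, %, km/h, mm (24-h)."""

    temp_c: float
    rh_pct: float
    wind_kmh: float
    precip_mm: float
    date: _date

    def __post_init__(self):
        if not 0.0 <= self.rh_pct <= 100.0:
            raise ValueError(f"rh_pct out of [0, 100]: {self.rh_pct}")
        if self.wind_kmh < 0.0:
            raise ValueError(f"negative wind_kmh: {self.wind_kmh}")
        if self.precip_mm < 0.0:
            raise ValueError(f"negative precip_mm: {self.precip_mm}")


@dataclass(frozen=True)
class CodeState:
    """The three moisture codes."""

    ffmc: float
    dmc: float
    dc: float

    def __post_init__(self):
        if not 0.0 <= self.ffmc <= 101.0:
            raise ValueError(f"ffmc out of [0, 101]: {self.ffmc}")
        if self.dmc < 0.0 or self.dc < 0.0:
            raise ValueError("dmc and dc must be >= 0")


@dataclass(frozen=True)
class FwiIndices:
    isi: float
    bui: float
    fwi: float


@dataclass(frozen=True)
class SeasonRules:
    """Fire-season startup/shutdown thresholds on daily maximum temperature."""

    start_temp_c: float = 12.0
    stop_temp_c: float = 5.0
    run_days: int = 3

    def __post_init__(self):
        if self.run_days < 1:
            raise ValueError("run_days must be >= 1")
        if self.start_temp_c <= self.stop_temp_c:
            raise ValueError("start_temp_c must exceed stop_temp_c")


@dataclass(frozen=True)
class OverwinterParams:
    """Carryover fraction ``a`` and winter-rain effectiveness ``b``."""

    a: float = 0.75
    b: float = 0.75

    def __post_init__(self):
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.b <= 1.0):
            raise ValueError("overwinter coefficients must lie in [0, 1]")


#: conventional agency startup defaults where no overwinter history exists
DEFAULT_STARTUP = CodeState(ffmc=85.0, dmc=6.0, dc=15.0)


# ---------------------------------------------------------------------------
# vectorised daily update equations
# ---------------------------------------------------------------------------

def ffmc_update(ffmc0, temp, rh, wind, precip):
    """Next-day Fine Fuel Moisture Code (array-safe)."""
    ffmc0 = np.asarray(ffmc0, dtype=float)
    temp = np.asarray(temp, dtype=float)
    rh = np.asarray(rh, dtype=float)
    wind = np.asarray(wind, dtype=float)
    precip = np.asarray(precip, dtype=float)

    mo = 147.2 * (101.0 - ffmc0) / (59.5 + ffmc0)

    # rainfall phase (effective rain above the 0.5 mm canopy threshold)
    rf = np.maximum(precip - 0.5, 0.0)
    rainy = precip > 0.5
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        mr = mo + 42.5 * rf * np.exp(-100.0 / (251.0 - mo)) * (
            1.0 - np.exp(-6.93 / np.where(rf > 0, rf, 1.0))
        )
        mr = np.where(
            mo > 150.0,
            mr + 0.0015 * (mo - 150.0) ** 2 * np.sqrt(rf),
            mr,
        )
    mr = np.minimum(mr, 250.0)
    mo = np.where(rainy, mr, mo)

    ed = (
        0.942 * rh**0.679
        + 11.0 * np.exp((rh - 100.0) / 10.0)
        + 0.18 * (21.1 - temp) * (1.0 - np.exp(-0.115 * rh))
    )
    ew = (
        0.618 * rh**0.753
        + 10.0 * np.exp((rh - 100.0) / 10.0)
        + 0.18 * (21.1 - temp) * (1.0 - np.exp(-0.115 * rh))
    )

    # drying above equilibrium
    ko = 0.424 * (1.0 - (rh / 100.0) ** 1.7) + 0.0694 * np.sqrt(wind) * (
        1.0 - (rh / 100.0) ** 8
    )
    kd = ko * 0.581 * np.exp(0.0365 * temp)
    m_dry = ed + (mo - ed) * 10.0**-kd

    # wetting below equilibrium
    k1 = 0.424 * (1.0 - ((100.0 - rh) / 100.0) ** 1.7) + 0.0694 * np.sqrt(
        wind
    ) * (1.0 - ((100.0 - rh) / 100.0) ** 8)
    kw = k1 * 0.581 * np.exp(0.0365 * temp)
    m_wet = ew - (ew - mo) * 10.0**-kw

    m = np.where(mo > ed, m_dry, np.where(mo < ew, m_wet, mo))
    ffmc = 59.5 * (250.0 - m) / (147.2 + m)
    return np.clip(ffmc, 0.0, 101.0)


def dmc_update(dmc0, temp, rh, precip, month):
    """Next-day Duff Moisture Code; ``month`` is 1..12 (array-safe)."""
    dmc0 = np.asarray(dmc0, dtype=float)
    temp = np.asarray(temp, dtype=float)
    rh = np.asarray(rh, dtype=float)
    precip = np.asarray(precip, dtype=float)
    month = np.asarray(month, dtype=int)

    rainy = precip > 1.5
    re = 0.92 * precip - 1.27
    mo = 20.0 + 280.0 / np.exp(0.023 * dmc0)
    b = np.where(
        dmc0 <= 33.0,
        100.0 / (0.5 + 0.3 * dmc0),
        np.where(
            dmc0 <= 65.0,
            14.0 - 1.3 * np.log(np.maximum(dmc0, 1e-12)),
            6.2 * np.log(np.maximum(dmc0, 1e-12)) - 17.2,
        ),
    )
    mr = mo + 1000.0 * re / (48.77 + b * re)
    pr = np.maximum(43.43 * (5.6348 - np.log(np.maximum(mr - 20.0, 1e-12))), 0.0)
    dmc_after_rain = np.where(rainy, pr, dmc0)

    le = DAY_LENGTH_DMC[month - 1]
    k = np.where(
        temp > -1.1,
        1.894 * (temp + 1.1) * (100.0 - rh) * le * 1e-6,
        0.0,
    )
    return np.maximum(dmc_after_rain + 100.0 * k, 0.0)


def dc_update(dc0, temp, precip, month):
    """Next-day Drought Code; ``month`` is 1..12 (array-safe)."""
    dc0 = np.asarray(dc0, dtype=float)
    temp = np.asarray(temp, dtype=float)
    precip = np.asarray(precip, dtype=float)
    month = np.asarray(month, dtype=int)

    rainy = precip > 2.8
    rd = 0.83 * precip - 1.27
    qo = 800.0 * np.exp(-dc0 / 400.0)
    qr = qo + 3.937 * rd
    dr = np.maximum(400.0 * np.log(800.0 / np.maximum(qr, 1e-12)), 0.0)
    dc_after_rain = np.where(rainy, dr, dc0)

    lf = DAY_LENGTH_DC[month - 1]
    v = np.maximum(0.36 * (np.maximum(temp, -2.8) + 2.8) + lf, 0.0)
    return np.maximum(dc_after_rain + 0.5 * v, 0.0)


def initial_spread_index(ffmc, wind):
    """ISI from FFMC and 10-m wind (km/h), array-safe."""
    ffmc = np.asarray(ffmc, dtype=float)
    wind = np.asarray(wind, dtype=float)
    if np.any(wind < 0):
        raise ValueError("negative wind speed")
    m = 147.2 * (101.0 - ffmc) / (59.5 + ffmc)
    fw = np.exp(0.05039 * wind)
    ff = 91.9 * np.exp(-0.1386 * m) * (1.0 + m**5.31 / 4.93e7)
    return 0.208 * fw * ff


def buildup_index(dmc, dc):
    """BUI from DMC and DC, array-safe."""
    dmc = np.asarray(dmc, dtype=float)
    dc = np.asarray(dc, dtype=float)
    denom = dmc + 0.4 * dc
    with np.errstate(divide="ignore", invalid="ignore"):
        low = np.where(denom > 0, 0.8 * dmc * dc / denom, 0.0)
        high = dmc - (1.0 - 0.8 * dc / np.where(denom > 0, denom, 1.0)) * (
            0.92 + (0.0114 * dmc) ** 1.7
        )
    bui = np.where(dmc <= 0.4 * dc, low, high)
    return np.maximum(bui, 0.0)


def fire_weather_index(isi, bui):
    """FWI from ISI and BUI, array-safe."""
    isi = np.asarray(isi, dtype=float)
    bui = np.asarray(bui, dtype=float)
    fd = np.where(
        bui <= 80.0,
        0.626 * bui**0.809 + 2.0,
        1000.0 / (25.0 + 108.64 * np.exp(-0.023 * bui)),
    )
    b = 0.1 * isi * fd
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(
            b > 1.0,
            np.exp(2.72 * (0.434 * np.log(np.maximum(b, 1e-12))) ** 0.647),
            b,
        )
    return np.maximum(s, 0.0)


# ---------------------------------------------------------------------------
# scalar interface
# ---------------------------------------------------------------------------

def update_codes(prev: CodeState, obs: WeatherObs) -> CodeState:
    """Advance the three moisture codes by one day of noon weather."""
    month = obs.date.month
    return CodeState(
        ffmc=float(ffmc_update(prev.ffmc, obs.temp_c, obs.rh_pct, obs.wind_kmh, obs.precip_mm)),
        dmc=float(dmc_update(prev.dmc, obs.temp_c, obs.rh_pct, obs.precip_mm, month)),
        dc=float(dc_update(prev.dc, obs.temp_c, obs.precip_mm, month)),
    )


def compute_indices(codes: CodeState, wind_kmh: float) -> FwiIndices:
    """ISI, BUI and FWI from today's codes and noon wind."""
    if wind_kmh < 0:
        raise ValueError("negative wind speed")
    isi = float(initial_spread_index(codes.ffmc, wind_kmh))
    bui = float(buildup_index(codes.dmc, codes.dc))
    return FwiIndices(isi=isi, bui=bui, fwi=float(fire_weather_index(isi, bui)))


# ---------------------------------------------------------------------------
# season mask and overwintering
# ---------------------------------------------------------------------------

def season_mask(tmax_series: np.ndarray, rules: SeasonRules = SeasonRules()) -> np.ndarray:
    """Fire-season active mask from daily maximum temperature.

    ``tmax_series`` has time on axis 0 (any trailing cell axes).  The
    season turns on the day *after* ``run_days`` consecutive days above
    ``start_temp_c``, and off the day after ``run_days`` consecutive days
    below ``stop_temp_c``; multiple cycles per series are allowed.
    """
    t = np.asarray(tmax_series, dtype=float)
    squeeze = t.ndim == 1
    if squeeze:
        t = t[:, None]
    n = t.shape[0]
    mask = np.zeros(t.shape, dtype=bool)
    if n < rules.run_days:
        warnings.warn("series shorter than run_days; season never starts")
        return mask[:, 0] if squeeze else mask

    active = np.zeros(t.shape[1:], dtype=bool)
    warm_run = np.zeros(t.shape[1:], dtype=int)
    cold_run = np.zeros(t.shape[1:], dtype=int)
    for i in range(n):
        mask[i] = active
        warm_run = np.where(t[i] > rules.start_temp_c, warm_run + 1, 0)
        cold_run = np.where(t[i] < rules.stop_temp_c, cold_run + 1, 0)
        start = ~active & (warm_run >= rules.run_days)
        stop = active & (cold_run >= rules.run_days)
        active = (active | start) & ~stop
    return mask[:, 0] if squeeze else mask


def overwinter_dc(
    fall_dc, winter_precip_mm, params: OverwinterParams = OverwinterParams()
):
    """Spring startup Drought Code from the fall value and overwinter rain.

    Moisture-equivalent carryover: Q_spring = a·Q_fall + b·(3.94·r_w),
    DC = 400·ln(800/Q), clamped to ≥ 0.
    """
    fall_dc = np.asarray(fall_dc, dtype=float)
    rw = np.asarray(winter_precip_mm, dtype=float)
    if np.any(fall_dc < 0) or np.any(rw < 0):
        raise ValueError("fall_dc and winter precipitation must be >= 0")
    q_fall = 800.0 * np.exp(-fall_dc / 400.0)
    q_spring = params.a * q_fall + params.b * 3.94 * rw
    return np.maximum(400.0 * np.log(800.0 / np.maximum(q_spring, 1e-12)), 0.0)


# ---------------------------------------------------------------------------
# grid engine
# ---------------------------------------------------------------------------

_REQUIRED_VARS = ("temp", "rh", "wind", "precip")


def run_fwi_grid(
    weather: xr.Dataset,
    rules: SeasonRules = SeasonRules(),
    overwinter: OverwinterParams = OverwinterParams(),
    startup_codes: CodeState = DEFAULT_STARTUP,
) -> xr.Dataset:
    """Run the full system over a gridded daily weather dataset.

    ``weather`` must carry ``temp`` (noon °C), ``rh`` (%), ``wind``
    (km/h) and ``precip`` (24-h mm) on dims ``(time, lat, lon)``; an
    optional ``tmax`` drives the season rules (defaults to ``temp``).
    Per-cell trajectories are independent; outside the fire season the
    codes are held, the indices are missing (NaN), precipitation is
    accumulated for Drought Code overwintering, and at each startup after
    a previous shutdown the spring DC comes from :func:`overwinter_dc`.
    """
    for var in _REQUIRED_VARS:
        if var not in weather:
            raise KeyError(f"weather dataset is missing required variable '{var}'")

    temp = weather["temp"].transpose("time", "lat", "lon").values.astype(float)
    rh = weather["rh"].transpose("time", "lat", "lon").values.astype(float)
    wind = weather["wind"].transpose("time", "lat", "lon").values.astype(float)
    precip = weather["precip"].transpose("time", "lat", "lon").values.astype(float)
    tmax = (
        weather["tmax"].transpose("time", "lat", "lon").values.astype(float)
        if "tmax" in weather
        else temp
    )
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("rh out of [0, 100]")
    if np.any(wind < 0) or np.any(precip < 0):
        raise ValueError("negative wind or precipitation")

    times = pd.DatetimeIndex(weather["time"].values)
    months = times.month.values
    nt, nlat, nlon = temp.shape
    shape = (nlat, nlon)

    active = season_mask(tmax, rules)

    ffmc = np.full((nt,) + shape, np.nan)
    dmc = np.full((nt,) + shape, np.nan)
    dc = np.full((nt,) + shape, np.nan)
    isi = np.full((nt,) + shape, np.nan)
    bui = np.full((nt,) + shape, np.nan)
    fwi = np.full((nt,) + shape, np.nan)

    cur_ffmc = np.full(shape, startup_codes.ffmc)
    cur_dmc = np.full(shape, startup_codes.dmc)
    cur_dc = np.full(shape, startup_codes.dc)
    ever_active = np.zeros(shape, dtype=bool)
    fall_dc = np.full(shape, np.nan)
    winter_rain = np.zeros(shape)

    prev_active = np.zeros(shape, dtype=bool)
    for i in range(nt):
        act = active[i]
        starting = act & ~prev_active
        stopping = prev_active & ~act

        if np.any(stopping):
            fall_dc[stopping] = cur_dc[stopping]
            winter_rain[stopping] = 0.0

        if np.any(starting):
            cur_ffmc[starting] = startup_codes.ffmc
            cur_dmc[starting] = startup_codes.dmc
            restart = starting & ever_active & ~np.isnan(fall_dc)
            fresh = starting & ~restart
            cur_dc[fresh] = startup_codes.dc
            if np.any(restart):
                cur_dc[restart] = overwinter_dc(
                    fall_dc[restart], winter_rain[restart], overwinter
                )
            ever_active |= starting

        off = ~act
        winter_rain[off] += precip[i][off]

        if np.any(act):
            nf = ffmc_update(cur_ffmc, temp[i], rh[i], wind[i], precip[i])
            nd = dmc_update(cur_dmc, temp[i], rh[i], precip[i], months[i])
            nc = dc_update(cur_dc, temp[i], precip[i], months[i])
            cur_ffmc = np.where(act, nf, cur_ffmc)
            cur_dmc = np.where(act, nd, cur_dmc)
            cur_dc = np.where(act, nc, cur_dc)

            day_isi = initial_spread_index(cur_ffmc, wind[i])
            day_bui = buildup_index(cur_dmc, cur_dc)
            day_fwi = fire_weather_index(day_isi, day_bui)
            ffmc[i] = np.where(act, cur_ffmc, np.nan)
            dmc[i] = np.where(act, cur_dmc, np.nan)
            dc[i] = np.where(act, cur_dc, np.nan)
            isi[i] = np.where(act, day_isi, np.nan)
            bui[i] = np.where(act, day_bui, np.nan)
            fwi[i] = np.where(act, day_fwi, np.nan)

        prev_active = act

    coords = {"time": weather["time"], "lat": weather["lat"], "lon": weather["lon"]}
    dims = ("time", "lat", "lon")
    return xr.Dataset(
        {
            "ffmc": (dims, ffmc),
            "dmc": (dims, dmc),
            "dc": (dims, dc),
            "isi": (dims, isi),
            "bui": (dims, bui),
            "fwi": (dims, fwi),
            "season_active": (dims, active),
        },
        coords=coords,
        attrs={
            "start_temp_c": rules.start_temp_c,
            "stop_temp_c": rules.stop_temp_c,
            "run_days": rules.run_days,
            "overwinter_a": overwinter.a,
            "overwinter_b": overwinter.b,
        },
    )
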