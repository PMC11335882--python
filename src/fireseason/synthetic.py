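"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the shapes and statistical character of the real
inputs — reanalysis-style daily surface weather and 500-hPa heights on a
regular lat/lon grid, binary snow-cover series, root-zone soil-moisture
series, growing fires with hotspot sampling and reference perimeters —
while recording every implant (heat episodes, height ridges, melt days,
drying ramps, true day-of-burn fields and areas) in a truth bundle that
recovery tests read back.

Weather is a seasonal cycle plus AR(1) Gaussian anomalies, with
precipitation as thinned gamma events: deliberately simple, but
sufficient for percentile climatologies and index property tests.  Fire
growth is day-indexed expanding ellipses, which guarantees a monotone
day-of-burn field to serve as kriging truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from .burn_dates import PIXEL_M, BurnDateGrid
from .geometry import albers_lonlat, solar_noon_offset_hours

__all__ = [
    "GridSpec",
    "WeatherParams",
    "HeatEpisode",
    "RidgeImplant",
    "SnowDroughtParams",
    "FireSpec",
    "FireScenarioParams",
    "TruthBundle",
    "gen_weather",
    "gen_heights",
    "gen_snow_rzsm",
    "gen_fires",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon mesh (cell centres)."""

    nlat: int = 20
    nlon: int = 20
    lat0: float = 52.0
    lon0: float = -118.0
    dlat: float = 0.5
    dlon: float = 0.5

    @property
    def lat(self) -> np.ndarray:
        return self.lat0 + np.arange(self.nlat) * self.dlat

    @property
    def lon(self) -> np.ndarray:
        return self.lon0 + np.arange(self.nlon) * self.dlon


@dataclass(frozen=True)
class HeatEpisode:
    """Implanted hot/dry spell over a cell box and date window."""

    year: int
    start_doy: int
    days: int
    temp_boost: float = 8.0
    lat_slice: tuple[int, int] = (0, 20)
    lon_slice: tuple[int, int] = (0, 20)


@dataclass(frozen=True)
class WeatherParams:
    """Seasonal-cycle + AR(1) daily weather process.

    Annual-mean temperature 5 °C with an 18 °C seasonal amplitude gives
    boreal-like winters near −13 °C and summers near 23 °C; daily maxima
    run 5 °C above the noon value, which drives season startup near
    mid-May under the 12 °C/3-day rule.  Precipitation occurs on ~30% of
    days with gamma-distributed amounts (mean ≈ 4 mm).
    """

    temp_mean_c: float = 5.0
    temp_amplitude_c: float = 18.0
    temp_ar1: float = 0.7
    temp_sd_c: float = 3.0
    tmax_offset_c: float = 5.0
    rh_base_pct: float = 70.0
    rh_temp_slope: float = 1.5  # % RH drop per °C of warm anomaly
    rh_sd_pct: float = 8.0
    wind_shape: float = 2.0
    wind_scale_kmh: float = 6.0
    wet_day_prob: float = 0.30
    precip_shape: float = 0.8
    precip_scale_mm: float = 5.0


@dataclass(frozen=True)
class RidgeImplant:
    """Implanted persistent positive height anomaly (blocking proxy)."""

    start_date: str  # e.g. "2023-06-01"
    days: int
    lat_slice: tuple[int, int]
    lon_slice: tuple[int, int]
    amplitude_sd: float = 2.5


@dataclass(frozen=True)
class SnowDroughtParams:
    melt_day_base: int = 115
    melt_day_spread: int = 20  # per-cell uniform offset half-width
    target_year_shift: int = -12  # target-year melt earlier by this many days
    snow_return_doy: int = 315
    rzsm_base: float = 400.0  # kg m⁻²
    rzsm_wetting_per_day: float = 0.02
    ramp_amount: float = 25.0  # kg m⁻² drop over the ramp
    ramp_window: int = 14


@dataclass(frozen=True)
class FireSpec:
    fire_id: str
    x: float  # ignition, Albers metres
    y: float
    start_date: str
    n_days: int
    final_area_ha: float
    aspect: float = 1.6  # ellipse axis ratio
    theta: float = 0.0  # orientation (radians)
    cause: str = "lightning"
    response: str = "full"
    mapped: bool = True  # has a reference (mapped) perimeter


@dataclass(frozen=True)
class FireScenarioParams:
    hotspot_density_ha: float = 50.0  # one hotspot per this many hectares
    detection_jitter_h: float = 3.0
    n_false_preseason: int = 12
    n_ecozones: int = 2
    ecozone_split_x: float = 0.0  # vertical split between ecozones
    island_fraction: float = 0.06  # unburned-island share of ellipse area
    n_slivers: int = 4  # sub-1-ha artifact polygons added to reference set


@dataclass
class TruthBundle:
    """Ground truth recorded by the generators."""

    melt_days: dict = field(default_factory=dict)  # year -> (nlat, nlon) array
    ramp_start_doy: np.ndarray | None = None
    ramp_amount: np.ndarray | None = None
    ridge_events: list = field(default_factory=list)  # RidgeImplant list
    blocking_day_counts: np.ndarray | None = None
    fire_true_area_ha: dict = field(default_factory=dict)
    fire_day_grids: dict = field(default_factory=dict)  # fire_id -> BurnDateGrid
    total_true_area_ha: float = 0.0


def _dates(year0: int, year1: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{year0}-01-01", f"{year1}-12-31", freq="D")


def _seasonal_temp(doy: np.ndarray, params: WeatherParams) -> np.ndarray:
    return params.temp_mean_c + params.temp_amplitude_c * np.cos(
        2.0 * np.pi * (doy - 200) / 365.25
    )


def _ar1(rng, n, ncell, rho, sd):
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    e = np.empty((n, ncell))
    e[0] = rng.normal(0.0, sd, ncell)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + rng.normal(0.0, innov_sd, ncell)
    return e


def gen_weather(
    grid: GridSpec,
    year0: int,
    year1: int,
    params: WeatherParams = WeatherParams(),
    episodes: tuple[HeatEpisode, ...] = (),
    seed: int = 0,
) -> xr.Dataset:
    """Daily surface weather grids (noon temp, tmax, RH, wind, precip).

    Identical seeds give bit-identical output.  Implanted heat episodes
    raise temperature by their boost, cut RH by 20 points and zero the
    precipitation over their cell boxes and date windows.
    """
    rng = np.random.default_rng(seed)
    times = _dates(year0, year1)
    doy = times.dayofyear.to_numpy()
    n = len(times)
    ncell = grid.nlat * grid.nlon

    clim = _seasonal_temp(doy, params)[:, None]
    anom = _ar1(rng, n, ncell, params.temp_ar1, params.temp_sd_c)
    temp = clim + anom
    tmax = temp + params.tmax_offset_c

    rh = (
        params.rh_base_pct
        - params.rh_temp_slope * anom
        + rng.normal(0.0, params.rh_sd_pct, (n, ncell))
    )
    wind = rng.gamma(params.wind_shape, params.wind_scale_kmh, (n, ncell))
    wet = rng.random((n, ncell)) < params.wet_day_prob
    precip = np.where(
        wet, rng.gamma(params.precip_shape, params.precip_scale_mm, (n, ncell)), 0.0
    )

    years = times.year.to_numpy()
    for ep in episodes:
        sel = (years == ep.year) & (doy >= ep.start_doy) & (doy < ep.start_doy + ep.days)
        cells = np.zeros((grid.nlat, grid.nlon), dtype=bool)
        cells[slice(*ep.lat_slice), slice(*ep.lon_slice)] = True
        cells = cells.ravel()
        box = np.outer(sel, cells)
        temp[box] += ep.temp_boost
        tmax[box] += ep.temp_boost
        rh[box] -= 20.0
        precip[box] = 0.0

    rh = np.clip(rh, 5.0, 100.0)
    shape = (n, grid.nlat, grid.nlon)
    coords = {"time": times, "lat": grid.lat, "lon": grid.lon}
    dims = ("time", "lat", "lon")
    return xr.Dataset(
        {
            "temp": (dims, temp.reshape(shape)),
            "tmax": (dims, tmax.reshape(shape)),
            "rh": (dims, rh.reshape(shape)),
            "wind": (dims, wind.reshape(shape)),
            "precip": (dims, precip.reshape(shape)),
        },
        coords=coords,
    )


def gen_heights(
    grid: GridSpec,
    year0: int,
    year1: int,
    ridges: tuple[RidgeImplant, ...] = (),
    eval_year: int | None = None,
    mean_m: float = 5600.0,
    sd_m: float = 60.0,
    ar1: float = 0.8,
    eval_damp: float = 0.2,
    eval_clip_sd: float = 0.6,
    seed: int = 0,
) -> tuple[xr.DataArray, TruthBundle]:
    """Daily 500-hPa height grids with implanted persistent ridges.

    Baseline years carry full AR(1) variability so the climatological SD
    is realistic.  In ``eval_year`` the background anomalies are damped
    and clipped well below one SD, so the only above-threshold anomalies
    are the implanted ridges — making event recovery exact.  The truth
    bundle records the implants and per-cell blocking-day counts of the
    qualifying implants (≥ 5 days persistence is judged by the caller's
    detection config; truth counts cover *all* implanted days per ridge).
    """
    rng = np.random.default_rng(seed)
    times = _dates(year0, year1)
    n = len(times)
    ncell = grid.nlat * grid.nlon

    e = _ar1(rng, n, ncell, ar1, 1.0)
    if eval_year is not None:
        in_eval = times.year == eval_year
        e[in_eval] = np.clip(eval_damp * e[in_eval], -eval_clip_sd, eval_clip_sd)
    heights = mean_m + sd_m * e

    truth = TruthBundle()
    for ridge in ridges:
        start = pd.Timestamp(ridge.start_date)
        sel = (times >= start) & (times < start + pd.Timedelta(days=ridge.days))
        cells = np.zeros((grid.nlat, grid.nlon), dtype=bool)
        cells[slice(*ridge.lat_slice), slice(*ridge.lon_slice)] = True
        box = np.outer(np.asarray(sel), cells.ravel())
        heights[box] += ridge.amplitude_sd * sd_m
        truth.ridge_events.append(ridge)

    da = xr.DataArray(
        heights.reshape(n, grid.nlat, grid.nlon),
        coords={"time": times, "lat": grid.lat, "lon": grid.lon},
        dims=("time", "lat", "lon"),
        name="z500",
    )
    return da, truth


def gen_snow_rzsm(
    grid: GridSpec,
    baseline_years: tuple[int, int],
    target_year: int,
    params: SnowDroughtParams = SnowDroughtParams(),
    ramp_cells: tuple[tuple[int, int], ...] | None = None,
    seed: int = 0,
) -> tuple[dict[int, np.ndarray], xr.DataArray, TruthBundle]:
    """Binary snow series and root-zone soil-moisture series with truth.

    Returns ``(snow, rzsm, truth)`` where ``snow[year]`` is a boolean
    array (day-of-year, lat, lon) of snow cover, and ``rzsm`` is a daily
    soil-moisture DataArray for the target year.  Each cell's melt day
    varies between years around the cell's base value; the target year
    melts earlier by ``target_year_shift`` days.  The soil-moisture
    series is flat-plus-slow-wetting with one implanted linear drying
    ramp per cell (a 14-day drop of ``ramp_amount``), so the implanted
    ramp is the unique maximal drying window.
    """
    rng = np.random.default_rng(seed)
    cell_base = params.melt_day_base + rng.integers(
        -params.melt_day_spread, params.melt_day_spread + 1, (grid.nlat, grid.nlon)
    )
    truth = TruthBundle()

    snow: dict[int, np.ndarray] = {}
    all_years = list(range(baseline_years[0], baseline_years[1] + 1)) + [target_year]
    for year in all_years:
        ndays = 366 if pd.Timestamp(f"{year}-12-31").dayofyear == 366 else 365
        if year == target_year:
            melt = cell_base + params.target_year_shift
        else:
            melt = cell_base + rng.integers(-5, 6, (grid.nlat, grid.nlon))
        doys = np.arange(1, ndays + 1)[:, None, None]
        covered = (doys < melt[None]) | (doys >= params.snow_return_doy)
        snow[year] = covered
        truth.melt_days[year] = melt.copy()

    # target-year soil moisture with one drying ramp per cell
    ndays = 366 if pd.Timestamp(f"{target_year}-12-31").dayofyear == 366 else 365
    times = pd.date_range(f"{target_year}-01-01", periods=ndays, freq="D")
    base = params.rzsm_base + params.rzsm_wetting_per_day * np.arange(ndays)
    rzsm = np.repeat(base[:, None], grid.nlat * grid.nlon, axis=1).reshape(
        ndays, grid.nlat, grid.nlon
    )
    may1 = int(pd.Timestamp(f"{target_year}-05-01").dayofyear) - 1
    jun30 = int(pd.Timestamp(f"{target_year}-06-30").dayofyear) - 1
    ramp_start = np.zeros((grid.nlat, grid.nlon), dtype=int)
    ramp_amount = np.full((grid.nlat, grid.nlon), params.ramp_amount)
    latest = jun30 - params.ramp_window + 1
    starts = rng.integers(may1, latest + 1, (grid.nlat, grid.nlon))
    w = params.ramp_window
    wet = params.rzsm_wetting_per_day
    for i in range(grid.nlat):
        for j in range(grid.nlon):
            s = int(starts[i, j])
            amt = params.ramp_amount
            v = rzsm[:, i, j]
            # strict linear decline of `amt` from day s to day s+w-1, then
            # resume the slow wetting from the lowered level: the window
            # starting at s is the unique maximal 14-day drop
            v[s : s + w] = v[s] - amt * np.arange(w) / (w - 1)
            v[s + w :] = v[s + w - 1] + wet * np.arange(1, ndays - (s + w) + 1)
            ramp_start[i, j] = s
    truth.ramp_start_doy = ramp_start
    truth.ramp_amount = ramp_amount

    rzsm_da = xr.DataArray(
        rzsm,
        coords={"time": times, "lat": grid.lat, "lon": grid.lon},
        dims=("time", "lat", "lon"),
        name="rzsm",
    )
    return snow, rzsm_da, truth


# ---------------------------------------------------------------------------
# fires
# ---------------------------------------------------------------------------

def _ellipse(cx, cy, a, b, theta, n=96) -> Polygon:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ex = a * np.cos(t)
    ey = b * np.sin(t)
    x = cx + ex * np.cos(theta) - ey * np.sin(theta)
    y = cy + ex * np.sin(theta) + ey * np.cos(theta)
    return Polygon(np.column_stack([x, y]))


def _fire_day_grid(spec: FireSpec, start_ord: int) -> BurnDateGrid:
    """True day-of-burn raster: first day each pixel centre is inside."""
    final_area_m2 = spec.final_area_ha * 1e4
    b_final = np.sqrt(final_area_m2 / (np.pi * spec.aspect))
    a_final = spec.aspect * b_final
    final = _ellipse(spec.x, spec.y, a_final, b_final, spec.theta)

    from .burn_dates import _grid_for_perimeter

    ix0, iy0, gx, gy, _ = _grid_for_perimeter(final)
    day = np.full(gx.shape, -1, dtype=int)
    for t in range(1, spec.n_days + 1):
        frac = t / spec.n_days
        ell = _ellipse(
            spec.x, spec.y, a_final * np.sqrt(frac), b_final * np.sqrt(frac), spec.theta
        )
        inside = shapely.contains_xy(ell, gx.ravel(), gy.ravel()).reshape(gx.shape)
        newly = inside & (day < 0)
        day[newly] = start_ord + t - 1
    return BurnDateGrid(fire_id=spec.fire_id, ix0=ix0, iy0=iy0, day=day)


def gen_fires(
    specs: tuple[FireSpec, ...],
    params: FireScenarioParams = FireScenarioParams(),
    water: list[Polygon] | None = None,
    seed: int = 0,
) -> dict:
    """Grow elliptical fires; sample hotspots; build reference perimeters.

    Returns a dict with:

    ``hotspots``
        DataFrame (lon, lat, x, y, acq_datetime UTC, sensor, fire_id),
        including ``n_false_preseason`` pre-April false detections.
    ``reference``
        DataFrame of mapped perimeters (truth ellipse minus water and
        unburned islands) for fires with ``mapped=True``, plus sub-1-ha
        sliver artifacts; columns fire_id, ecozone, geometry, area_ha.
    ``records``
        Fire-record table (fire_id, size_ha, start/out dates, cause,
        response, lon, lat, ecozone).
    ``truth``
        TruthBundle with per-fire true burned areas (net of water and
        islands), true day-of-burn grids, and the true national total.
    ``water``
        The water-body union used.
    """
    rng = np.random.default_rng(seed)
    truth = TruthBundle()
    water_union = unary_union(water) if water else Polygon()

    hotspot_rows = []
    ref_rows = []
    record_rows = []
    xs_all, ys_all = [], []

    for spec in specs:
        start = pd.Timestamp(spec.start_date)
        start_ord = start.toordinal()
        grid = _fire_day_grid(spec, start_ord)
        truth.fire_day_grids[spec.fire_id] = grid

        final_area_m2 = spec.final_area_ha * 1e4
        b_final = np.sqrt(final_area_m2 / (np.pi * spec.aspect))
        a_final = spec.aspect * b_final
        footprint = _ellipse(spec.x, spec.y, a_final, b_final, spec.theta)

        # unburned islands: a few small discs inside the ellipse
        islands = []
        island_target = params.island_fraction * footprint.area
        while sum(g.area for g in islands) < island_target:
            rr = 0.12 * b_final * (0.5 + rng.random())
            ang = rng.random() * 2 * np.pi
            rad = 0.7 * rng.random()
            ix = spec.x + rad * a_final * np.cos(ang)
            iy = spec.y + rad * b_final * np.sin(ang)
            islands.append(Point(ix, iy).buffer(rr, quad_segs=16))
        holes = unary_union(islands + ([water_union] if not water_union.is_empty else []))
        burned = footprint.difference(holes)
        true_area_ha = burned.area / 1e4
        truth.fire_true_area_ha[spec.fire_id] = true_area_ha

        # hotspots sampled from truly burned pixels of each day's band
        lon_c, lat_c = albers_lonlat(spec.x, spec.y)
        offset = int(solar_noon_offset_hours(lon_c))
        ii, jj = np.nonzero(grid.day >= 0)
        px = (grid.ix0 + jj + 0.5) * PIXEL_M
        py = (grid.iy0 + ii + 0.5) * PIXEL_M
        pixel_burned = shapely.contains_xy(burned, px, py)
        days = grid.day[ii, jj]
        for t in range(spec.n_days):
            d = start_ord + t
            sel = np.flatnonzero((days == d) & pixel_burned)
            if sel.size == 0:
                continue
            band_ha = sel.size * grid.pixel_area_ha
            n_pts = max(1, int(np.ceil(band_ha / params.hotspot_density_ha)))
            pick = rng.choice(sel, size=min(n_pts, sel.size), replace=False)
            for p in pick:
                hx = px[p] + rng.uniform(-0.4, 0.4) * PIXEL_M
                hy = py[p] + rng.uniform(-0.4, 0.4) * PIXEL_M
                if not footprint.contains(Point(hx, hy)):
                    hx, hy = px[p], py[p]  # keep edge detections inside
                lon, lat = albers_lonlat(hx, hy)
                local = pd.Timestamp.fromordinal(d) + pd.Timedelta(
                    hours=13.5 + rng.normal(0.0, params.detection_jitter_h / 3.0)
                )
                hotspot_rows.append(
                    {
                        "lon": float(lon),
                        "lat": float(lat),
                        "x": hx,
                        "y": hy,
                        "acq_datetime": local - pd.Timedelta(hours=offset),
                        "sensor": "VIIRS-375",
                        "fire_id": spec.fire_id,
                    }
                )
        xs_all.append(spec.x)
        ys_all.append(spec.y)

        ecozone = 0 if spec.x < params.ecozone_split_x else 1
        if spec.mapped:
            for part in getattr(burned, "geoms", [burned]):
                ref_rows.append(
                    {
                        "fire_id": spec.fire_id,
                        "ecozone": ecozone,
                        "geometry": part,
                        "area_ha": part.area / 1e4,
                    }
                )
        record_rows.append(
            {
                "fire_id": spec.fire_id,
                "size_ha": true_area_ha,
                "start_date": start,
                "out_date": start + pd.Timedelta(days=spec.n_days - 1),
                "cause": spec.cause,
                "response": spec.response,
                "lon": float(lon_c),
                "lat": float(lat_c),
                "ecozone": ecozone,
            }
        )

    # sub-1-ha sliver artifacts appended to the reference set
    for k in range(params.n_slivers):
        sx = float(np.mean(xs_all)) + rng.uniform(-5e4, 5e4)
        sy = float(np.mean(ys_all)) + rng.uniform(-5e4, 5e4)
        sliver = Point(sx, sy).buffer(np.sqrt(0.5e4 / np.pi), quad_segs=8)  # 0.5 ha
        ref_rows.append(
            {
                "fire_id": f"sliver_{k}",
                "ecozone": 0 if sx < params.ecozone_split_x else 1,
                "geometry": sliver,
                "area_ha": sliver.area / 1e4,
            }
        )

    # pre-season false detections (local dates in March)
    year = pd.Timestamp(specs[0].start_date).year
    for k in range(params.n_false_preseason):
        fx = float(np.mean(xs_all)) + rng.uniform(-2e5, 2e5)
        fy = float(np.mean(ys_all)) + rng.uniform(-2e5, 2e5)
        lon, lat = albers_lonlat(fx, fy)
        offset = int(solar_noon_offset_hours(lon))
        local = pd.Timestamp(f"{year}-03-01") + pd.Timedelta(
            days=int(rng.integers(0, 25)), hours=13
        )
        hotspot_rows.append(
            {
                "lon": float(lon),
                "lat": float(lat),
                "x": fx,
                "y": fy,
                "acq_datetime": local - pd.Timedelta(hours=offset),
                "sensor": "VIIRS-375",
                "fire_id": f"false_{k}",
            }
        )

    truth.total_true_area_ha = float(sum(truth.fire_true_area_ha.values()))
    return {
        "hotspots": pd.DataFrame(hotspot_rows),
        "reference": pd.DataFrame(ref_rows),
        "records": pd.DataFrame(record_rows),
        "truth": truth,
        "water": water_union,
    }
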