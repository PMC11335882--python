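"""Baseline climatologies and extreme-fire-weather statistics.

The central quantity is the per-cell 95th percentile of in-season FWI
over a baseline period (FWI95).  A day is an *extreme fire weather day*
at a cell when its FWI exceeds the cell's FWI95; aggregating the cell
areas where this happens over a forested mask gives the daily extent of
extreme fire weather, whose rank correlation with daily area burned is
the headline association this module computes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

__all__ = [
    "PercentileField",
    "ForestMask",
    "vpd_from_t_td",
    "percentile_field",
    "extent_series",
    "extreme_day_counts",
    "standardized_anomaly",
    "season_anomaly_rank",
    "correlate_extent_burn",
]

# improved-Magnus saturation vapor pressure constants (over water)
_MAGNUS_A = 6.1094  # hPa
_MAGNUS_B = 17.625
_MAGNUS_C = 243.04  # °C


@dataclass
class PercentileField:
    """Per-cell baseline FWI quantile with contribution counts."""

    q95: xr.DataArray
    baseline_years: tuple[int, int]
    n_days: xr.DataArray
    q: float = 0.95


@dataclass
class ForestMask:
    """Boolean forest mask thresholded from fractional canopy cover."""

    mask: xr.DataArray
    threshold: float = 0.20
    source: str = "canopy_cover"

    @classmethod
    def from_canopy_cover(
        cls, canopy: xr.DataArray, threshold: float = 0.20, source: str = "canopy_cover"
    ) -> "ForestMask":
        return cls(mask=canopy > threshold, threshold=threshold, source=source)


def saturation_vapor_pressure_hpa(temp_c):
    """Improved-Magnus saturation vapour pressure over water (hPa)."""
    t = np.asarray(temp_c, dtype=float)
    return _MAGNUS_A * np.exp(_MAGNUS_B * t / (_MAGNUS_C + t))


def vpd_from_t_td(temp_c, dewpoint_c):
    """Vapour pressure deficit (hPa) from temperature and dewpoint.

    Dewpoints above the temperature (supersaturation artefacts) are
    clamped to the temperature, yielding VPD = 0 there.
    """
    t = np.asarray(temp_c, dtype=float)
    td = np.asarray(dewpoint_c, dtype=float)
    if np.any(td > t):
        warnings.warn("dewpoint above temperature clamped (VPD set to 0)")
        td = np.minimum(td, t)
    return saturation_vapor_pressure_hpa(t) - saturation_vapor_pressure_hpa(td)


def percentile_field(
    fwi_fields: xr.Dataset,
    baseline_years: tuple[int, int] = (1991, 2020),
    q: float = 0.95,
    var: str = "fwi",
    min_days: int = 100,
) -> PercentileField:
    """Per-cell baseline quantile of in-season index values.

    Off-season days (``season_active`` false, or NaN index) are omitted.
    Quantiles use linear interpolation between order statistics.  Cells
    with fewer than ``min_days`` contributing in-season days are masked.
    """
    years = pd.DatetimeIndex(fwi_fields["time"].values).year
    sel = (years >= baseline_years[0]) & (years <= baseline_years[1])
    if not sel.any():
        raise ValueError(f"no data within baseline years {baseline_years}")
    sub = fwi_fields.isel(time=np.flatnonzero(sel))
    values = sub[var].where(sub["season_active"])
    n_days = values.notnull().sum("time")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        q95 = values.quantile(q, dim="time", method="linear").drop_vars("quantile")
    q95 = q95.where(n_days >= min_days)
    return PercentileField(q95=q95, baseline_years=baseline_years, n_days=n_days, q=q)


def _check_aligned(a: xr.DataArray, b: xr.DataArray) -> None:
    if not (
        np.array_equal(a["lat"].values, b["lat"].values)
        and np.array_equal(a["lon"].values, b["lon"].values)
    ):
        raise ValueError("grids are not aligned on lat/lon")


def extent_series(
    fwi_fields: xr.Dataset,
    q: PercentileField,
    forest: ForestMask,
    region_labels: xr.DataArray,
    cell_areas_km2: np.ndarray,
    region_names: dict[int, str] | None = None,
    var: str = "fwi",
) -> pd.DataFrame:
    """Daily forested area (ha) with FWI above FWI95, per region.

    ``region_labels`` is an integer grid (−1 = outside all regions).
    The proportion divides by the region's total forested area, so it is
    invariant to a uniform rescaling of the cell areas' units.
    """
    _check_aligned(fwi_fields[var], q.q95)
    _check_aligned(fwi_fields[var], forest.mask)
    _check_aligned(fwi_fields[var], region_labels)

    areas_ha = np.asarray(cell_areas_km2, dtype=float) * 100.0
    labels = region_labels.values.astype(int)
    fmask = forest.mask.values.astype(bool)
    q95 = q.q95.values
    valid_region = labels >= 0
    nreg = labels.max() + 1 if valid_region.any() else 0

    forest_area = np.bincount(
        labels[valid_region & fmask],
        weights=areas_ha[valid_region & fmask],
        minlength=nreg,
    )

    exceed = (
        fwi_fields[var].values > q95[None, :, :]
    ) & fwi_fields["season_active"].values & fmask[None, :, :] & valid_region[None, :, :]

    rows = []
    times = pd.DatetimeIndex(fwi_fields["time"].values)
    names = region_names or {i: str(i) for i in range(nreg)}
    for i, t in enumerate(times):
        day = exceed[i]
        area = np.bincount(labels[day], weights=areas_ha[day], minlength=nreg)
        for r in range(nreg):
            if forest_area[r] <= 0:
                continue
            rows.append(
                {
                    "date": t,
                    "region": names.get(r, str(r)),
                    "area_ha": area[r],
                    "proportion": area[r] / forest_area[r],
                }
            )
    return pd.DataFrame(rows)


def extreme_day_counts(
    fwi_fields: xr.Dataset,
    q: PercentileField,
    year: int,
    var: str = "fwi",
) -> xr.Dataset:
    """Per-cell count of extreme days in ``year`` and anomaly vs baseline.

    The anomaly subtracts the baseline-mean yearly count of exceedances.
    """
    years = pd.DatetimeIndex(fwi_fields["time"].values).year
    exceed = (fwi_fields[var] > q.q95) & fwi_fields["season_active"]

    def yearly_count(y):
        idx = np.flatnonzero(years == y)
        if idx.size == 0:
            raise ValueError(f"year {y} absent from input")
        return exceed.isel(time=idx).sum("time")

    count = yearly_count(year)
    y0, y1 = q.baseline_years
    base_years = [y for y in range(y0, y1 + 1) if (years == y).any()]
    baseline_mean = xr.concat(
        [yearly_count(y) for y in base_years], dim="year"
    ).mean("year")
    return xr.Dataset(
        {"count": count, "anomaly": count - baseline_mean, "baseline_mean": baseline_mean}
    )


def standardized_anomaly(values: xr.DataArray, baseline: xr.DataArray, dim: str = "time"):
    """z-score of ``values`` against the baseline mean and SD along ``dim``.

    Cells whose baseline SD is zero are masked (NaN) with a warning.
    """
    mean = baseline.mean(dim)
    sd = baseline.std(dim, ddof=1)
    if (sd == 0).any():
        warnings.warn("zero baseline SD: cells masked in standardized anomaly")
    return (values - mean) / sd.where(sd > 0)


def season_anomaly_rank(
    field: xr.DataArray,
    target_year: int,
    baseline_years: tuple[int, int] = (1991, 2020),
    eval_years: tuple[int, int] | None = None,
    season_months: tuple[int, int] = (5, 10),
    rank_direction: str = "high",
) -> xr.Dataset:
    """Seasonal-mean anomaly of a target year and its rank among all years.

    The seasonal mean is taken over ``season_months`` (inclusive, default
    May–October).  ``rank_direction='high'`` makes rank 1 the largest
    seasonal mean (temperature, VPD); ``'low'`` makes rank 1 the smallest
    (precipitation: most extreme = driest).
    """
    if rank_direction not in ("high", "low"):
        raise ValueError("rank_direction must be 'high' or 'low'")
    times = pd.DatetimeIndex(field["time"].values)
    in_season = (times.month >= season_months[0]) & (times.month <= season_months[1])
    seasonal = field.isel(time=np.flatnonzero(in_season))
    syears = pd.DatetimeIndex(seasonal["time"].values).year

    eval_years = eval_years or (int(syears.min()), int(syears.max()))
    wanted = list(range(eval_years[0], eval_years[1] + 1))
    missing = [y for y in wanted if not (syears == y).any()]
    if missing:
        raise ValueError(f"missing years in evaluation period: {missing}")

    per_year = xr.concat(
        [seasonal.isel(time=np.flatnonzero(syears == y)).mean("time") for y in wanted],
        dim=pd.Index(wanted, name="year"),
    )
    baseline = per_year.sel(year=slice(baseline_years[0], baseline_years[1]))
    anomaly = per_year.sel(year=target_year) - baseline.mean("year")

    vals = per_year.values  # (year, lat, lon)
    order = np.argsort(-vals if rank_direction == "high" else vals, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, vals.shape[0] + 1)[:, None, None], axis=0)
    target_rank = ranks[wanted.index(target_year)]
    rank_da = xr.DataArray(
        target_rank, coords=anomaly.coords, dims=anomaly.dims, name="rank"
    )
    return xr.Dataset({"anomaly": anomaly, "rank": rank_da})


def correlate_extent_burn(
    extent: pd.DataFrame, burn: pd.DataFrame, min_days: int = 3
) -> pd.DataFrame:
    """Spearman rank correlation of daily extreme-weather extent vs burn.

    Both frames need columns ``date``, ``region`` and a value column
    (``area_ha`` in ``extent``, ``area_burned_ha`` in ``burn``); the
    correlation is computed on dates present in both, per region, with
    ties handled by midranks.  Regions with fewer than ``min_days``
    paired days get a NaN coefficient and ``ok=False``.
    """
    merged = extent.merge(burn, on=["date", "region"], how="inner")
    rows = []
    for region, grp in merged.groupby("region", sort=True):
        n = len(grp)
        if n < min_days:
            rows.append({"region": region, "spearman": np.nan, "n_days": n, "ok": False})
            continue
        rho = stats.spearmanr(grp["area_ha"], grp["area_burned_ha"]).statistic
        rows.append({"region": region, "spearman": float(rho), "n_days": n, "ok": True})
    return pd.DataFrame(rows)
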