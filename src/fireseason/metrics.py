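"""Fire-level summaries: sizes, timing, duration, spread days, smoke.

Size classes follow the operational conventions: fires strictly larger
than 200 ha are "large", strictly larger than 50,000 ha "very large".
Potential spread days of a fire are the days, between its start and out
dates, on which any grid cell overlapping the fire experienced extreme
fire weather (FWI above the local baseline 95th percentile).  Fire size
is related to potential spread days by a power law fitted on log–log
axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SizeThresholds",
    "RegionConfig",
    "size_summary",
    "ignition_month_summary",
    "duration_spread_analysis",
    "fit_power_law",
    "response_cause_summary",
    "pm25_exceedance",
]


@dataclass(frozen=True)
class SizeThresholds:
    large_ha: float = 200.0
    very_large_ha: float = 50_000.0
    growth_subset_ha: float = 1_000.0
    interp_min_ha: float = 500.0
    min_polygon_ha: float = 1.0


@dataclass(frozen=True)
class RegionConfig:
    """West/east split of the domain at a meridian (degrees east)."""

    split_meridian: float = -85.0

    def side(self, lon: float) -> str:
        return "west" if lon < self.split_meridian else "east"


DEFAULT_SIZE_CLASSES = (0.0, 200.0, 1_000.0, 10_000.0, 50_000.0, np.inf)


def size_summary(
    records: pd.DataFrame, class_edges: tuple[float, ...] = DEFAULT_SIZE_CLASSES
) -> pd.DataFrame:
    """Counts and area proportions per fire size class.

    Classes are right-closed intervals (a, b], so a fire of exactly
    200 ha falls in the (0, 200] class and is *not* large — largeness
    requires strictly exceeding the threshold.
    """
    sizes = records["size_ha"]
    cats = pd.cut(sizes, bins=list(class_edges), right=True)
    counts = cats.value_counts(sort=False)
    area = sizes.groupby(cats, observed=False).sum()
    total = sizes.sum()
    return pd.DataFrame(
        {
            "size_class": counts.index.astype(str),
            "count": counts.to_numpy(),
            "area_ha": area.to_numpy(),
            "area_proportion": (area / total).to_numpy() if total > 0 else np.nan,
        }
    )


def ignition_month_summary(records: pd.DataFrame, min_size_ha: float = 1_000.0) -> pd.DataFrame:
    """Per start-month count and area-burned proportions (fires > min size)."""
    sub = records[records["size_ha"] > min_size_ha].copy()
    months = pd.to_datetime(sub["start_date"]).dt.month
    counts = months.value_counts().sort_index()
    area = sub.groupby(months.values)["size_ha"].sum().sort_index()
    return pd.DataFrame(
        {
            "month": counts.index.to_numpy(),
            "count": counts.to_numpy(),
            "count_proportion": counts.to_numpy() / counts.sum(),
            "area_proportion": area.to_numpy() / area.sum(),
        }
    )


def _spread_days_for_fire(start, out, cells, fwi_fields, q95_values) -> int:
    times = pd.DatetimeIndex(fwi_fields["time"].values)
    sel = (times >= start) & (times <= out)
    if not sel.any() or not cells:
        return 0
    fw = fwi_fields["fwi"].values[sel]
    active = fwi_fields["season_active"].values[sel]
    # extreme for the fire = any overlapping cell exceeds its own threshold
    ext = np.zeros(int(sel.sum()), dtype=bool)
    for (i, j) in cells:
        thr = q95_values[i, j]
        if np.isnan(thr):
            continue
        ext |= (np.nan_to_num(fw[:, i, j], nan=-np.inf) > thr) & active[:, i, j]
    return int(ext.sum())


def duration_spread_analysis(
    records: pd.DataFrame,
    fwi_fields,
    q95,
    fire_cells: dict | None = None,
    regions: RegionConfig = RegionConfig(),
    interval: tuple[float, float] = (5.0, 95.0),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Durations, potential spread days, side medians and power-law fit.

    ``fire_cells`` maps fire id → list of (ilat, ilon) grid cells
    overlapping the fire footprint; fires without an entry are mapped to
    the nearest cell of their centroid (with a warning implied by the
    mapping).  Returns ``(per_fire, per_side, power_law)`` where
    ``per_side`` holds the median duration and the 5th–95th percentile
    interval per west/east side, and ``power_law`` the fitted exponent
    of size vs (spread days + 1).
    """
    q95_values = q95.q95.values if hasattr(q95, "q95") else np.asarray(q95)
    lats = fwi_fields["lat"].values
    lons = fwi_fields["lon"].values

    rows = []
    for _, rec in records.iterrows():
        start = pd.Timestamp(rec["start_date"])
        out = pd.Timestamp(rec["out_date"])
        cells = (fire_cells or {}).get(rec["fire_id"])
        if not cells:
            i = int(np.abs(lats - rec["lat"]).argmin())
            j = int(np.abs(lons - rec["lon"]).argmin())
            cells = [(i, j)]
        rows.append(
            {
                "fire_id": rec["fire_id"],
                "size_ha": rec["size_ha"],
                "side": regions.side(rec["lon"]),
                "duration_days": (out - start).days + 1,
                "spread_days": _spread_days_for_fire(
                    start, out, cells, fwi_fields, q95_values
                ),
            }
        )
    per_fire = pd.DataFrame(rows)

    side_rows = []
    for side, grp in per_fire.groupby("side"):
        d = grp["duration_days"].to_numpy()
        side_rows.append(
            {
                "side": side,
                "n_fires": len(grp),
                "median_duration": float(np.median(d)),
                "duration_lo": float(np.percentile(d, interval[0])),
                "duration_hi": float(np.percentile(d, interval[1])),
            }
        )
    per_side = pd.DataFrame(side_rows)

    power_law = fit_power_law(per_fire["size_ha"], per_fire["spread_days"])
    return per_fire, per_side, power_law


def fit_power_law(sizes, spread_days) -> dict:
    """Least-squares fit of log(size) = a + γ·log(spread days + 1).

    Returns the exponent, intercept and the exponent's standard error.
    """
    x = np.log(np.asarray(spread_days, dtype=float) + 1.0)
    y = np.log(np.asarray(sizes, dtype=float))
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or np.ptp(x) == 0:
        return {"exponent": np.nan, "intercept": np.nan, "se": np.nan, "n": n}
    coef, cov = np.polyfit(x, y, 1, cov=True)
    return {
        "exponent": float(coef[0]),
        "intercept": float(coef[1]),
        "se": float(np.sqrt(cov[0, 0])),
        "n": n,
    }


def response_cause_summary(
    records: pd.DataFrame, thresholds: SizeThresholds = SizeThresholds()
) -> dict:
    """Tabulate count/area shares by cause and response, and containment.

    Containment rate per response type = fraction of its fires held
    under the large-fire threshold (strictly below 200 ha).  Unknown
    categories are counted under ``"unknown"``.
    """
    df = records.copy()
    df["cause"] = df["cause"].where(
        df["cause"].isin(["lightning", "human"]), "unknown"
    )
    df["response"] = df["response"].where(
        df["response"].isin(["full", "modified", "monitored"]), "unknown"
    )
    out = {}
    for axis in ("cause", "response"):
        grp = df.groupby(axis)["size_ha"]
        tab = pd.DataFrame(
            {
                "count": grp.count(),
                "count_proportion": grp.count() / len(df),
                "area_ha": grp.sum(),
                "area_proportion": grp.sum() / df["size_ha"].sum(),
            }
        )
        out[axis] = tab
    contained = (
        df.assign(contained=df["size_ha"] < thresholds.large_ha)
        .groupby("response")["contained"]
        .mean()
    )
    out["containment_rate"] = contained
    return out


def pm25_exceedance(series: np.ndarray, threshold: float = 27.0) -> dict:
    """Exceedance-day count and annual maximum of a daily PM2.5 series.

    The count is of days strictly above ``threshold`` (µg m⁻³).
    Missing days (NaN) are ignored; an all-missing series is flagged.
    """
    x = np.asarray(series, dtype=float)
    valid = np.isfinite(x)
    if not valid.any():
        return {"exceedance_days": None, "annual_max": None, "ok": False}
    return {
        "exceedance_days": int((x[valid] > threshold).sum()),
        "annual_max": float(x[valid].max()),
        "ok": True,
    }
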