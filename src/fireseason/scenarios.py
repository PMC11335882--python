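"""Canonical synthetic study scenarios exercised end to end.

Each function builds one self-contained synthetic study — stationary
climate for the exceedance/extent statistics, implanted-ridge blocking
recovery, the 20-fire burned-area recovery, the large-fire day-of-burn
kriging check — runs the corresponding pipeline stages, and returns the
measured quantities together with the generator truth.  The scenario
parameters below *are* the study conditions; tests and the acceptance
script both consume these functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import Point

from .blocking import BlockingConfig, anomaly_field, blocking_day_map, detect_events
from .burn_dates import KrigingConfig, daily_area_series, krige_burn_dates, prepare_hotspots
from .climatology import ForestMask, correlate_extent_burn, extent_series, percentile_field
from .fwi import OverwinterParams, SeasonRules, run_fwi_grid
from .geometry import cell_areas_km2
from .metrics import duration_spread_analysis, fit_power_law
from .perimeters import (
    buffer_hotspots,
    calibration_factors,
    clean_polygons,
    merge_hybrid,
    optimize_radii,
)
from .synthetic import (
    FireScenarioParams,
    FireSpec,
    GridSpec,
    RidgeImplant,
    gen_fires,
    gen_heights,
    gen_weather,
)

__all__ = [
    "stationary_exceedance_study",
    "blocking_recovery_study",
    "burned_area_recovery_study",
    "kriging_accuracy_study",
    "fire_season_association_study",
]


# ---------------------------------------------------------------------------
# stationary FWI95 exceedance / extent study
# ---------------------------------------------------------------------------

def stationary_exceedance_study(
    seed: int = 0,
    grid: GridSpec = GridSpec(nlat=20, nlon=20),
    baseline_years: tuple[int, int] = (1991, 2020),
    eval_years: tuple[int, int] = (2021, 2025),
) -> dict:
    """30-year baseline + 5 evaluation years from the same process.

    Under stationarity the per-cell probability of exceeding the
    baseline FWI95 on an in-season evaluation day is 5% by construction,
    and the mean forested-extent proportion converges to 0.05.  Returns
    the measured exceedance rate and mean extent proportion.
    """
    weather = gen_weather(grid, baseline_years[0], eval_years[1], seed=seed)
    fields = run_fwi_grid(weather, SeasonRules(), OverwinterParams())
    q = percentile_field(fields, baseline_years, q=0.95, min_days=100)

    years = pd.DatetimeIndex(fields["time"].values).year
    in_eval = (years >= eval_years[0]) & (years <= eval_years[1])
    sub = fields.isel(time=np.flatnonzero(in_eval))
    fwi = sub["fwi"].where(sub["season_active"])
    exceed = (fwi > q.q95).sum().item()
    valid = fwi.notnull().sum().item()
    rate = exceed / valid

    canopy = xr.ones_like(q.q95.fillna(0.0)) * 0.6
    forest = ForestMask.from_canopy_cover(canopy)
    labels = xr.zeros_like(q.q95.fillna(0.0)).astype(int)
    areas = cell_areas_km2(grid.lat, grid.lon)
    ext = extent_series(sub, q, forest, labels, areas, region_names={0: "all"})
    # stationarity statistic: exceeding area over the *season-active*
    # forested area (off-season cells cannot exceed by definition, so the
    # fixed-denominator daily proportion dilutes the 5% property)
    active_area_ha = (
        (sub["season_active"].values * areas[None, :, :] * 100.0).sum(axis=(1, 2))
    )
    daily_area = ext.groupby("date")["area_ha"].sum().to_numpy()
    mean_prop = float(daily_area.sum() / active_area_ha.sum())
    return {
        "exceedance_rate": rate,
        "mean_extent_proportion": mean_prop,
        "n_cell_days": valid,
        "fields": fields,
        "q": q,
        "extent": ext,
        "grid": grid,
    }


# ---------------------------------------------------------------------------
# blocking recovery study
# ---------------------------------------------------------------------------

#: implant roster: (start, duration, lat slice, lon slice); 9×9 boxes on the
#: default grid exceed the 100,000 km² footprint criterion, 5×5 boxes do not
BLOCKING_ROSTER: tuple[tuple[str, int, tuple[int, int], tuple[int, int]], ...] = (
    ("2023-04-05", 3, (0, 9), (0, 9)),       # too short
    ("2023-04-16", 4, (10, 19), (0, 9)),     # too short
    ("2023-04-28", 5, (0, 9), (10, 19)),     # qualifies
    ("2023-05-12", 6, (10, 19), (10, 19)),   # qualifies
    ("2023-05-26", 7, (0, 9), (0, 9)),       # qualifies
    ("2023-06-10", 8, (10, 19), (0, 9)),     # qualifies
    ("2023-06-26", 7, (8, 13), (8, 13)),     # footprint below area floor
    ("2023-07-10", 9, (0, 9), (10, 19)),     # qualifies
    ("2023-07-27", 10, (10, 19), (10, 19)),  # qualifies
    ("2023-08-14", 12, (5, 14), (5, 14)),    # qualifies
)


def blocking_recovery_study(
    seed: int = 0, grid: GridSpec = GridSpec(nlat=20, nlon=20)
) -> dict:
    """Implant ten ridges straddling the duration and area criteria.

    Returns detected events, the qualifying-implant truth, truth per-cell
    blocking-day counts and the detected counts.
    """
    config = BlockingConfig()
    ridges = tuple(
        RidgeImplant(start, days, latsl, lonsl, amplitude_sd=2.5)
        for (start, days, latsl, lonsl) in BLOCKING_ROSTER
    )
    heights, _ = gen_heights(
        grid, 1991, 2023, ridges, eval_year=2023, seed=seed
    )
    areas = cell_areas_km2(grid.lat, grid.lon)
    z = anomaly_field(heights, (1991, 2020))
    events = detect_events(z, config, areas)
    detected_map = blocking_day_map(events, (grid.nlat, grid.nlon), config.season_months)

    def qualifies(days, latsl, lonsl):
        if days < config.min_days:
            return False
        box = np.zeros((grid.nlat, grid.nlon), dtype=bool)
        box[slice(*latsl), slice(*lonsl)] = True
        return float(areas[box].sum()) >= config.min_area_km2

    truth_events = [
        (pd.Timestamp(start), days, latsl, lonsl)
        for (start, days, latsl, lonsl) in BLOCKING_ROSTER
        if qualifies(days, latsl, lonsl)
    ]
    truth_map = np.zeros((grid.nlat, grid.nlon), dtype=int)
    for (_, days, latsl, lonsl) in truth_events:
        truth_map[slice(*latsl), slice(*lonsl)] += days

    matched = 0
    for (start, days, latsl, lonsl) in truth_events:
        box = np.zeros((grid.nlat, grid.nlon), dtype=bool)
        box[slice(*latsl), slice(*lonsl)] = True
        for e in events:
            if (
                e.start == start
                and e.duration == days
                and all(np.array_equal(m, box) for m in e.day_masks)
            ):
                matched += 1
                break
    precision = matched / len(events) if events else 0.0
    recall = matched / len(truth_events) if truth_events else 0.0
    return {
        "events": events,
        "truth_events": truth_events,
        "precision": precision,
        "recall": recall,
        "detected_day_map": detected_map,
        "truth_day_map": truth_map,
    }


# ---------------------------------------------------------------------------
# burned-area recovery study
# ---------------------------------------------------------------------------

_WEST = -1_300_000.0  # ecozone-0 fires sit west of x=0, ecozone-1 east
_EAST = 1_100_000.0
_Y0 = 2_200_000.0

CANDIDATE_RADII: tuple[tuple[float, float], ...] = tuple(
    (r_out, r_in)
    for r_out in (300.0, 400.0, 500.0, 600.0, 700.0, 800.0)
    for r_in in (0.0, 100.0, 200.0)
)


def _fire_layout(rng, year: int, n_per_zone: int, sizes_ha, mapped_mask, tag: str):
    """Scatter fires on a loose grid so perimeters never touch."""
    specs = []
    k = 0
    for zone, x0 in ((0, _WEST), (1, _EAST)):
        for i in range(n_per_zone):
            size = float(sizes_ha[k])
            specs.append(
                FireSpec(
                    fire_id=f"{tag}_{year}_{zone}_{i}",
                    x=x0 + (i % 4) * 60_000.0,
                    y=_Y0 + (i // 4) * 60_000.0 + zone * 15_000.0,
                    start_date=f"{year}-0{rng.integers(5, 9)}-0{rng.integers(1, 9)}",
                    n_days=int(rng.integers(6, 16)),
                    final_area_ha=size,
                    aspect=float(rng.uniform(1.2, 2.0)),
                    theta=float(rng.uniform(0, np.pi)),
                    cause="lightning" if rng.random() < 0.6 else "human",
                    response=str(rng.choice(["full", "modified", "monitored"])),
                    mapped=bool(mapped_mask[k]),
                )
            )
            k += 1
    return specs


def _water_bodies(rng, n=6):
    lakes = []
    for _ in range(n):
        cx = rng.uniform(_WEST - 40_000, _WEST + 220_000)
        cy = rng.uniform(_Y0 - 20_000, _Y0 + 100_000)
        lakes.append(Point(cx, cy).buffer(rng.uniform(400.0, 1200.0), quad_segs=16))
        cx = rng.uniform(_EAST - 40_000, _EAST + 220_000)
        cy = rng.uniform(_Y0 - 20_000, _Y0 + 100_000)
        lakes.append(Point(cx, cy).buffer(rng.uniform(400.0, 1200.0), quad_segs=16))
    return lakes


def _buffered_area_by_fire(hotspots: pd.DataFrame, params_by_zone, zone_of_fire):
    """Dissolved two-step buffered area (ha) per fire id."""
    out = {}
    for fid, grp in hotspots.groupby("fire_id"):
        params = params_by_zone[zone_of_fire[fid]]
        polys = buffer_hotspots(grp[["x", "y"]].to_numpy(), params)
        out[fid] = sum(p.area for p in polys) / 1e4
    return out


def burned_area_recovery_study(seed: int = 0) -> dict:
    """Full hotspot-to-hybrid pipeline on a 20-fire target scenario.

    Historical years 2013–2015 (8 mapped fires per ecozone per year)
    drive the radius optimisation and the ecozone calibration factors;
    the 2023 target year has 20 fires, 12 mapped and 8 hotspot-only,
    with water holes, unburned islands, sub-hectare sliver artifacts and
    pre-April false detections.  Returns the hybrid total, the truth
    total, and bookkeeping about the cleaning filters.
    """
    rng = np.random.default_rng(seed)
    water = _water_bodies(rng)
    scenario_params = FireScenarioParams()

    # --- historical years: optimise radii and calibrate -------------------
    hist_hotspots, hist_reference = [], []
    hist_truth_by_year = {}
    for k, year in enumerate((2013, 2014, 2015)):
        sizes = rng.uniform(700.0, 5000.0, 16)
        specs = _fire_layout(rng, year, 8, sizes, np.ones(16, bool), "h")
        out = gen_fires(tuple(specs), scenario_params, water=water, seed=seed * 101 + k)
        hs = prepare_hotspots(out["hotspots"])
        hist_hotspots.append(hs)
        ref = out["reference"]
        hist_reference.append(ref[~ref["fire_id"].str.startswith("sliver")].assign(year=year))
        hist_truth_by_year[year] = out

    hist_hs = pd.concat(hist_hotspots, ignore_index=True)
    hist_ref = pd.concat(hist_reference, ignore_index=True)
    radii = optimize_radii(hist_hs, hist_ref, list(CANDIDATE_RADII))

    zone_of_fire = dict(zip(hist_ref["fire_id"], hist_ref["ecozone"]))
    buffered_by_fire = _buffered_area_by_fire(hist_hs, radii, zone_of_fire)
    cal_rows = []
    for (zone, year), grp in hist_ref.groupby(["ecozone", "year"]):
        ref_area = grp["area_ha"].sum()
        buf_area = sum(buffered_by_fire.get(f, 0.0) for f in grp["fire_id"].unique())
        cal_rows.append(
            {"ecozone": zone, "year": year, "reference_area_ha": ref_area,
             "buffered_area_ha": buf_area}
        )
    factors = calibration_factors(pd.DataFrame(cal_rows), years=(2012, 2022))

    # --- target year ------------------------------------------------------
    sizes = rng.uniform(700.0, 6000.0, 20)
    mapped = np.array([True] * 6 + [False] * 4 + [True] * 6 + [False] * 4)
    specs = _fire_layout(rng, 2023, 10, sizes, mapped, "t")
    target = gen_fires(tuple(specs), scenario_params, water=water, seed=seed * 101 + 7)
    truth = target["truth"]

    hs_all = target["hotspots"]
    hs = prepare_hotspots(hs_all)
    n_false_removed = len(hs_all) - len(hs)

    mapped_ids = {s.fire_id for s in specs if s.mapped}
    reference = target["reference"]
    n_ref_before = len(reference)
    reference = clean_polygons(reference, water=target["water"], min_area_ha=1.0)
    n_slivers_removed = (
        n_ref_before
        - len(reference)
        - 0  # cleaning may split polygons; slivers tracked by id below
    )
    slivers_left = reference["fire_id"].str.startswith("sliver").sum()

    buffered_rows = []
    for fid, grp in hs.groupby("fire_id"):
        if fid in mapped_ids:
            continue
        zone = 0 if grp["x"].mean() < 0 else 1
        polys = buffer_hotspots(grp[["x", "y"]].to_numpy(), radii[zone])
        for i, poly in enumerate(polys):
            buffered_rows.append(
                {"fire_id": f"m3_{fid}_{i}", "ecozone": zone, "geometry": poly,
                 "area_ha": poly.area / 1e4}
            )
    buffered = clean_polygons(pd.DataFrame(buffered_rows), water=target["water"])

    hybrid, total = merge_hybrid(reference, buffered, factors)
    return {
        "total_ha": total,
        "truth_total_ha": truth.total_true_area_ha,
        "radii": radii,
        "factors": factors,
        "hybrid": hybrid,
        "records": target["records"],
        "truth": truth,
        "n_false_removed": n_false_removed,
        "n_false_planted": scenario_params.n_false_preseason,
        "slivers_left": int(slivers_left),
        "hotspots": hs,
        "specs": specs,
    }


# ---------------------------------------------------------------------------
# day-of-burn kriging study
# ---------------------------------------------------------------------------

def kriging_accuracy_study(seed: int = 0) -> dict:
    """One 20-day, ~100 kha elliptical fire with ~2,000 hotspots.

    Kriges the detection dates back to the 180-m grid and measures the
    per-pixel mean absolute day-of-burn error against the generator
    truth, plus the daily-area conservation identity.
    """
    spec = FireSpec(
        fire_id="big", x=-1_250_000.0, y=2_350_000.0, start_date="2023-06-01",
        n_days=20, final_area_ha=100_000.0, aspect=1.5, theta=0.4,
    )
    out = gen_fires(
        (spec,), FireScenarioParams(island_fraction=0.0, n_slivers=0), seed=seed
    )
    truth_grid = out["truth"].fire_day_grids["big"]
    hs = prepare_hotspots(out["hotspots"])
    hs = hs[hs["fire_id"] == "big"]

    # perimeter polygon: the generating ellipse reconstructed from truth pixels
    from shapely.ops import unary_union

    b = np.sqrt(spec.final_area_ha * 1e4 / (np.pi * spec.aspect))
    from .synthetic import _ellipse

    perimeter = _ellipse(spec.x, spec.y, spec.aspect * b, b, spec.theta)
    grid = krige_burn_dates(
        hs, perimeter, KrigingConfig(max_neighbors=3000), fire_id="big"
    )

    both = (grid.day >= 0) & (truth_grid.day >= 0)
    mae = float(np.abs(grid.day[both] - truth_grid.day[both]).mean())
    series = daily_area_series([grid])
    conserved = float(series["area_burned_ha"].sum()) == grid.footprint_area_ha()
    return {
        "mae_days": mae,
        "conserved": conserved,
        "n_hotspots": len(hs),
        "grid": grid,
        "truth_grid": truth_grid,
        "daily_series": series,
    }


# ---------------------------------------------------------------------------
# extent-vs-burn association + fire metrics on one coherent season
# ---------------------------------------------------------------------------

def fire_season_association_study(seed: int = 0) -> dict:
    """Couple daily burned area to extreme-fire-weather extent.

    Builds a short stationary climate, computes the FWI95 extent series,
    then generates a synthetic daily burned-area series whose magnitude
    follows the extent (plus noise) and measures the Spearman
    correlation — the analysis applied to Table-1-style data — plus a
    power-law size/spread-days fit on synthetic fire records.
    """
    rng = np.random.default_rng(seed)
    grid = GridSpec(nlat=10, nlon=10)
    study = stationary_exceedance_study(
        seed=seed, grid=grid, baseline_years=(1991, 2010), eval_years=(2011, 2012)
    )
    ext = study["extent"]
    ext = ext[pd.DatetimeIndex(ext["date"]).year == 2012].reset_index(drop=True)
    ext = ext[ext["area_ha"].notna()]

    # daily burn responds monotonically to extent with multiplicative noise
    burn = pd.DataFrame(
        {
            "date": ext["date"],
            "region": ext["region"],
            "area_burned_ha": (10.0 + ext["area_ha"] / 1e4)
            * rng.lognormal(0.0, 0.35, len(ext)),
        }
    )
    corr = correlate_extent_burn(ext, burn)

    # synthetic fire records: size follows a power law in spread days
    n = 200
    gamma_true = 1.0
    spread = rng.integers(0, 40, n)
    sizes = 300.0 * (spread + 1.0) ** gamma_true * rng.lognormal(0.0, 0.4, n)
    start = pd.Timestamp("2012-06-01")
    records = pd.DataFrame(
        {
            "fire_id": np.arange(n),
            "size_ha": sizes,
            "start_date": start,
            "out_date": [start + pd.Timedelta(days=int(d)) for d in rng.integers(20, 120, n)],
            "cause": rng.choice(["lightning", "human"], n, p=[0.6, 0.4]),
            "response": rng.choice(["full", "modified", "monitored"], n),
            "lon": rng.uniform(-120, -60, n),
            "lat": rng.uniform(50, 60, n),
        }
    )
    per_fire, per_side, _ = duration_spread_analysis(
        records, study["fields"], study["q"]
    )
    power = fit_power_law(sizes, spread)
    return {
        "spearman": float(corr["spearman"].iloc[0]),
        "power_law": power,
        "gamma_true": gamma_true,
        "per_fire": per_fire,
        "per_side": per_side,
        "median_duration": float(per_fire["duration_days"].median()),
    }
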