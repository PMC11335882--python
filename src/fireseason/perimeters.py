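"""Hotspot buffering, calibration and hybrid burned-area composites.

Thermal-anomaly point detections are turned into burned-area polygons by
a two-step buffer: each hotspot is buffered outward ``r_out`` metres,
overlapping discs are dissolved, and the dissolved boundary is
contracted inward ``r_in`` metres.  Buffered areas systematically
overestimate burned area (unburned islands, water), so per-ecozone
calibration factors — reference mapped area divided by buffered area,
over historical years — rescale them before the buffered estimates are
merged with reference-mapped perimeters into a hybrid composite.

All geometry here lives in the package's Albers equal-area projection
(metres); areas are hectares.  Perimeter sets are plain pandas
DataFrames with a shapely ``geometry`` column plus attribute columns
(``fire_id``, ``source``, ``area_ha``, ``ecozone``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import unary_union

__all__ = [
    "BufferParams",
    "CalibrationFactor",
    "buffer_hotspots",
    "optimize_radii",
    "calibration_factors",
    "clean_polygons",
    "merge_hybrid",
    "landcover_proportions",
    "LandcoverRaster",
]

SNAP_TOLERANCE_M = 1.0  # snap before dissolve to avoid slivers


@dataclass(frozen=True)
class BufferParams:
    r_out: float
    r_in: float
    ecozone: int | None = None

    def __post_init__(self):
        if not self.r_out > self.r_in >= 0:
            raise ValueError("require r_out > r_in >= 0")


@dataclass(frozen=True)
class CalibrationFactor:
    ecozone: int
    factor: float
    n_years: int

    def __post_init__(self):
        if self.factor <= 0:
            raise ValueError("calibration factor must be positive")


def _as_polygons(geom) -> list[Polygon]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, MultiPolygon):
        return list(geom.geoms)
    return [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]


def buffer_hotspots(points_xy: np.ndarray, params: BufferParams) -> list[Polygon]:
    """Two-step buffer: out ``r_out``, dissolve, contract ``r_in``.

    ``points_xy`` is an (n, 2) array of projected coordinates (m).
    Contraction may split a dissolved polygon or delete small parts.
    Returns disjoint polygons.
    """
    pts = np.asarray(points_xy, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        return []
    discs = [Point(x, y).buffer(params.r_out, quad_segs=32) for x, y in pts]
    dissolved = shapely.set_precision(unary_union(discs), SNAP_TOLERANCE_M)
    if params.r_in > 0:
        dissolved = dissolved.buffer(-params.r_in, quad_segs=32)
    return _as_polygons(dissolved)


def _iou(a, b) -> float:
    union = a.union(b).area
    return a.intersection(b).area / union if union > 0 else 0.0


def optimize_radii(
    hotspots: pd.DataFrame,
    reference: pd.DataFrame,
    candidates: list[tuple[float, float]],
    quad_segs: int = 8,
) -> dict[int, BufferParams]:
    """Pick per-ecozone buffer radii against reference perimeters.

    ``hotspots`` needs columns ``x``, ``y``, ``fire_id``; ``reference``
    needs ``fire_id``, ``ecozone``, ``geometry``.  Every candidate
    ``(r_out, r_in)`` pair is evaluated exhaustively per ecozone; the
    objective is the intersection-over-union of the dissolved buffered
    polygons with the reference union, which jointly maximises the
    intersecting area and minimises commission and omission error.  Ties
    break to the smallest ``r_out``, then smallest ``r_in``.  Ecozones
    with no reference fires are omitted with a warning.
    """
    if not candidates:
        raise ValueError("empty candidate grid")
    out: dict[int, BufferParams] = {}
    for ecozone, ref_zone in reference.groupby("ecozone"):
        fire_ids = set(ref_zone["fire_id"])
        pts = hotspots[hotspots["fire_id"].isin(fire_ids)]
        if pts.empty:
            warnings.warn(f"ecozone {ecozone}: no hotspots for reference fires")
            continue
        ref_union = unary_union(list(ref_zone["geometry"]))
        xy = pts[["x", "y"]].to_numpy()
        best = None
        for r_out, r_in in sorted(candidates):
            discs = [Point(x, y).buffer(r_out, quad_segs=quad_segs) for x, y in xy]
            buf = unary_union(discs)
            if r_in > 0:
                buf = buf.buffer(-r_in, quad_segs=quad_segs)
            score = _iou(buf, ref_union)
            if best is None or score > best[0] + 1e-12:
                best = (score, r_out, r_in)
        out[int(ecozone)] = BufferParams(r_out=best[1], r_in=best[2], ecozone=int(ecozone))
    return out


def calibration_factors(
    areas: pd.DataFrame, years: tuple[int, int] = (2012, 2022), weighted: bool = False
) -> dict[int, CalibrationFactor]:
    """Ecozone calibration factors from historical area pairs.

    ``areas`` has columns ``ecozone``, ``year``, ``reference_area_ha``,
    ``buffered_area_ha``.  Per stratum (ecozone, year) the ratio
    reference/buffered is formed; strata with zero buffered area are
    skipped with a warning.  Factors aggregate yearly ratios per ecozone
    by unweighted mean (``weighted=True`` pools areas instead).
    """
    df = areas[(areas["year"] >= years[0]) & (areas["year"] <= years[1])].copy()
    factors: dict[int, CalibrationFactor] = {}
    for ecozone, grp in df.groupby("ecozone"):
        good = grp["buffered_area_ha"] > 0
        if not good.all():
            warnings.warn(
                f"ecozone {ecozone}: skipping {int((~good).sum())} strata with zero buffered area"
            )
        grp = grp[good]
        if grp.empty:
            continue
        if weighted:
            factor = grp["reference_area_ha"].sum() / grp["buffered_area_ha"].sum()
        else:
            factor = (grp["reference_area_ha"] / grp["buffered_area_ha"]).mean()
        factors[int(ecozone)] = CalibrationFactor(
            ecozone=int(ecozone), factor=float(factor), n_years=len(grp)
        )
    return factors


def clean_polygons(
    perims: pd.DataFrame,
    water: shapely.Geometry | None = None,
    min_area_ha: float = 1.0,
) -> pd.DataFrame:
    """Erase water bodies, repair geometry, drop sub-threshold polygons.

    Water removal precedes the area filter, so fragments created by the
    erasure are themselves subject to the 1-ha minimum.  Areas are
    recomputed (hectares, equal-area metres) after cleaning.
    """
    rows = []
    for _, row in perims.iterrows():
        geom = row["geometry"]
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
        if water is not None and not water.is_empty:
            geom = geom.difference(water)
        for part in _as_polygons(geom):
            area_ha = part.area / 1e4
            if area_ha < min_area_ha:
                continue
            new = row.to_dict()
            new["geometry"] = part
            new["area_ha"] = area_ha
            rows.append(new)
    return pd.DataFrame(rows, columns=perims.columns)


def merge_hybrid(
    reference: pd.DataFrame,
    buffered: pd.DataFrame,
    factors: dict[int, CalibrationFactor],
) -> tuple[pd.DataFrame, float]:
    """Merge reference and calibrated buffered perimeters into a hybrid.

    Every fire must come from exactly one source.  The total burned area
    is Σ reference areas + Σ (buffered area × its ecozone factor).
    Returns ``(composite frame with provenance, total_ha)``.
    """
    both = set(reference.get("fire_id", [])) & set(buffered.get("fire_id", []))
    if both:
        raise ValueError(f"fires present in both sources: {sorted(both)}")

    ref = reference.copy()
    ref["source"] = "reference"
    ref["calibrated_area_ha"] = ref["area_ha"]

    buf = buffered.copy()
    buf["source"] = "buffered"
    if len(buf):
        missing = sorted(set(buf["ecozone"].astype(int)) - set(factors))
        if missing:
            raise ValueError(f"no calibration factor for ecozones {missing}")
        buf["calibrated_area_ha"] = [
            a * factors[int(z)].factor for a, z in zip(buf["area_ha"], buf["ecozone"])
        ]
    else:
        buf["calibrated_area_ha"] = pd.Series(dtype=float)

    hybrid = pd.concat([ref, buf], ignore_index=True)
    total_ha = float(hybrid["calibrated_area_ha"].sum())
    return hybrid, total_ha


@dataclass
class LandcoverRaster:
    """Classified land-cover raster on a regular equal-area grid.

    ``classes[i, j]`` holds integer class codes; pixel (i, j) is centred
    at ``(x0 + (j + 0.5)·pixel_m, y0 + (i + 0.5)·pixel_m)``.
    """

    classes: np.ndarray
    x0: float
    y0: float
    pixel_m: float
    class_names: dict[int, str]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.classes.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.pixel_m
        ys = self.y0 + (np.arange(ny) + 0.5) * self.pixel_m
        return np.meshgrid(xs, ys)


def landcover_proportions(
    perims: pd.DataFrame,
    raster: LandcoverRaster,
    nonfuel_classes: tuple[str, ...] = ("Water", "Rock"),
    region_col: str = "region",
) -> pd.DataFrame:
    """Proportion of burned area by land-cover class and region.

    Pixels are assigned to polygons by centre-in-polygon membership.
    Proportions are over fuel classes only and sum to 1 per region; the
    nonfuel fraction of burned pixels is reported separately.  Polygons
    entirely outside the raster raise an error naming the fires.
    """
    gx, gy = raster.pixel_centers()
    minx, maxx = gx.min(), gx.max()
    miny, maxy = gy.min(), gy.max()

    rows = []
    for region, grp in perims.groupby(region_col if region_col in perims else lambda _: "all"):
        outside = [
            fid
            for fid, g in zip(grp.get("fire_id", grp.index), grp["geometry"])
            if g.bounds[2] < minx or g.bounds[0] > maxx or g.bounds[3] < miny or g.bounds[1] > maxy
        ]
        if outside:
            raise ValueError(f"fires outside land-cover raster: {outside}")
        union = unary_union(list(grp["geometry"]))
        inside = shapely.contains_xy(union, gx.ravel(), gy.ravel())
        codes = raster.classes.ravel()[inside]
        counts = pd.Series(codes).value_counts()
        named = {raster.class_names[int(c)]: int(n) for c, n in counts.items()}
        fuel_total = sum(n for c, n in named.items() if c not in nonfuel_classes)
        total = sum(named.values())
        for cname, n in sorted(named.items()):
            is_fuel = cname not in nonfuel_classes
            rows.append(
                {
                    "region": region,
                    "class": cname,
                    "pixels": n,
                    "proportion": (n / fuel_total) if is_fuel and fuel_total else np.nan,
                    "nonfuel": not is_fuel,
                    "nonfuel_fraction": (n / total) if not is_fuel and total else np.nan,
                }
            )
    return pd.DataFrame(rows)
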