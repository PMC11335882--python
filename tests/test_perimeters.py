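"""Tests for hotspot buffering, calibration and the hybrid composite."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from fireseason.perimeters import (
    BufferParams,
    CalibrationFactor,
    buffer_hotspots,
    calibration_factors,
    clean_polygons,
    landcover_proportions,
    LandcoverRaster,
    merge_hybrid,
    optimize_radii,
)


class TestBufferHotspots:
    def test_single_point_net_disc(self):
        polys = buffer_hotspots(np.array([[0.0, 0.0]]), BufferParams(500.0, 200.0))
        assert len(polys) == 1
        assert polys[0].area == pytest.approx(np.pi * 300.0**2, rel=0.005)

    def test_overlapping_discs_dissolve(self):
        pts = np.array([[0.0, 0.0], [900.0, 0.0]])
        polys = buffer_hotspots(pts, BufferParams(500.0, 0.0))
        assert len(polys) == 1

    def test_distant_points_stay_separate(self):
        pts = np.array([[0.0, 0.0], [10_000.0, 0.0]])
        polys = buffer_hotspots(pts, BufferParams(500.0, 0.0))
        assert len(polys) == 2

    def test_empty_input(self):
        assert buffer_hotspots(np.empty((0, 2)), BufferParams(500.0, 0.0)) == []

    def test_contraction_monotone_in_r_in(self, rng):
        pts = rng.uniform(0, 5000, (30, 2))
        areas = []
        for r_in in (0.0, 100.0, 200.0, 300.0):
            polys = buffer_hotspots(pts, BufferParams(600.0, r_in))
            areas.append(sum(p.area for p in polys))
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            BufferParams(200.0, 300.0)


class TestOptimizeRadii:
    def test_recovers_disc_radius(self):
        # reference = 1500-m discs around each hotspot: buffering by the
        # disc radius reproduces the reference exactly, so it must win
        centers = np.array([[0.0, 0.0], [20_000.0, 0.0]])
        refs, spots = [], []
        for k, (cx, cy) in enumerate(centers):
            refs.append(
                {"fire_id": k, "ecozone": 1, "geometry": Point(cx, cy).buffer(1500.0, quad_segs=8)}
            )
            spots.append(pd.DataFrame({"x": [cx], "y": [cy], "fire_id": [k]}))
        candidates = [(r, 0.0) for r in (300.0, 800.0, 1500.0, 2500.0)]
        out = optimize_radii(pd.concat(spots), pd.DataFrame(refs), candidates)
        assert out[1].r_out == 1500.0

    def test_single_candidate_returned(self):
        refs = pd.DataFrame(
            [{"fire_id": 0, "ecozone": 3, "geometry": Point(0, 0).buffer(1000.0)}]
        )
        spots = pd.DataFrame({"x": [0.0], "y": [0.0], "fire_id": [0]})
        out = optimize_radii(spots, refs, [(700.0, 100.0)])
        assert out[3] == BufferParams(700.0, 100.0, ecozone=3)

    def test_tiny_reference_prefers_smallest_radii(self):
        refs = pd.DataFrame(
            [{"fire_id": 0, "ecozone": 0, "geometry": Point(0, 0).buffer(50.0)}]
        )
        spots = pd.DataFrame({"x": [0.0], "y": [0.0], "fire_id": [0]})
        out = optimize_radii(spots, refs, [(100.0, 0.0), (500.0, 0.0), (1000.0, 0.0)])
        assert out[0].r_out == 100.0

    def test_objective_beats_other_candidates(self, rng):
        """Chosen pair scores at least as well as every candidate (independent scorer)."""
        ref_poly = Point(0, 0).buffer(1200.0)
        refs = pd.DataFrame([{"fire_id": 0, "ecozone": 0, "geometry": ref_poly}])
        ang = rng.uniform(0, 2 * np.pi, 60)
        rad = 1100.0 * np.sqrt(rng.uniform(0, 1, 60))
        spots = pd.DataFrame(
            {"x": rad * np.cos(ang), "y": rad * np.sin(ang), "fire_id": 0}
        )
        candidates = [(400.0, 0.0), (700.0, 100.0), (1200.0, 300.0), (2000.0, 500.0)]
        out = optimize_radii(spots, refs, candidates)

        def score(r_out, r_in):
            polys = buffer_hotspots(spots[["x", "y"]].to_numpy(), BufferParams(r_out, r_in))
            from shapely.ops import unary_union

            buf = unary_union(polys)
            inter = buf.intersection(ref_poly).area
            commission = buf.difference(ref_poly).area
            omission = ref_poly.difference(buf).area
            return inter / (inter + commission + omission)

        chosen = score(out[0].r_out, out[0].r_in)
        for r_out, r_in in candidates:
            assert chosen >= score(r_out, r_in) - 5e-3  # discretisation tolerance


class TestCalibrationFactors:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(
            rows, columns=["ecozone", "year", "reference_area_ha", "buffered_area_ha"]
        )

    def test_constant_ratio(self):
        rows = [(1, y, 80_000.0, 100_000.0) for y in range(2012, 2023)]
        out = calibration_factors(self._table(rows))
        assert out[1].factor == pytest.approx(0.8)
        assert out[1].n_years == 11

    def test_mean_of_ratios(self):
        rows = [(1, 2012, 60.0, 100.0), (1, 2013, 100.0, 100.0)]
        out = calibration_factors(self._table(rows))
        assert out[1].factor == pytest.approx(0.8)

    def test_zero_buffered_stratum_skipped(self):
        rows = [(1, 2012, 60.0, 100.0), (1, 2013, 50.0, 0.0)]
        with pytest.warns(UserWarning):
            out = calibration_factors(self._table(rows))
        assert out[1].factor == pytest.approx(0.6)

    def test_random_strata_match_brute_force(self, rng):
        rows = []
        for z in (1, 2, 3):
            for y in range(2012, 2023):
                rows.append((z, y, rng.uniform(10, 100), rng.uniform(10, 100)))
        df = self._table(rows)
        out = calibration_factors(df)
        for z in (1, 2, 3):
            sub = df[df["ecozone"] == z]
            expected = np.mean(sub["reference_area_ha"] / sub["buffered_area_ha"])
            assert out[z].factor == pytest.approx(expected, rel=1e-12)


def _square(cx, cy, half):
    return Polygon(
        [(cx - half, cy - half), (cx + half, cy - half), (cx + half, cy + half), (cx - half, cy + half)]
    )


class TestCleanPolygons:
    def test_small_polygon_removed(self):
        perims = pd.DataFrame(
            {
                "fire_id": [0, 1],
                "ecozone": [1, 1],
                "geometry": [_square(0, 0, 35.0), _square(5000, 0, 500.0)],  # 0.49 / 100 ha
                "area_ha": [0.49, 100.0],
            }
        )
        out = clean_polygons(perims)
        assert list(out["fire_id"]) == [1]

    def test_lake_erased(self):
        perims = pd.DataFrame(
            {"fire_id": [0], "ecozone": [1], "geometry": [_square(0, 0, 1000.0)], "area_ha": [400.0]}
        )
        lake = _square(0, 0, 200.0)
        out = clean_polygons(perims, water=lake)
        assert out["area_ha"].sum() == pytest.approx(400.0 - 16.0)

    def test_no_water_overlap_identity(self):
        poly = _square(0, 0, 1000.0)
        perims = pd.DataFrame(
            {"fire_id": [0], "ecozone": [1], "geometry": [poly], "area_ha": [400.0]}
        )
        out = clean_polygons(perims, water=_square(10_000, 0, 100.0))
        assert out["area_ha"].iloc[0] == pytest.approx(400.0)


class TestMergeHybrid:
    @staticmethod
    def _set(ids, areas, ecozones):
        return pd.DataFrame(
            {"fire_id": ids, "area_ha": areas, "ecozone": ecozones,
             "geometry": [None] * len(ids)}
        )

    def test_empty_buffered(self):
        ref = self._set([1, 2], [60_000.0, 40_000.0], [1, 1])
        buf = self._set([], [], [])
        _, total = merge_hybrid(ref, buf, {})
        assert total == pytest.approx(100_000.0)

    def test_calibrated_sum(self):
        ref = self._set([1], [100_000.0], [1])
        buf = self._set([2], [50_000.0], [1])
        factors = {1: CalibrationFactor(1, 0.8, 10)}
        _, total = merge_hybrid(ref, buf, factors)
        assert total == pytest.approx(140_000.0)

    def test_conflicting_fire_rejected(self):
        ref = self._set([1], [10.0], [1])
        buf = self._set([1], [10.0], [1])
        with pytest.raises(ValueError, match="1"):
            merge_hybrid(ref, buf, {1: CalibrationFactor(1, 1.0, 1)})

    def test_additivity(self, rng):
        ref = self._set(list(range(5)), rng.uniform(10, 100, 5), [1] * 5)
        buf = self._set(list(range(5, 9)), rng.uniform(10, 100, 4), [2] * 4)
        factors = {2: CalibrationFactor(2, 0.7, 5)}
        hybrid, total = merge_hybrid(ref, buf, factors)
        assert total == pytest.approx(hybrid["calibrated_area_ha"].sum())
        assert total == pytest.approx(ref["area_ha"].sum() + 0.7 * buf["area_ha"].sum())


class TestLandcoverProportions:
    @staticmethod
    def _raster(classes):
        names = {0: "Water", 1: "Treed conifer", 2: "Treed broadleaf"}
        return LandcoverRaster(
            classes=classes, x0=0.0, y0=0.0, pixel_m=100.0, class_names=names
        )

    def test_uniform_conifer(self):
        raster = self._raster(np.ones((50, 50), dtype=int))
        perims = pd.DataFrame(
            {"fire_id": [0], "region": ["r"], "geometry": [_square(2500, 2500, 1000.0)]}
        )
        out = landcover_proportions(perims, raster)
        row = out[out["class"] == "Treed conifer"].iloc[0]
        assert row["proportion"] == pytest.approx(1.0)

    def test_half_split_along_midline(self):
        classes = np.ones((50, 50), dtype=int)
        classes[:, 25:] = 2
        raster = self._raster(classes)
        perims = pd.DataFrame(
            {"fire_id": [0], "region": ["r"], "geometry": [_square(2500, 2500, 1000.0)]}
        )
        out = landcover_proportions(perims, raster)
        p = out.set_index("class")["proportion"]
        assert p["Treed conifer"] == pytest.approx(0.5)
        assert p["Treed broadleaf"] == pytest.approx(0.5)

    def test_random_mosaic_matches_pixel_tally(self, rng):
        classes = rng.integers(0, 3, (40, 40))
        raster = self._raster(classes)
        square = _square(2000, 2000, 1500.0)
        perims = pd.DataFrame({"fire_id": [0], "region": ["r"], "geometry": [square]})
        out = landcover_proportions(perims, raster)
        # brute-force per-pixel tally
        gx, gy = raster.pixel_centers()
        inside = (
            (gx >= 500) & (gx <= 3500) & (gy >= 500) & (gy <= 3500)
        )
        codes = classes[inside]
        fuel = codes[codes != 0]
        for code, name in ((1, "Treed conifer"), (2, "Treed broadleaf")):
            got = out[out["class"] == name]["proportion"].iloc[0]
            assert got == pytest.approx((fuel == code).mean())
        water_row = out[out["class"] == "Water"].iloc[0]
        assert bool(water_row["nonfuel"])
        assert water_row["nonfuel_fraction"] == pytest.approx((codes == 0).mean())

    def test_polygon_outside_raster_rejected(self):
        raster = self._raster(np.ones((10, 10), dtype=int))
        perims = pd.DataFrame(
            {"fire_id": ["far"], "region": ["r"], "geometry": [_square(1e6, 1e6, 100.0)]}
        )
        with pytest.raises(ValueError, match="far"):
            landcover_proportions(perims, raster)
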