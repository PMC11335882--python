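"""Tests for climatologies, extreme-extent statistics and VPD."""

import math

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from fireseason.climatology import (
    ForestMask,
    correlate_extent_burn,
    extent_series,
    extreme_day_counts,
    percentile_field,
    season_anomaly_rank,
    standardized_anomaly,
    vpd_from_t_td,
)


class TestVpd:
    def test_saturation_gives_zero(self):
        assert float(vpd_from_t_td(17.0, 17.0)) == pytest.approx(0.0)

    def test_supersaturation_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert float(vpd_from_t_td(10.0, 12.0)) == 0.0

    def test_hand_evaluated_magnus(self):
        # improved-Magnus with 6.1094 hPa, 17.625, 243.04 °C at 30 / 10 °C
        es30 = 6.1094 * math.exp(17.625 * 30 / (243.04 + 30))
        es10 = 6.1094 * math.exp(17.625 * 10 / (243.04 + 10))
        assert float(vpd_from_t_td(30.0, 10.0)) == pytest.approx(es30 - es10, rel=1e-12)

    def test_positive_everywhere_dew_below_temp(self, rng):
        t = rng.uniform(-20, 35, 200)
        td = t - rng.uniform(0.01, 20, 200)
        assert (vpd_from_t_td(t, td) > 0).all()


def _fields(values, active=None, lat=None, lon=None, start="1991-01-01"):
    values = np.asarray(values, dtype=float)
    nt, nlat, nlon = values.shape
    times = pd.date_range(start, periods=nt, freq="D")
    if active is None:
        active = np.ones_like(values, dtype=bool)
    return xr.Dataset(
        {
            "fwi": (("time", "lat", "lon"), values),
            "season_active": (("time", "lat", "lon"), active),
        },
        coords={
            "time": times,
            "lat": lat if lat is not None else np.arange(nlat, dtype=float),
            "lon": lon if lon is not None else np.arange(nlon, dtype=float),
        },
    )


class TestPercentileField:
    def test_constant_series(self):
        ds = _fields(np.full((120, 1, 1), 7.0))
        q = percentile_field(ds, (1991, 1991), min_days=100)
        assert q.q95.values.item() == pytest.approx(7.0)

    def test_linear_interpolation_matches_brute_force(self, rng):
        vals = rng.uniform(0, 100, 150)
        ds = _fields(vals.reshape(-1, 1, 1))
        q = percentile_field(ds, (1991, 1991), min_days=100)
        s = np.sort(vals)
        pos = 0.95 * (len(s) - 1)
        k = int(pos)
        expected = s[k] + (pos - k) * (s[k + 1] - s[k])
        assert q.q95.values.item() == pytest.approx(expected, rel=1e-12)

    def test_off_season_values_ignored(self, rng):
        vals = rng.uniform(0, 50, 150).reshape(-1, 1, 1)
        active = np.ones_like(vals, dtype=bool)
        spiked = vals.copy()
        active2 = active.copy()
        spiked[::7] = 1e6
        active2[::7] = False
        q1 = percentile_field(_fields(vals, active2), (1991, 1991), min_days=100)
        q2 = percentile_field(_fields(spiked, active2), (1991, 1991), min_days=100)
        assert q1.q95.values.item() == pytest.approx(q2.q95.values.item())

    def test_day_permutation_invariance(self, rng):
        vals = rng.uniform(0, 50, 150)
        ds1 = _fields(vals.reshape(-1, 1, 1))
        ds2 = _fields(rng.permutation(vals).reshape(-1, 1, 1))
        q1 = percentile_field(ds1, (1991, 1991), min_days=100)
        q2 = percentile_field(ds2, (1991, 1991), min_days=100)
        assert q1.q95.values.item() == pytest.approx(q2.q95.values.item())

    def test_low_count_cells_masked(self):
        ds = _fields(np.full((50, 1, 1), 5.0))
        q = percentile_field(ds, (1991, 1991), min_days=100)
        assert np.isnan(q.q95.values.item())


def _extent_setup(exceed: bool, nlat=2, nlon=2):
    vals = np.full((3, nlat, nlon), 10.0 if exceed else 1.0)
    ds = _fields(vals)
    q95 = xr.DataArray(
        np.full((nlat, nlon), 5.0), coords={"lat": ds.lat, "lon": ds.lon}, dims=("lat", "lon")
    )
    from fireseason.climatology import PercentileField

    q = PercentileField(q95=q95, baseline_years=(1991, 2020), n_days=q95 * 0 + 200)
    forest = ForestMask(mask=xr.ones_like(q95).astype(bool))
    labels = xr.zeros_like(q95).astype(int)
    areas = np.full((nlat, nlon), 2.0)
    return ds, q, forest, labels, areas


class TestExtentSeries:
    def test_no_exceedance_gives_zero(self):
        ds, q, forest, labels, areas = _extent_setup(False)
        ext = extent_series(ds, q, forest, labels, areas)
        assert (ext["area_ha"] == 0).all() and (ext["proportion"] == 0).all()

    def test_full_exceedance_gives_region_area(self):
        ds, q, forest, labels, areas = _extent_setup(True)
        ext = extent_series(ds, q, forest, labels, areas)
        assert (ext["proportion"] == 1.0).all()
        assert (ext["area_ha"] == 4 * 2.0 * 100).all()

    def test_proportion_invariant_to_area_rescaling(self):
        ds, q, forest, labels, areas = _extent_setup(True)
        p1 = extent_series(ds, q, forest, labels, areas)["proportion"]
        p2 = extent_series(ds, q, forest, labels, areas * 37.5)["proportion"]
        np.testing.assert_allclose(p1, p2)

    def test_misaligned_grids_rejected(self):
        ds, q, forest, labels, areas = _extent_setup(True)
        q.q95 = q.q95.assign_coords(lat=q.q95.lat + 0.1)
        with pytest.raises(ValueError, match="aligned"):
            extent_series(ds, q, forest, labels, areas)


class TestExtremeDayCounts:
    def test_constructed_exceedances_counted(self):
        vals = np.full((365 * 2, 1, 1), 1.0)
        vals[3] = vals[40] = vals[400] = 10.0  # 2 in year1, 1 in year2
        ds = _fields(vals, start="1991-01-01")
        from fireseason.climatology import PercentileField

        q95 = xr.DataArray([[5.0]], coords={"lat": ds.lat, "lon": ds.lon}, dims=("lat", "lon"))
        q = PercentileField(q95=q95, baseline_years=(1991, 1991), n_days=q95 * 0 + 200)
        out = extreme_day_counts(ds, q, 1992)
        assert int(out["count"].values.item()) == 1
        assert out["anomaly"].values.item() == pytest.approx(1 - 2)

    def test_never_exceeding_cell(self):
        vals = np.full((365 * 2, 1, 1), 1.0)
        ds = _fields(vals)
        from fireseason.climatology import PercentileField

        q95 = xr.DataArray([[5.0]], coords={"lat": ds.lat, "lon": ds.lon}, dims=("lat", "lon"))
        q = PercentileField(q95=q95, baseline_years=(1991, 1991), n_days=q95 * 0 + 200)
        out = extreme_day_counts(ds, q, 1992)
        assert int(out["count"].values.item()) == 0
        assert out["anomaly"].values.item() == pytest.approx(-out["baseline_mean"].values.item())


class TestStandardizedAnomaly:
    def test_mean_and_sd_points(self, rng):
        base = xr.DataArray(rng.normal(10, 2, 200), dims=("time",))
        mean = float(base.mean())
        sd = float(base.std(ddof=1))
        assert float(standardized_anomaly(xr.DataArray(mean), base)) == pytest.approx(0.0, abs=1e-12)
        assert float(standardized_anomaly(xr.DataArray(mean + sd), base)) == pytest.approx(1.0, abs=1e-12)

    def test_zero_sd_masked(self):
        base = xr.DataArray(np.full(10, 3.0), dims=("time",))
        with pytest.warns(UserWarning):
            z = standardized_anomaly(xr.DataArray(4.0), base)
        assert np.isnan(float(z))


class TestSeasonAnomalyRank:
    @staticmethod
    def _series(per_year: dict):
        frames = []
        for year, val in per_year.items():
            times = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
            frames.append(
                xr.DataArray(
                    np.full((len(times), 1, 1), float(val)),
                    coords={"time": times, "lat": [0.0], "lon": [0.0]},
                    dims=("time", "lat", "lon"),
                )
            )
        return xr.concat(frames, dim="time")

    def test_rank_one_for_maximum_year(self):
        field = self._series({2000: 1.0, 2001: 2.0, 2002: 5.0})
        out = season_anomaly_rank(field, 2002, baseline_years=(2000, 2001))
        assert int(out["rank"].values.item()) == 1
        assert out["anomaly"].values.item() == pytest.approx(5.0 - 1.5)

    def test_precip_direction_rank_one_driest(self):
        field = self._series({2000: 5.0, 2001: 3.0, 2002: 1.0})
        out = season_anomaly_rank(
            field, 2002, baseline_years=(2000, 2001), rank_direction="low"
        )
        assert int(out["rank"].values.item()) == 1

    def test_ranks_match_brute_force_sort(self, rng):
        vals = {2000 + i: v for i, v in enumerate(rng.normal(0, 1, 8))}
        field = self._series(vals)
        target = 2004
        out = season_anomaly_rank(field, target, baseline_years=(2000, 2007))
        expected = 1 + sum(v > vals[target] for v in vals.values())
        assert int(out["rank"].values.item()) == expected

    def test_missing_year_listed(self):
        field = self._series({2000: 1.0, 2002: 2.0})
        with pytest.raises(ValueError, match="2001"):
            season_anomaly_rank(field, 2002, baseline_years=(2000, 2002))


class TestCorrelateExtentBurn:
    @staticmethod
    def _frames(ext_vals, burn_vals):
        dates = pd.date_range("2023-06-01", periods=len(ext_vals), freq="D")
        ext = pd.DataFrame({"date": dates, "region": "r", "area_ha": ext_vals})
        burn = pd.DataFrame({"date": dates, "region": "r", "area_burned_ha": burn_vals})
        return ext, burn

    def test_comonotone_is_one(self):
        ext, burn = self._frames([1, 2, 3, 4], [10, 20, 30, 40])
        out = correlate_extent_burn(ext, burn)
        assert out["spearman"].iloc[0] == pytest.approx(1.0)

    def test_antimonotone_is_minus_one(self):
        ext, burn = self._frames([1, 2, 3, 4], [8, 6, 4, 2])
        out = correlate_extent_burn(ext, burn)
        assert out["spearman"].iloc[0] == pytest.approx(-1.0)

    def test_ties_match_brute_force_midranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 7.0, 8.0, 9.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 4.0, 6.0, 7.0, 7.0, 9.0, 10.0])

        def midranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        ext, burn = self._frames(x, y)
        out = correlate_extent_burn(ext, burn)
        assert out["spearman"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.uniform(0, 1, 30)
        y = rng.uniform(0, 1, 30)
        ext1, burn1 = self._frames(x, y)
        ext2, burn2 = self._frames(np.exp(3 * x), y**3)
        r1 = correlate_extent_burn(ext1, burn1)["spearman"].iloc[0]
        r2 = correlate_extent_burn(ext2, burn2)["spearman"].iloc[0]
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_too_few_days_flagged(self):
        ext, burn = self._frames([1, 2], [3, 4])
        out = correlate_extent_burn(ext, burn)
        assert not out["ok"].iloc[0] and np.isnan(out["spearman"].iloc[0])
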