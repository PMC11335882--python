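"""Unit and property tests for the FWI System engine."""

import datetime

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

import _fwi_oracle as oracle
from conftest import random_weather_sequence
from fireseason.fwi import (
    DEFAULT_STARTUP,
    CodeState,
    OverwinterParams,
    SeasonRules,
    WeatherObs,
    buildup_index,
    compute_indices,
    dc_update,
    dmc_update,
    ffmc_update,
    fire_weather_index,
    initial_spread_index,
    overwinter_dc,
    run_fwi_grid,
    season_mask,
    update_codes,
)

JULY = datetime.date(2023, 7, 15)


class TestUpdateCodes:
    def test_dry_warm_day_raises_dc(self):
        prev = CodeState(ffmc=85, dmc=10, dc=100)
        obs = WeatherObs(temp_c=25, rh_pct=40, wind_kmh=10, precip_mm=0, date=JULY)
        assert update_codes(prev, obs).dc > 100

    def test_heavy_rain_lowers_ffmc(self):
        prev = CodeState(ffmc=90, dmc=10, dc=100)
        for temp in (0.0, 15.0, 30.0):
            obs = WeatherObs(temp_c=temp, rh_pct=70, wind_kmh=5, precip_mm=20, date=JULY)
            assert update_codes(prev, obs).ffmc < 90

    def test_invalid_weather_rejected(self):
        with pytest.raises(ValueError):
            WeatherObs(temp_c=20, rh_pct=120, wind_kmh=5, precip_mm=0, date=JULY)
        with pytest.raises(ValueError):
            WeatherObs(temp_c=20, rh_pct=50, wind_kmh=-1, precip_mm=0, date=JULY)
        with pytest.raises(ValueError):
            WeatherObs(temp_c=20, rh_pct=50, wind_kmh=5, precip_mm=-2, date=JULY)

    def test_matches_scalar_oracle_on_random_sequences(self, rng):
        """Vectorised updates equal an independent scalar transcription."""
        for _ in range(50):
            seq = random_weather_sequence(rng, n_days=60)
            expected = oracle.run_sequence(85.0, 6.0, 15.0, seq)
            f, d, c = 85.0, 6.0, 15.0
            for (t, h, w, p, m), exp in zip(seq, expected):
                f = float(ffmc_update(f, t, h, w, p))
                d = float(dmc_update(d, t, h, p, m))
                c = float(dc_update(c, t, p, m))
                isi = float(initial_spread_index(f, w))
                bui = float(buildup_index(d, c))
                fwi = float(fire_weather_index(isi, bui))
                assert np.allclose([f, d, c, isi, bui, fwi], exp, atol=1e-9)


class TestComputeIndices:
    def test_bui_zero_when_dmc_zero(self):
        codes = CodeState(ffmc=85, dmc=0, dc=0)
        assert compute_indices(codes, 10).bui == 0

    def test_isi_increasing_in_wind(self):
        codes = CodeState(ffmc=90, dmc=20, dc=200)
        assert compute_indices(codes, 30).isi > compute_indices(codes, 0).isi

    def test_fwi_zero_when_isi_zero(self):
        # ISI can only hit 0 at ffmc=0 with huge negative... assert the invariant form
        assert float(fire_weather_index(0.0, 50.0)) == 0.0

    def test_negative_wind_rejected(self):
        with pytest.raises(ValueError):
            compute_indices(CodeState(ffmc=85, dmc=5, dc=20), -3)

    @settings(max_examples=200, deadline=None)
    @given(
        ffmc=st.floats(0, 101),
        dmc=st.floats(0, 400),
        dc=st.floats(0, 1200),
        wind=st.floats(0, 100),
    )
    def test_bounds_hold_everywhere(self, ffmc, dmc, dc, wind):
        isi = float(initial_spread_index(ffmc, wind))
        bui = float(buildup_index(dmc, dc))
        fwi = float(fire_weather_index(isi, bui))
        assert isi >= 0 and bui >= 0 and fwi >= 0


class TestSeasonMask:
    def test_startup_after_three_warm_days(self):
        tmax = np.full(10, 13.0)
        mask = season_mask(tmax, SeasonRules())
        # on the day AFTER the third qualifying day
        assert not mask[:3].any() and mask[3:].all()

    def test_never_active_when_cold(self):
        assert not season_mask(np.full(30, 12.0)).any()

    def test_shutdown_after_three_cold_days(self):
        tmax = np.concatenate([np.full(5, 15.0), np.full(5, 4.0)])
        mask = season_mask(tmax)
        assert mask[3:8].all() and not mask[8:].any()

    def test_multiple_cycles(self):
        tmax = np.concatenate(
            [np.full(5, 15.0), np.full(5, 0.0), np.full(5, 15.0), np.full(5, 0.0)]
        )
        mask = season_mask(tmax)
        assert mask[3:8].all() and not mask[8:13].any() and mask[13:18].all()

    def test_short_series_warns_all_inactive(self):
        with pytest.warns(UserWarning):
            mask = season_mask(np.array([20.0, 20.0]))
        assert not mask.any()


class TestOverwinterDc:
    def test_identity_carryover(self):
        assert float(overwinter_dc(237.0, 0.0, OverwinterParams(a=1.0, b=0.5))) == pytest.approx(237.0)

    def test_monotone_in_precip(self):
        lo = float(overwinter_dc(300.0, 50.0))
        hi = float(overwinter_dc(300.0, 250.0))
        assert lo >= hi

    def test_matches_closed_form(self):
        got = float(overwinter_dc(300.0, 150.0, OverwinterParams(a=0.75, b=0.75)))
        assert got == pytest.approx(oracle.overwinter_oracle(300.0, 150.0, 0.75, 0.75), abs=1e-9)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            OverwinterParams(a=1.5, b=0.5)


def _weather_dataset(rng, nlat=2, nlon=2, year0=2022, year1=2023):
    times = pd.date_range(f"{year0}-01-01", f"{year1}-12-31", freq="D")
    doy = times.dayofyear.to_numpy()
    clim = 5.0 + 18.0 * np.cos(2 * np.pi * (doy - 200) / 365.25)
    n = len(times)
    shape = (n, nlat, nlon)
    temp = clim[:, None, None] + rng.normal(0, 3, shape)
    data = {
        "temp": temp,
        "tmax": temp + 5.0,
        "rh": np.clip(rng.normal(70, 15, shape), 5, 100),
        "wind": rng.gamma(2.0, 6.0, shape),
        "precip": np.where(rng.random(shape) < 0.3, rng.gamma(0.8, 5.0, shape), 0.0),
    }
    return xr.Dataset(
        {k: (("time", "lat", "lon"), v) for k, v in data.items()},
        coords={"time": times, "lat": np.arange(nlat) * 0.5 + 52, "lon": np.arange(nlon) * 0.5 - 118},
    )


class TestRunFwiGrid:
    def test_missing_variable_errors(self, rng):
        ds = _weather_dataset(rng).drop_vars("wind")
        with pytest.raises(KeyError, match="wind"):
            run_fwi_grid(ds)

    def test_cell_independence_under_permutation(self, rng):
        ds = _weather_dataset(rng, nlat=3, nlon=1)
        out = run_fwi_grid(ds)
        flipped = ds.isel(lat=[2, 1, 0])
        out2 = run_fwi_grid(flipped)
        np.testing.assert_array_equal(
            out["fwi"].values[:, ::-1, :], out2["fwi"].values
        )

    def test_grid_equals_scalar_walk(self, rng):
        """1×1 grid reproduces a scalar walk with identical transitions."""
        ds = _weather_dataset(rng, nlat=1, nlon=1, year0=2023, year1=2023)
        out = run_fwi_grid(ds)
        mask = out["season_active"].values[:, 0, 0]
        temp = ds["temp"].values[:, 0, 0]
        rh = ds["rh"].values[:, 0, 0]
        wind = ds["wind"].values[:, 0, 0]
        precip = ds["precip"].values[:, 0, 0]
        months = pd.DatetimeIndex(ds["time"].values).month

        f, d, c = 85.0, 6.0, 15.0
        started = False
        for i in range(len(temp)):
            if not mask[i]:
                assert np.isnan(out["fwi"].values[i, 0, 0])
                continue
            started = True
            f = oracle.ffmc_next(f, temp[i], rh[i], wind[i], precip[i])
            d = oracle.dmc_next(d, temp[i], rh[i], precip[i], months[i])
            c = oracle.dc_next(c, temp[i], precip[i], months[i])
            assert out["ffmc"].values[i, 0, 0] == pytest.approx(f, abs=1e-9)
            assert out["dmc"].values[i, 0, 0] == pytest.approx(d, abs=1e-9)
            assert out["dc"].values[i, 0, 0] == pytest.approx(c, abs=1e-9)
        assert started

    def test_spring_dc_equals_overwinter_of_fall_dc(self, rng):
        """Across a winter, startup DC is the overwintered fall DC."""
        ds = _weather_dataset(rng, nlat=1, nlon=1, year0=2022, year1=2023)
        out = run_fwi_grid(ds)
        mask = out["season_active"].values[:, 0, 0]
        precip = ds["precip"].values[:, 0, 0]

        transitions = np.flatnonzero(np.diff(mask.astype(int)))
        # need at least one full off-then-on cycle
        offs = [i for i in transitions if mask[i] and not mask[i + 1]]
        ons = [i for i in transitions if not mask[i] and mask[i + 1]]
        restarts = [on for on in ons if any(off < on for off in offs)]
        assert restarts, "no overwinter restart in the synthetic series"
        on = restarts[0]
        off = max(off for off in offs if off < on)
        fall_dc = out["dc"].values[off, 0, 0]
        winter_rain = precip[off + 1 : on + 1].sum()
        expected = oracle.overwinter_oracle(fall_dc, winter_rain, 0.75, 0.75)
        # first active day applies one daily update on top of the startup DC
        start_dc = out["dc"].values[on + 1, 0, 0]
        months = pd.DatetimeIndex(ds["time"].values).month
        stepped = oracle.dc_next(
            expected, ds["temp"].values[on + 1, 0, 0], precip[on + 1], months[on + 1]
        )
        assert start_dc == pytest.approx(stepped, abs=1e-9)
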