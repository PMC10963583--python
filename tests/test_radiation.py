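"""Radiation model: shadows, sky view, longwave limits, T_mrt."""

import numpy as np
import pandas as pd
import pytest

from heatscape.radiation import (SIGMA, RadiationConfig, VegParams, cast_shadow,
                                 longwave_components, mean_radiant_flux,
                                 shortwave_components, sky_view_factor,
                                 tmrt_from_sstr, tmrt_timeseries, run_tiled)
from heatscape.rasters import SiteRasters
from heatscape.solar import SunPosition
from heatscape.synthetic import default_demo_site, gen_site_rasters
from heatscape.timeseries import InputError, MetSeries

from oracles import shadow_oracle
from conftest import random_scene


class TestCastShadow:
    def test_zenith_sun_shadow_equals_footprint(self, box_site_rasters):
        sf = cast_shadow(box_site_rasters, SunPosition(0.0, 0.001))
        footprint = (box_site_rasters.dsm - box_site_rasters.dem) > 0
        np.testing.assert_array_equal(sf.building_shadow, footprint)

    def test_45deg_shadow_extends_building_height(self, box_site_rasters):
        # sun due north at 45 deg elevation: 10 m box, rows 15..24 occupied,
        # shadow reaches 10 m south of the south wall
        sf = cast_shadow(box_site_rasters, SunPosition(0.0, 45.0))
        rows = np.flatnonzero(sf.building_shadow.any(axis=1))
        assert rows.min() == 15 and rows.max() == 34

    def test_under_crown_transmission(self, mixed_site_rasters):
        sf = cast_shadow(mixed_site_rasters, SunPosition(0.0, 30.0))
        under = (mixed_site_rasters.chm > 0) & ~sf.building_shadow
        assert np.all(sf.transmission[under & sf.veg_shadow] == 0.03)

    def test_night_sun_rejected(self, box_site_rasters):
        with pytest.raises(InputError):
            cast_shadow(box_site_rasters, SunPosition(0.0, 95.0))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("azimuth,elevation", [(37.0, 25.0), (210.0, 55.0)])
    def test_matches_ray_marching_oracle(self, seed, azimuth, elevation):
        rng = np.random.default_rng(seed)
        rasters = random_scene(rng, max_size=35)
        sun = SunPosition(azimuth, 90.0 - elevation)
        fast = cast_shadow(rasters, sun)
        slow_b, slow_v = shadow_oracle(rasters, sun)
        np.testing.assert_array_equal(fast.building_shadow, slow_b)
        np.testing.assert_array_equal(fast.veg_shadow, slow_v)


class TestSkyViewFactor:
    def test_flat_open_ground(self):
        flat = gen_site_rasters(default_demo_site(30.0).__class__(extent=(30.0, 30.0)))
        svf = sky_view_factor(flat)
        np.testing.assert_allclose(svf, 1.0, atol=1e-3)

    def test_infinite_canyon_analytic_value(self):
        # H/W = 1 canyon (20 m walls, 20 m floor): floor-centre SVF is
        # cos(arctan 2) = 0.4472 in the continuum
        ny = nx = 120
        dem = np.zeros((ny, nx))
        dsm = dem.copy()
        dsm[:50, :] = 20.0
        dsm[70:, :] = 20.0
        canyon = SiteRasters(dem, dsm, np.zeros_like(dem))
        svf = sky_view_factor(canyon, n_directions=72, max_radius=120)
        centre = svf[59:61, 55:65].mean()
        assert centre == pytest.approx(np.cos(np.arctan(2.0)), abs=0.02)

    def test_monotone_in_building_height(self, box_site_rasters):
        svf_low = sky_view_factor(box_site_rasters)
        taller = SiteRasters(box_site_rasters.dem,
                             box_site_rasters.dem + 2 * box_site_rasters.building_height,
                             box_site_rasters.chm)
        svf_high = sky_view_factor(taller)
        assert np.all(svf_high <= svf_low + 1e-12)
        assert svf_high.min() < svf_low.min()


class TestLongwave:
    cfg = RadiationConfig()

    def test_isothermal_enclosure_blackbody(self):
        svf = np.array([[0.0]])
        ld, lu, ll = longwave_components(15.0, 50.0, 0.0, svf, np.array([[0.0]]),
                                         self.cfg)
        expected = SIGMA * (15.0 + 273.15) ** 4
        for comp in (ld, lu, ll):
            assert comp[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_ldown_increases_with_humidity(self):
        svf = np.array([[1.0]])
        zeros = np.array([[0.0]])
        prev = -np.inf
        for rh in (20.0, 50.0, 80.0):
            ld, _, _ = longwave_components(20.0, rh, 0.0, svf, zeros, self.cfg)
            assert ld[0, 0] > prev
            prev = ld[0, 0]

    def test_overcast_night_approaches_blackbody(self):
        svf = np.array([[1.0]])
        ld, _, _ = longwave_components(10.0, 80.0, 1.0, svf, np.array([[0.0]]),
                                       self.cfg)
        assert ld[0, 0] == pytest.approx(SIGMA * 283.15 ** 4, rel=1e-12)


class TestMeanRadiantFlux:
    def test_isotropic_longwave_reference(self):
        iso = SIGMA * 273.15 ** 4 * np.ones((2, 2))
        zeros = np.zeros((2, 2))
        sstr = mean_radiant_flux(zeros, zeros, [zeros] * 4, iso, iso, iso)
        np.testing.assert_allclose(sstr, 0.97 * SIGMA * 273.15 ** 4, rtol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        comps = [rng.uniform(0, 300, (3, 3)) for _ in range(3)]
        k_lat = [rng.uniform(0, 100, (3, 3)) for _ in range(4)]
        s1 = mean_radiant_flux(comps[0], comps[1], k_lat, comps[2], comps[2], comps[2])
        s2 = mean_radiant_flux(2 * comps[0], 2 * comps[1], [2 * k for k in k_lat],
                               2 * comps[2], 2 * comps[2], 2 * comps[2])
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-12)

    def test_negative_component_rejected(self):
        z = np.zeros((1, 1))
        with pytest.raises(InputError):
            mean_radiant_flux(z - 1, z, [z] * 4, z, z, z)

    def test_energy_bound(self):
        rng = np.random.default_rng(5)
        kd, ku = rng.uniform(0, 800, (2, 4, 4))
        kl = [rng.uniform(0, 400, (4, 4)) for _ in range(4)]
        ld, lu, ll = rng.uniform(200, 500, (3, 4, 4))
        sstr = mean_radiant_flux(kd, ku, kl, ld, lu, ll)
        bound = 0.7 * (kd + ku + sum(kl)) + 0.97 * np.maximum.reduce([ld, lu, ll])
        assert np.all(sstr <= bound + 1e-9)


class TestTmrtInversion:
    def test_zero_celsius(self):
        assert tmrt_from_sstr(0.97 * SIGMA * 273.15 ** 4) == pytest.approx(0.0, abs=1e-9)

    def test_300_kelvin(self):
        assert tmrt_from_sstr(0.97 * SIGMA * 300.0 ** 4) == pytest.approx(26.85, abs=1e-9)

    def test_strictly_increasing(self):
        s = np.linspace(10.0, 900.0, 50)
        assert np.all(np.diff(tmrt_from_sstr(s)) > 0)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            tmrt_from_sstr(-1.0)


def _noon_met(swdown=900.0, tair=25.0):
    idx = pd.DatetimeIndex([pd.Timestamp("1995-01-15 12:00")])
    return MetSeries(pd.DataFrame(
        {"tair": [tair], "rh": [40.0], "wind10": [3.0], "swdown": [swdown]},
        index=idx))


def test_shade_effect_exceeds_10_degrees():
    """Clear noon sun over buildings and trees: shaded cells are markedly
    cooler, with a site-wide T_mrt range above 10 degC."""
    rasters = gen_site_rasters(default_demo_site(60.0))
    da = tmrt_timeseries(rasters, _noon_met(), RadiationConfig(max_radius=40.0))
    grid = da.values[0]
    assert grid.max() - grid.min() > 10.0
    sf = cast_shadow(rasters, SunPosition(0.0, 25.0), max_radius=40.0)
    # compare fully shaded vs fully sunlit cells under the actual sun
    from heatscape.solar import solar_position
    sun = solar_position(da["time"].values[0], -42.883, 147.330, 10.0)
    sf = cast_shadow(rasters, sun, max_radius=40.0)
    assert grid[sf.building_shadow].mean() < grid[sf.sunlit].mean() - 5.0


def test_tiled_equals_untiled():
    rasters = gen_site_rasters(default_demo_site(60.0))
    idx = pd.date_range("1995-01-15 04:00", periods=18, freq="h")
    rng = np.random.default_rng(0)
    met = MetSeries(pd.DataFrame({
        "tair": 22 + 4 * rng.random(18), "rh": 50.0, "wind10": 3.0,
        "swdown": np.clip(900 * np.sin(np.pi * (np.arange(18) - 2) / 14), 0, None),
    }, index=idx))
    cfg = RadiationConfig(max_radius=20.0)
    tiled = run_tiled(rasters, met, tile=30.0, buffer=20.0, config=cfg)
    untiled = tmrt_timeseries(rasters, met, cfg)
    np.testing.assert_allclose(tiled.values, untiled.values, atol=1e-9)


def test_night_skips_shadow_computation(monkeypatch):
    import heatscape.radiation as rad

    def boom(*a, **k):
        raise AssertionError("cast_shadow called at night")

    monkeypatch.setattr(rad, "cast_shadow", boom)
    rasters = gen_site_rasters(default_demo_site(30.0))
    idx = pd.DatetimeIndex([pd.Timestamp("1995-01-15 00:00")])
    met = MetSeries(pd.DataFrame({"tair": [15.0], "rh": [60.0],
                                  "wind10": [2.0], "swdown": [0.0]}, index=idx))
    da = rad.tmrt_timeseries(rasters, met, RadiationConfig(max_radius=15.0))
    assert np.isfinite(da.values).all()


def test_vegparams_bounds_validated():
    with pytest.raises(Exception):
        VegParams(sw_transmissivity=1.5)
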