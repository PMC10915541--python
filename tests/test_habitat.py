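"""Chlorophyll-gradient habitat scoring, time integration and distances."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import whaletrack as wt
from whaletrack.habitat import (HabitatParams, calibrate_gradient_ramp,
                                chl_gradient, daily_habitat, example_params,
                                integrate_habitat, main_habitat_mask,
                                distance_to_main_habitat)


def raster(values, lons=None, lats=None):
    v = np.asarray(values, dtype=float)
    lons = np.linspace(4.0, 4.0 + (v.shape[-1] - 1) / 24, v.shape[-1]) if lons is None else lons
    lats = np.linspace(41.0, 41.0 + (v.shape[-2] - 1) / 24, v.shape[-2]) if lats is None else lats
    dims = ("lat", "lon") if v.ndim == 2 else ("time", "lat", "lon")
    coords = {"lat": lats, "lon": lons}
    if v.ndim == 3:
        coords["time"] = pd.date_range("2021-05-01", periods=v.shape[0])
    return xr.DataArray(v, coords=coords, dims=dims)


class TestGradient:
    def test_constant_field_zero_interior(self):
        g = chl_gradient(raster(np.full((6, 6), 0.3)))
        assert np.nanmax(g.values) == 0.0
        assert np.isnan(g.values[0, :]).all() and np.isnan(g.values[:, 0]).all()

    def test_linear_field_exact_slope(self):
        # C = a * x_km on a planar grid: |grad| = a at every interior cell
        a = 0.004
        nx = ny = 8
        x_km = np.arange(nx) * 5.0
        field = np.tile(a * x_km, (ny, 1))
        g = chl_gradient(raster(field), planar_spacing_km=5.0)
        interior = g.values[1:-1, 1:-1]
        np.testing.assert_allclose(interior, a, atol=1e-10)

    def test_latitude_scaling_of_eastwest_spacing(self):
        # same lon increment spans less ground at higher latitude, so the
        # same digital field has a LARGER physical gradient
        field = np.tile(np.arange(6, dtype=float), (6, 1))
        low = chl_gradient(raster(field, lats=np.linspace(0, 5 / 24, 6)))
        high = chl_gradient(raster(field, lats=np.linspace(60, 60 + 5 / 24, 6)))
        assert np.nanmean(high.values) > 1.9 * np.nanmean(low.values)

    def test_missing_neighbour_propagates(self):
        f = np.full((6, 6), 0.3)
        f[2, 3] = np.nan
        g = chl_gradient(raster(f))
        assert np.isnan(g.values[2, 2]) and np.isnan(g.values[2, 4])
        assert np.isnan(g.values[1, 3]) and np.isnan(g.values[3, 3])

    def test_rotation_consistency(self):
        rng = np.random.default_rng(1)
        f = rng.random((9, 9))
        g = chl_gradient(raster(f), planar_spacing_km=3.0).values
        g_rot = chl_gradient(raster(np.rot90(f)), planar_spacing_km=3.0).values
        np.testing.assert_allclose(np.rot90(g), g_rot, atol=1e-10)

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            chl_gradient(raster(np.ones((2, 5))))


class TestDailyHabitat:
    def setup_method(self):
        self.params = HabitatParams(chl_min=0.1, chl_max=1.0,
                                    grad_ramp=(0.001, 0.005),
                                    depth_min=90.0, shelf_band=(90.0, 200.0),
                                    shelf_alpha=0.5)

    def score(self, chl, grad, depth):
        c = raster(np.full((3, 3), chl))
        g = raster(np.full((3, 3), grad))
        d = raster(np.full((3, 3), depth))
        return float(daily_habitat(c, g, d, self.params).values[1, 1])

    def test_unfavourable_chlorophyll_excludes(self):
        assert self.score(2.0, 1.0, 2000.0) == 0.0   # bloom too rich
        assert self.score(0.05, 1.0, 2000.0) == 0.0  # oligotrophic

    def test_ramp_midpoint_is_half(self):
        assert self.score(0.5, 0.003, 2000.0) == pytest.approx(0.5)

    def test_saturated_gradient_deep_water_is_one(self):
        assert self.score(0.5, 0.01, 2000.0) == 1.0

    def test_depth_rules(self):
        assert self.score(0.5, 0.01, 50.0) == 0.0      # shallower than minimum
        assert self.score(0.5, 0.01, 150.0) == 0.5     # outer-shelf multiplier
        assert self.score(0.5, 0.01, 250.0) == 1.0

    def test_monotone_in_gradient(self):
        scores = [self.score(0.5, g, 2000.0) for g in np.linspace(0, 0.01, 30)]
        assert (np.diff(scores) >= -1e-12).all()

    def test_exclusions_hold_everywhere(self):
        rng = np.random.default_rng(2)
        chl = raster(rng.uniform(0.0, 2.0, (12, 12)))
        grad = raster(rng.uniform(0.0, 0.01, (12, 12)))
        depth = raster(rng.uniform(0.0, 2500.0, (12, 12)))
        hab = daily_habitat(chl, grad, depth, self.params).values
        bad = ((depth.values < 90.0) | (chl.values < 0.1) | (chl.values > 1.0))
        assert np.nanmax(np.where(bad, hab, 0.0)) == 0.0
        assert np.nanmin(hab) >= 0.0 and np.nanmax(hab) <= 1.0

    def test_misaligned_grids_rejected(self):
        c = raster(np.full((4, 4), 0.5))
        g = raster(np.full((4, 4), 0.003))
        d = raster(np.full((4, 4), 500.0), lons=np.linspace(9, 10, 4))
        with pytest.raises(ValueError, match="misaligned"):
            daily_habitat(c, g, d, self.params)

    def test_missing_chl_propagates(self):
        c = np.full((3, 3), 0.5); c[1, 1] = np.nan
        hab = daily_habitat(raster(c), raster(np.full((3, 3), 0.01)),
                            raster(np.full((3, 3), 2000.0)), self.params)
        assert np.isnan(hab.values[1, 1]) and hab.values[0, 0] == 1.0


class TestIntegration:
    def params(self, smooth=1):
        return HabitatParams(chl_min=0.1, chl_max=1.0, grad_ramp=(0.001, 0.005),
                             smoothing_days=smooth)

    def test_always_favourable_is_hundred_percent(self):
        hab = raster(np.ones((4, 3, 3)))
        freq = integrate_habitat(hab, self.params())
        np.testing.assert_allclose(freq.values, 100.0)

    def test_alternating_days_give_fifty_percent(self):
        days = np.zeros((4, 3, 3))
        days[0] = days[2] = 1.0
        freq = integrate_habitat(raster(days), self.params(smooth=1))
        np.testing.assert_allclose(freq.values, 50.0)

    def test_all_missing_cell_is_missing(self):
        days = np.ones((4, 3, 3))
        days[:, 1, 1] = np.nan
        freq = integrate_habitat(raster(days), self.params())
        assert np.isnan(freq.values[1, 1]) and freq.values[0, 0] == 100.0

    def test_cloudy_days_excluded_from_denominator(self):
        days = np.ones((4, 3, 3))
        days[0, 0, 0] = np.nan  # cloud: 3 valid favourable days of 3
        freq = integrate_habitat(raster(days), self.params(smooth=1))
        assert freq.values[0, 0] == pytest.approx(100.0)

    def test_mean_mode(self):
        days = np.full((4, 3, 3), 0.4)
        freq = integrate_habitat(raster(days), self.params(smooth=1), mode="mean")
        np.testing.assert_allclose(freq.values, 40.0)


class TestMainHabitatMask:
    def test_strict_threshold(self):
        freq = raster(np.array([[31.0, 30.0], [29.0, 50.0]]))
        mask = main_habitat_mask(freq, 30.0)
        assert bool(mask.values[0, 0]) and not bool(mask.values[0, 1])
        assert not bool(mask.values[1, 0]) and bool(mask.values[1, 1])

    def test_empty_input_empty_mask(self):
        freq = raster(np.full((3, 3), np.nan))
        assert int(main_habitat_mask(freq).sum()) == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        freq = raster(rng.uniform(0, 100, (10, 10)))
        cells = [int(main_habitat_mask(freq, t).sum()) for t in (10, 30, 50, 70)]
        assert cells == sorted(cells, reverse=True)

    def test_main_habitat_concentrates_on_front(self):
        spec = wt.simulate.FrontFieldSpec(n_days=6, noise_sd=0.01,
                                          drift_km_per_day=1.0, seed=4)
        chl = wt.simulate.simulate_chl_series(spec)
        depth = wt.simulate.simulate_bathymetry(spec.grid,
                                                {"kind": "constant", "depth": 2000.0})
        # favourable chlorophyll window centred inside the front transition
        params = HabitatParams(chl_min=spec.chl_low + 0.1,
                               chl_max=spec.chl_high - 0.1,
                               grad_ramp=(0.005, 0.02), smoothing_days=3)
        grad = chl_gradient(chl)
        hab = daily_habitat(chl, grad, depth, params)
        mask = main_habitat_mask(integrate_habitat(hab, params))
        lon2d, lat2d = np.meshgrid(chl["lon"].values, chl["lat"].values)
        from whaletrack.simulate import _cross_track_km
        d_first = _cross_track_km(spec, lon2d, lat2d, 0)
        d_last = _cross_track_km(spec, lon2d, lat2d, spec.n_days - 1)
        band = (np.minimum(np.abs(d_first), np.abs(d_last)) <= spec.front_width_km) \
            | ((d_first < 0) & (d_last > 0)) | ((d_first > 0) & (d_last < 0))
        m = mask.values
        assert m.sum() > 20
        assert (m & band).sum() / m.sum() >= 0.90


class TestDistances:
    def mask_at(self, cells):
        m = np.zeros((8, 8), dtype=bool)
        for i, j in cells:
            m[i, j] = True
        lons = 4.0 + np.arange(8) / 24.0
        lats = 41.75 + np.arange(8) / 24.0
        return xr.DataArray(m, coords={"lat": lats, "lon": lons},
                            dims=("lat", "lon"))

    def test_inside_cell_distance_zero(self):
        mask = self.mask_at([(3, 3)])
        pos = pd.DataFrame({"lon": [float(mask["lon"][3])],
                            "lat": [float(mask["lat"][3])]})
        d, frac = distance_to_main_habitat(pos, mask)
        assert d[0] == 0.0 and frac == 1.0

    def test_one_cell_east_at_42_degrees(self):
        # 1/24 deg of longitude at 42N is ~3.44 km of ground distance
        mask = self.mask_at([(6, 3)])
        lat = float(mask["lat"][6])
        assert lat == pytest.approx(42.0)
        pos = pd.DataFrame({"lon": [float(mask["lon"][4])], "lat": [lat]})
        d, _ = distance_to_main_habitat(pos, mask)
        expect = wt.geo.EARTH_RADIUS_KM * np.cos(np.radians(42.0)) * np.radians(1 / 24)
        assert d[0] == pytest.approx(expect, abs=0.01)
        assert d[0] == pytest.approx(3.44, abs=0.02)

    def test_fraction_within_nondecreasing_in_distance(self):
        mask = self.mask_at([(0, 0)])
        rng = np.random.default_rng(5)
        pos = pd.DataFrame({"lon": 4.0 + rng.uniform(0, 0.3, 40),
                            "lat": 41.75 + rng.uniform(0, 0.3, 40)})
        fracs = [distance_to_main_habitat(pos, mask, within_km=d)[1]
                 for d in (1.0, 5.0, 20.0, 100.0)]
        assert fracs == sorted(fracs)

    def test_empty_mask_warns_infinite(self):
        mask = self.mask_at([])
        pos = pd.DataFrame({"lon": [4.1], "lat": [41.9]})
        with pytest.warns(UserWarning, match="empty"):
            d, frac = distance_to_main_habitat(pos, mask)
        assert np.isinf(d[0]) and frac == 0.0


class TestCalibration:
    def test_uniform_presence_quantiles(self):
        g = np.linspace(0.001, 0.01, 10_001)
        g0, g1, cdf = calibrate_gradient_ramp(g)
        assert g0 == pytest.approx(0.00145, abs=1e-5)
        assert g1 == pytest.approx(0.00955, abs=1e-5)
        assert (cdf["cum_fraction"].iloc[-1] == 1.0)

    def test_extreme_quantiles_give_min_max(self):
        g = np.linspace(0.002, 0.008, 100)
        g0, g1, _ = calibrate_gradient_ramp(g, quantiles=(0.0, 1.0))
        assert g0 == 0.002 and g1 == 0.008

    def test_degenerate_presence_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_gradient_ramp(np.full(100, 0.004))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 30"):
            calibrate_gradient_ramp(np.linspace(0, 1, 10))

    def test_example_params_validate(self):
        assert example_params().main_threshold == 30.0
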