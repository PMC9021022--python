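"""Tests of habitat diagnostics: maps, series, overlap, site NPP, presence."""

import numpy as np
import pytest
import xarray as xr
from hypothesis import given, settings, strategies as st

import paleohabitat as ph
from paleohabitat.analysis import site_npp_frame

from conftest import make_record


def H_field(values, grid, time_ka):
    return xr.DataArray(
        np.asarray(values, dtype=float),
        dims=("time", "lat", "lon"),
        coords={"time": time_ka, **grid.coords()},
    )


GRID = ph.GridSpec.regular(0, 24, -12, 12, 3)
TIME = np.arange(100, 0, -1, dtype=float)


class TestTimeMean:
    def test_constant_in_time_unchanged(self, rng):
        base = rng.uniform(size=GRID.shape)
        H = H_field(np.repeat(base[None], 100, axis=0), GRID, TIME)
        out = ph.time_mean_map(H, (30.0, 70.0))
        assert np.allclose(out.values, base)

    def test_single_slice_window(self, rng):
        cube = rng.uniform(size=(100, *GRID.shape))
        H = H_field(cube, GRID, TIME)
        out = ph.time_mean_map(H, (50.0, 50.0))
        assert np.allclose(out.values, cube[50])

    def test_alternating_field_averages_to_half(self):
        cube = np.zeros((100, *GRID.shape))
        cube[::2] = 1.0
        out = ph.time_mean_map(H_field(cube, GRID, TIME))
        assert np.allclose(out.values, 0.5)

    def test_empty_window_rejected(self, rng):
        H = H_field(rng.uniform(size=(100, *GRID.shape)), GRID, TIME)
        with pytest.raises(ValueError, match="no slices"):
            ph.time_mean_map(H, (300.0, 400.0))


class TestRegionalSeries:
    def test_uniform_field_constant_series(self):
        H = H_field(np.full((100, *GRID.shape), 0.3), GRID, TIME)
        out = ph.regional_series(H, ph.RegionalBox(10.5, 1.5, width=4))
        assert np.allclose(out.values, 0.3)

    def test_single_cell_box(self, rng):
        cube = rng.uniform(size=(100, *GRID.shape))
        H = H_field(cube, GRID, TIME)
        lon = float(GRID.lon_centers[2])
        lat = float(GRID.lat_centers[3])
        out = ph.regional_series(H, ph.RegionalBox(lon, lat, width=2.9))
        assert np.allclose(out.values, cube[:, 3, 2])

    def test_forcing_period_survives_regional_averaging(self):
        """Spectral peak of a 25-ka sinusoidal suitability series stays at
        25 ka after box averaging (periodogram oracle)."""
        t = np.arange(200, 0, -1, dtype=float)
        series = 0.5 + 0.3 * np.sin(2 * np.pi * t / 25.0)
        cube = np.broadcast_to(series[:, None, None], (200, *GRID.shape)).copy()
        out = ph.regional_series(H_field(cube, GRID, t), ph.RegionalBox(10.0, 0.0))
        x = out.values - out.values.mean()
        power = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(200, d=1.0)
        assert freqs[np.argmax(power[1:]) + 1] == pytest.approx(1 / 25.0, abs=1 / 200.0)

    def test_no_land_in_box_rejected(self):
        mask = np.ones(GRID.shape, dtype=bool)
        mask[:, :2] = False
        grid = ph.GridSpec.regular(0, 24, -12, 12, 3, land_mask=mask)
        cube = np.full((10, *grid.shape), 0.4)
        H = H_field(cube, grid, np.arange(10, 0, -1, dtype=float)).where(grid.land_da())
        with pytest.raises(ValueError, match="no land"):
            ph.regional_series(H, ph.RegionalBox(1.5, 0.0, width=3))


class TestOverlap:
    def _pair(self, rng):
        a = rng.uniform(size=(60, *GRID.shape))
        b = rng.uniform(size=(60, *GRID.shape))
        t = np.arange(60, 0, -1, dtype=float)
        return H_field(a, GRID, t), H_field(b, GRID, t)

    def test_zero_field_annihilates(self, rng):
        H1, H2 = self._pair(rng)
        out = ph.overlap_product(H1, H2 * 0.0)
        assert np.allclose(out.values, 0.0)

    def test_self_product_is_square(self, rng):
        H1, _ = self._pair(rng)
        assert np.allclose(ph.overlap_product(H1, H1).values, H1.values**2)

    def test_uniform_product_hovmoeller(self):
        t = np.arange(60, 0, -1, dtype=float)
        H1 = H_field(np.full((60, *GRID.shape), 0.5), GRID, t)
        H2 = H_field(np.full((60, *GRID.shape), 0.4), GRID, t)
        hov = ph.zonal_mean(ph.overlap_product(H1, H2))
        assert hov.dims == ("time", "lat")
        assert np.allclose(hov.values, 0.2)

    def test_product_bounded_unit_interval(self, rng):
        H1, H2 = self._pair(rng)
        out = ph.overlap_product(H1, H2)
        assert ((out.values >= 0) & (out.values <= 1)).all()

    def test_zonal_mean_of_latitude_constant_field(self):
        t = np.arange(10, 0, -1, dtype=float)
        profile = np.linspace(0, 1, GRID.shape[0])
        cube = np.broadcast_to(profile[None, :, None], (10, *GRID.shape)).copy()
        out = ph.zonal_mean(H_field(cube, GRID, t))
        assert np.allclose(out.values, profile[None, :])

    def test_covariance_identities(self, rng):
        H1, _ = self._pair(rng)
        const = H_field(np.full((60, *GRID.shape), 0.7), GRID, H1["time"].values)
        assert np.allclose(ph.overlap_covariance(H1, const).values, 0.0, atol=1e-12)
        var = ph.overlap_covariance(H1, H1)
        assert np.allclose(var.values, H1.values.var(axis=0, ddof=1), atol=1e-12)
        anti = ph.overlap_covariance(H1, 1.0 - H1)
        assert np.allclose(anti.values, -var.values, atol=1e-12)
        # [0,1]-valued fields bound the covariance by 1/4
        assert (np.abs(var.values) <= 0.25 + 1e-12).all()

    def test_grid_mismatch_rejected(self, rng):
        H1, H2 = self._pair(rng)
        with pytest.raises(ValueError, match="co-registered"):
            ph.overlap_covariance(H1, H2.isel(lon=slice(0, 4)))


class TestHaversine:
    def test_one_degree_longitude_near_equator(self):
        # 1 deg of longitude at 4 N is ~110.9 km on a 6,371-km sphere
        d = ph.haversine_km(36.0, 4.0, 37.0, 4.0)
        assert d == pytest.approx(110.9, abs=0.1)

    def test_against_law_of_cosines_oracle(self, rng):
        for _ in range(50):
            lon1, lon2 = rng.uniform(-180, 180, 2)
            lat1, lat2 = rng.uniform(-89, 89, 2)
            l1, l2, p1, p2 = map(np.radians, (lon1, lon2, lat1, lat2))
            cosd = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(l2 - l1)
            expected = 6371.0 * np.arccos(np.clip(cosd, -1, 1))
            assert ph.haversine_km(lon1, lat1, lon2, lat2) == pytest.approx(
                expected, abs=1e-6
            )

    @given(
        lon1=st.floats(-180, 180), lat1=st.floats(-90, 90),
        lon2=st.floats(-180, 180), lat2=st.floats(-90, 90),
        lon3=st.floats(-180, 180), lat3=st.floats(-90, 90),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_symmetry_and_triangle_inequality(self, lon1, lat1, lon2, lat2, lon3, lat3):
        d12 = ph.haversine_km(lon1, lat1, lon2, lat2)
        d21 = ph.haversine_km(lon2, lat2, lon1, lat1)
        assert d12 == pytest.approx(d21, rel=1e-12, abs=1e-9)
        d13 = ph.haversine_km(lon1, lat1, lon3, lat3)
        d23 = ph.haversine_km(lon2, lat2, lon3, lat3)
        assert d12 <= d13 + d23 + 1e-6


class TestSiteNPP:
    # grid covering the east-African reference point (4 N, 36 E)
    EA_GRID = ph.GridSpec.regular(24, 48, -8, 16, 3)

    def _npp_field(self, value=300.0):
        cube = np.full((50, *self.EA_GRID.shape), value)
        t = np.arange(50, 0, -1, dtype=float)
        return H_field(cube, self.EA_GRID, t)

    def test_reference_site_distance_zero(self):
        npp = self._npp_field()
        recs = [make_record(lon=36.0, lat=4.0, age=25.0, dt=0.0)]
        pts = ph.npp_at_sites(recs, npp)
        assert pts[0].distance_km == 0.0
        assert pts[0].vicinity_npp == pytest.approx(300.0)

    def test_uniform_field_vicinity_mean(self, rng):
        npp = self._npp_field(412.5)
        recs = [
            make_record(site=f"s{i}", lon=float(rng.uniform(27, 45)),
                        lat=float(rng.uniform(-5, 13)), age=float(rng.uniform(5, 45)), dt=1.0)
            for i in range(10)
        ]
        pts = ph.npp_at_sites(recs, npp)
        frame = site_npp_frame(pts)
        assert np.allclose(frame["vicinity_npp"], 412.5)
        assert (frame["distance_km"] >= 0).all()

    def test_out_of_axis_record_skipped(self):
        npp = self._npp_field()
        recs = [
            make_record(site="ok", lon=36.0, lat=0.0, age=25.0),
            make_record(site="too_old", lon=36.0, lat=0.0, age=900.0),
        ]
        pts = ph.npp_at_sites(recs, npp)
        assert [p.site_name for p in pts] == ["ok"]


class TestPresence:
    def test_zero_uncertainty_unit_spike(self):
        t = np.arange(100, 0, -1, dtype=float)
        curve = ph.presence_probability([make_record(age=40.0, dt=0.0)], t)
        assert curve.values.max() == 1.0
        assert curve.values.sum() == 1.0
        assert curve.values[np.argmin(np.abs(t - 40.0))] == 1.0

    def test_uniform_kernel_plateau(self):
        t = np.arange(100, 0, -1, dtype=float)
        curve = ph.presence_probability([make_record(age=50.0, dt=10.0)], t)
        inside = (t >= 40.0) & (t <= 60.0)
        assert np.allclose(curve.values[inside], 1.0)
        assert np.allclose(curve.values[(t < 38) | (t > 62)], 0.0)

    def test_two_disjoint_records_two_plateaus(self):
        """Superposition of two non-overlapping kernels, each normalised
        below or at 1 (direct summation oracle)."""
        t = np.arange(200, 0, -1, dtype=float)
        recs = [make_record(age=50.0, dt=5.0), make_record(age=150.0, dt=10.0)]
        curve = ph.presence_probability(recs, t)
        # narrower kernel is denser: plateau 1 after normalisation
        assert np.allclose(curve.values[(t >= 45) & (t <= 55)], 1.0)
        assert np.allclose(
            curve.values[(t >= 140) & (t <= 160)], (1 / 20) / (1 / 10)
        )
        assert curve.values.max() == 1.0
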