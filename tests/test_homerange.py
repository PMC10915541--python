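"""Kernel UDs, isopleths and overlap indices."""

import numpy as np
import pandas as pd
import pytest

from whaletrack.homerange import (UDGrid, bhattacharyya, href_bandwidth,
                                  isopleth, kernel_ud, make_grid,
                                  percent_overlap, pooled_ud)


class TestHref:
    def test_four_points_unit_sd(self):
        # sd_x = sd_y = 1000 m  =>  h = 1000 * 4^(-1/6)
        pts = np.array([[-1000, -1000], [1000, 1000], [-1000, 1000], [1000, -1000]],
                       dtype=float) * np.sqrt(3) / 2  # sd(ddof=1) = 1000
        sd = pts.std(axis=0, ddof=1)
        np.testing.assert_allclose(sd, 1000.0)
        assert href_bandwidth(pts) == pytest.approx(1000.0 * 4 ** (-1 / 6), abs=1e-6)
        assert href_bandwidth(pts) == pytest.approx(793.70, abs=0.01)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 5000, (40, 2))
        assert href_bandwidth(2 * pts) == pytest.approx(2 * href_bandwidth(pts), rel=1e-12)

    def test_decreasing_in_n_at_fixed_spread(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 5000, (50, 2))
        hs = []
        for reps in (1, 4, 16):
            pts = np.tile(base, (reps, 1))  # same spread, larger n
            hs.append(href_bandwidth(pts))
        assert hs[0] > hs[1] > hs[2]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            href_bandwidth(np.array([[0.0, 0.0]]))
        with pytest.raises(ValueError):
            href_bandwidth(np.zeros((5, 2)))


class TestKernelUD:
    def test_mass_sums_to_one(self):
        rng = np.random.default_rng(3)
        ud = kernel_ud(rng.normal(0, 20000, (100, 2)), cell_size=10_000.0)
        assert ud.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_point_at_cell_center_matches_gaussian(self):
        h = 8000.0
        grid = make_grid(np.array([[0.0, 0.0]] * 2), cell_size=10_000.0, h=h)
        ud = kernel_ud(np.array([[5000.0, 5000.0]]), grid=grid, h=h)
        cx, cy = ud.cell_centers()
        j = int(np.argmin(np.abs(cx - 5000.0)))
        i = int(np.argmin(np.abs(cy - 5000.0)))
        assert ud.mass[i, j] == ud.mass.max()
        # closed-form Gaussian mass per cell (cell area x density), up to
        # the discretisation of the cell integral by its centre value
        expect = np.exp(0.0) / (2 * np.pi * h**2) * 10_000.0**2
        assert ud.mass[i, j] == pytest.approx(expect, rel=0.05)

    def test_mirrored_points_give_mirrored_ud(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 15000, (60, 2))
        h = href_bandwidth(pts)
        lim = 80_000.0
        grid = UDGrid(x0=-lim, y0=-lim, cell_size=10_000.0,
                      mass=np.zeros((16, 16)))
        ud = kernel_ud(pts, grid=grid, h=h)
        mirrored = kernel_ud(pts * np.array([-1.0, 1.0]), grid=grid, h=h)
        np.testing.assert_allclose(ud.mass, mirrored.mass[:, ::-1], atol=1e-15)

    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 20000, (50, 2))
        ud = kernel_ud(pts, cell_size=10_000.0)
        cx, cy = ud.cell_centers()
        dens = np.zeros_like(ud.mass)
        for px, py in pts:  # double loop oracle
            dens += np.exp(-(((cx[None, :] - px) ** 2 + (cy[:, None] - py) ** 2)
                             / (2 * ud.h**2)))
        dens /= len(pts) * 2 * np.pi * ud.h**2
        mass = dens * ud.cell_size**2
        mass /= mass.sum()
        np.testing.assert_allclose(ud.mass, mass, atol=1e-12)

    def test_undersized_grid_rejected(self):
        pts = np.array([[0.0, 0.0], [60_000.0, 0.0]])
        tight = UDGrid(x0=-5_000.0, y0=-5_000.0, cell_size=10_000.0,
                       mass=np.zeros((2, 8)))
        with pytest.raises(ValueError, match="margin"):
            kernel_ud(pts, grid=tight, h=8000.0)


class TestIsopleth:
    def hand_ud(self):
        mass = np.array([[0.40, 0.30, 0.10],
                         [0.05, 0.05, 0.04],
                         [0.03, 0.02, 0.01]])
        return UDGrid(x0=0.0, y0=0.0, cell_size=10_000.0, mass=mass)

    def test_fifty_percent_region_is_two_cells(self):
        r = isopleth(self.hand_ud(), 0.5)
        assert len(r.cell_indices) == 2
        assert r.contained_mass == pytest.approx(0.70)
        assert r.area_km2 == 200.0

    def test_level_one_takes_all_nonzero_cells(self):
        ud = self.hand_ud()
        ud.mass[2, 2] = 0.0
        ud.mass[0, 0] += 0.01
        r = isopleth(ud, 1.0)
        assert len(r.cell_indices) == 8

    def test_region_is_minimal(self):
        ud = self.hand_ud()
        r = isopleth(ud, 0.5)
        # dropping the least-dense member must fall below the level
        masses = np.sort(ud.mass.ravel()[r.cell_indices])
        assert r.contained_mass - masses[0] < 0.5

    def test_core_nested_in_home_range(self):
        rng = np.random.default_rng(6)
        ud = kernel_ud(rng.normal(0, 25000, (200, 2)), cell_size=10_000.0)
        r50 = isopleth(ud, 0.5)
        r95 = isopleth(ud, 0.95)
        assert r50.area_km2 <= r95.area_km2
        assert set(r50.cell_indices) <= set(r95.cell_indices)

    def test_time_fraction_interpretation(self):
        # equidistant positions: 70% of the time at one haunt, 30% at
        # another far away; the 50% core captures only the first haunt
        pts = np.vstack([np.tile([0.0, 0.0], (70, 1)),
                         np.tile([200_000.0, 0.0], (30, 1))])
        pts += np.random.default_rng(7).normal(0, 2000, pts.shape)
        ud = kernel_ud(pts, h=3000.0, cell_size=10_000.0)
        r = isopleth(ud, 0.5)
        cx, cy = ud.cell_centers()
        cols = r.cell_indices % ud.nx
        assert (cx[cols] < 100_000.0).all()
        assert r.contained_mass < 0.75


class TestOverlapIndices:
    def grid_pair(self):
        lim = 60_000.0
        grid = UDGrid(x0=-lim, y0=-lim, cell_size=10_000.0, mass=np.zeros((12, 12)))
        rng = np.random.default_rng(8)
        a = kernel_ud(rng.normal(-15000, 9000, (80, 2)), grid=grid, h=6000.0)
        b = kernel_ud(rng.normal(15000, 9000, (80, 2)), grid=grid, h=6000.0)
        return a, b

    def test_identical_regions_full_overlap(self):
        a, _ = self.grid_pair()
        r = isopleth(a, 0.95)
        assert percent_overlap(r, r) == pytest.approx(1.0)

    def test_disjoint_regions_zero_overlap(self):
        a, b = self.grid_pair()
        far = UDGrid(x0=a.x0 + 1e7, y0=a.y0, cell_size=a.cell_size, mass=b.mass)
        assert percent_overlap(isopleth(a, 0.5), isopleth(far, 0.5)) == 0.0

    def test_half_area_intersection(self):
        m1 = np.zeros((1, 4)); m1[0, :2] = 0.5       # cells 0,1
        m2 = np.zeros((1, 4)); m2[0, 1:3] = 0.5      # cells 1,2
        g1 = UDGrid(x0=0, y0=0, cell_size=10_000.0, mass=m1)
        g2 = UDGrid(x0=0, y0=0, cell_size=10_000.0, mass=m2)
        r1 = isopleth(g1, 1.0)
        r2 = isopleth(g2, 1.0)
        assert percent_overlap(r1, r2) == pytest.approx(0.5)

    def test_bhattacharyya_self_equals_contained_mass(self):
        a, _ = self.grid_pair()
        for level in (0.95, 0.50):
            r = isopleth(a, level)
            ba = bhattacharyya(a, a, level)
            assert ba == pytest.approx(r.contained_mass, abs=1e-12)
            assert ba <= level + a.mass.max()

    def test_bhattacharyya_symmetric(self):
        a, b = self.grid_pair()
        assert bhattacharyya(a, b, 0.95) == pytest.approx(
            bhattacharyya(b, a, 0.95), abs=1e-12)

    def test_two_cell_uniform_full_affinity(self):
        m = np.array([[0.5, 0.5]])
        g = UDGrid(x0=0, y0=0, cell_size=10_000.0, mass=m)
        assert bhattacharyya(g, g, 1.0) == pytest.approx(1.0)

    def test_disjoint_supports_zero_affinity(self):
        m1 = np.array([[1.0, 0.0]]); m2 = np.array([[0.0, 1.0]])
        g1 = UDGrid(x0=0, y0=0, cell_size=10_000.0, mass=m1)
        g2 = UDGrid(x0=0, y0=0, cell_size=10_000.0, mass=m2)
        assert bhattacharyya(g1, g2, 1.0) == 0.0

    def test_grid_mismatch_rejected(self):
        a, b = self.grid_pair()
        shifted = UDGrid(x0=a.x0 + 1.0, y0=a.y0, cell_size=a.cell_size, mass=b.mass)
        with pytest.raises(ValueError, match="identical grid"):
            bhattacharyya(a, shifted, 0.95)


class TestPooledUD:
    def tracks(self):
        rng = np.random.default_rng(9)
        rows = []
        for aid, year, centre in (("a", 2021, -20000), ("b", 2021, 20000),
                                  ("c", 2022, 0)):
            xy = rng.normal(centre, 8000, (50, 2))
            rows.append(pd.DataFrame({"animal_id": aid, "year": year,
                                      "x": xy[:, 0], "y": xy[:, 1]}))
        return pd.concat(rows, ignore_index=True)

    def test_single_animal_group_equals_individual_ud(self):
        tracks = self.tracks()
        uds = pooled_ud(tracks, "year")
        solo = tracks[tracks["animal_id"] == "c"]
        direct = kernel_ud(solo[["x", "y"]].to_numpy(), cell_size=10_000.0)
        np.testing.assert_allclose(uds[2022].mass, direct.mass, atol=1e-15)

    def test_duplicated_track_leaves_density_shape_unchanged(self):
        solo = self.tracks().query("animal_id == 'c'")
        pts = solo[["x", "y"]].to_numpy()
        h = href_bandwidth(pts)
        grid = make_grid(pts, cell_size=10_000.0, h=h)
        once = kernel_ud(pts, grid=grid, h=h)
        twice = kernel_ud(np.vstack([pts, pts]), grid=grid, h=h)
        np.testing.assert_allclose(once.mass, twice.mass, atol=1e-15)

    def test_doubling_n_shrinks_href_by_sixth_root(self):
        # duplicating the point set doubles n at (essentially) fixed spread;
        # the ddof=1 sd changes by O(1/n), hence the loose-ish tolerance
        pts = np.random.default_rng(10).normal(0, 10000, (2000, 2))
        h1 = href_bandwidth(pts)
        h2 = href_bandwidth(np.vstack([pts, pts]))
        assert h2 / h1 == pytest.approx(2 ** (-1 / 6), rel=1e-3)
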