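"""Kernel home ranges: bandwidth, gridded KDE, isopleths, annual summary."""

from datetime import date

import numpy as np
import pytest

from hydromove.homerange import (
    DensityGrid,
    annual_ranges,
    href_bandwidth,
    isopleth_area_km2,
    kde_at_points,
    kde_grid,
    range_summary,
)
from hydromove.projection import LocalProjection
from hydromove.tracking import AgeWindow

from conftest import make_trajectory


class TestHref:
    def test_closed_form(self):
        # sd_x = sd_y = 1000 m, n = 64: h = 1000 * 64^(-1/6) = 500 m exactly
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 1, size=(64, 2))
        pts = (pts - pts.mean(axis=0)) / pts.std(axis=0, ddof=1) * 1000.0
        assert href_bandwidth(pts) == pytest.approx(500.0, abs=1e-9)

    def test_scales_linearly_with_spread(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 800, size=(40, 2))
        assert href_bandwidth(2 * pts) == pytest.approx(2 * href_bandwidth(pts), rel=1e-12)

    def test_identical_points_error(self):
        with pytest.raises(ValueError, match="fixed bandwidth"):
            href_bandwidth(np.zeros((10, 2)))

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            href_bandwidth(np.random.default_rng(2).normal(size=(4, 2)))


class TestKdeGrid:
    def test_total_mass_is_one(self):
        rng = np.random.default_rng(3)
        grid = kde_grid(rng.normal(0, 2000, size=(50, 2)), h=800.0, cell_m=250.0)
        assert grid.total_mass == pytest.approx(1.0, abs=1e-3)

    def test_two_far_clusters_split_mass_evenly(self):
        pts = np.array([[0.0, 0.0], [50000.0, 0.0]])
        grid = kde_grid(pts, h=500.0, cell_m=100.0)
        mass = grid.density * grid.cell_area_m2
        left = mass[:, grid.x_centers < 25000.0].sum()
        assert left == pytest.approx(0.5, abs=0.01)

    def test_grid_matches_brute_force_kernel_sum(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 1500, size=(200, 2))
        h = 700.0
        grid = kde_grid(pts, h=h, cell_m=500.0)
        xs, ys = grid.x_centers, grid.y_centers
        norm = grid.total_mass  # pre-normalisation constant folded in
        # brute-force python-loop oracle at a few cells
        for i, j in [(0, 0), (3, 7), (10, 2), (grid.density.shape[0] - 1, 5)]:
            acc = 0.0
            for px, py in pts:
                acc += np.exp(-0.5 * ((xs[j] - px) ** 2 + (ys[i] - py) ** 2) / h**2)
            acc /= 2.0 * np.pi * h * h * len(pts)
            expected = kde_at_points(pts, h, [[xs[j], ys[i]]])[0]
            assert expected == pytest.approx(acc, rel=1e-12, abs=1e-300)

    def test_point_density_matches_separable_grid(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 1500, size=(80, 2))
        h = 600.0
        grid = kde_grid(pts, h=h, cell_m=500.0)
        xx, yy = np.meshgrid(grid.x_centers, grid.y_centers)
        exact = kde_at_points(pts, h, np.column_stack([xx.ravel(), yy.ravel()]))
        exact = exact.reshape(grid.density.shape)
        exact /= exact.sum() * grid.cell_area_m2
        np.testing.assert_allclose(grid.density, exact, rtol=1e-10)

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            kde_grid(np.zeros((5, 2)), h=0.0)


class TestIsopleth:
    def test_single_point_gaussian_closed_form(self):
        h = 1000.0
        grid = kde_grid(np.array([[0.0, 0.0]]), h=h, cell_m=100.0)
        # 95% highest-density region of a circular normal: radius chi2(2) 0.95
        expected_km2 = np.pi * (2.4477 * h) ** 2 / 1e6
        assert isopleth_area_km2(grid, 0.95) == pytest.approx(expected_km2, rel=0.05)

    def test_uniform_grid_minimal_set(self):
        dens = np.full((10, 10), 1.0)
        dens /= dens.sum() * 500.0**2
        grid = DensityGrid(density=dens, x_min=0.0, y_max=5000.0, cell=500.0)
        assert isopleth_area_km2(grid, 0.5) == pytest.approx(50 * 0.25)

    def test_monotone_in_level(self):
        rng = np.random.default_rng(6)
        grid = kde_grid(rng.normal(0, 3000, size=(60, 2)), h=900.0, cell_m=300.0)
        areas = [isopleth_area_km2(grid, lv) for lv in (0.2, 0.5, 0.8, 0.95)]
        assert areas == sorted(areas)
        assert isopleth_area_km2(grid, 0.95) >= isopleth_area_km2(grid, 0.50)

    def test_point_mass_single_cell(self):
        dens = np.zeros((5, 5))
        dens[2, 2] = 1.0 / 500.0**2
        grid = DensityGrid(density=dens, x_min=0.0, y_max=2500.0, cell=500.0)
        for lv in (0.05, 0.5, 0.95):
            assert isopleth_area_km2(grid, lv) == pytest.approx(0.25)

    def test_invalid_level(self):
        grid = DensityGrid(np.full((2, 2), 1.0 / 1e6), 0.0, 1000.0, 500.0)
        with pytest.raises(ValueError):
            isopleth_area_km2(grid, 1.5)

    def test_grid_convergence_on_smooth_data(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 2500, size=(300, 2))
        h = 1200.0
        a_coarse = isopleth_area_km2(kde_grid(pts, h, cell_m=500.0), 0.95)
        a_fine = isopleth_area_km2(kde_grid(pts, h, cell_m=250.0), 0.95)
        assert abs(a_fine - a_coarse) / a_fine < 0.03


class TestAnnualRanges:
    def _yearlong_traj(self, patches, n_days=120, seed=8):
        rng = np.random.default_rng(seed)
        proj = LocalProjection(30.0, -12.0)
        rows = []
        d0 = date(2014, 6, 1)
        for k in range(n_days):
            d = date.fromordinal(d0.toordinal() + k)
            cx, cy = patches[k % len(patches)]
            for h in (8, 12, 16):
                lon, lat = proj.to_lonlat(cx + rng.normal(0, 400), cy + rng.normal(0, 400))[0]
                rows.append((d.year, d.month, d.day, h, lon, lat))
        return make_trajectory("A", rows)

    def test_two_patch_range_covers_both(self):
        traj = self._yearlong_traj([(0.0, 0.0), (12000.0, 0.0)])
        wins = [AgeWindow("A", "adult", date(2014, 1, 1), date(2015, 12, 31))]
        (hr,) = annual_ranges(traj, wins, keep_grids=True)
        assert hr.age_class == "adult"
        # the 95% region must span both patches, 12 km apart in x
        grid = hr.grid
        mass = grid.density * grid.cell_area_m2
        order = np.argsort(-mass.ravel(), kind="stable")
        cum = np.cumsum(mass.ravel()[order])
        cutoff = mass.ravel()[order[np.searchsorted(cum, 0.95 * cum[-1])]]
        region = mass >= cutoff
        xs = np.broadcast_to(grid.x_centers, mass.shape)[region]
        assert xs.max() - xs.min() >= 10_000.0
        # and each half of the grid holds roughly half of the region's mass
        mid = (xs.max() + xs.min()) / 2.0
        left = mass[region & (np.broadcast_to(grid.x_centers, mass.shape) < mid)].sum()
        assert 0.3 <= left / mass[region].sum() <= 0.7

    def test_deterministic_across_identical_seasons(self):
        traj = self._yearlong_traj([(0.0, 0.0), (5000.0, 3000.0)])
        shifted = traj.fixes.copy()
        shifted["timestamp"] = shifted["timestamp"] + np.timedelta64(365, "D")
        both = make_trajectory("A", [])
        import pandas as pd

        both.fixes = pd.concat([traj.fixes, shifted], ignore_index=True)
        wins = [AgeWindow("A", "adult", date(2014, 1, 1), date(2016, 12, 31))]
        r1, r2 = annual_ranges(both, wins)
        assert r1.area_km2_95 == pytest.approx(r2.area_km2_95, rel=1e-4)
        assert r1.area_km2_50 == pytest.approx(r2.area_km2_50, rel=1e-4)

    def test_sparse_season_skipped(self):
        traj = self._yearlong_traj([(0.0, 0.0)], n_days=5)
        wins = [AgeWindow("A", "adult", date(2014, 1, 1), date(2015, 12, 31))]
        assert annual_ranges(traj, wins, min_fixes=30) == []

    def test_class_mean_arithmetic(self):
        from hydromove.homerange import KernelHomeRange

        ranges = [
            KernelHomeRange("A", 2014, "adult", 100, 500.0, 1000.0, 200.0),
            KernelHomeRange("B", 2014, "adult", 100, 500.0, 2000.0, 300.0),
        ]
        row = range_summary(ranges).iloc[0]
        assert row["mean_km2_95"] == pytest.approx(1500.0)
        assert row["sd_km2_95"] == pytest.approx(707.10678, rel=1e-6)
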