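import copy

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import sealhab as sh
from sealhab.gam import fit_binomial_gam
from sealhab.overlap import PredictionSurface

from oracles import overlap_by_haul_loop


def intercept_only_model(p=0.6):
    rng = np.random.default_rng(0)
    y = (rng.random(600) < p).astype(int)
    return fit_binomial_gam(pd.DataFrame({"label": y}), [])


def uniform_surface(domain, value):
    probs = np.where(domain.mask, value, np.nan)
    return PredictionSurface(domain=domain, probabilities=probs)


def random_hauls(domain, n, seed):
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(domain.mask)
    i = rng.integers(len(rows), size=n)
    g = domain.grid
    return pd.DataFrame({
        "date": pd.Timestamp("2003-06-01"),
        "lon": g.lon0 + g.cell_deg * (cols[i] + rng.uniform(0.01, 0.99, n)),
        "lat": g.lat0 + g.cell_deg * (rows[i] + rng.uniform(0.01, 0.99, n)),
        "catch_t": rng.lognormal(2.5, 0.8, n)})


class TestPredictSurface:
    def test_intercept_only_gives_constant_probability(self, world, domain):
        m = intercept_only_model()
        surf = sh.predict_surface(m, world.stack, world.colonies, domain)
        vals = surf.probabilities[domain.mask]
        vals = vals[np.isfinite(vals)]
        np.testing.assert_allclose(vals, expit(m.intercept), rtol=1e-12)
        assert np.isnan(surf.probabilities[~domain.mask]).all()

    def test_missing_covariate_cell_is_blank(self, world, domain):
        stack = copy.deepcopy(world.stack)
        rows, cols = np.nonzero(domain.mask)
        r0, c0 = rows[10], cols[10]
        for m in stack.months:
            stack.dynamic["SST"][m][r0, c0] = np.nan
        rng = np.random.default_rng(1)
        z = rng.normal(0, 1, 400)
        y = (rng.random(400) < expit(z)).astype(int)
        df = pd.DataFrame({"label": y, "SST": z})
        model = fit_binomial_gam(df, ["SST"])
        surf = sh.predict_surface(model, stack, world.colonies, domain)
        assert np.isnan(surf.probabilities[r0, c0])
        assert surf.n_blank >= 1

    def test_added_colony_only_decreases_cdist(self, world, domain):
        from sealhab.grids import covariate_frame
        rows, cols = np.nonzero(domain.mask)
        lon = world.grid.lon_centers[cols]
        lat = world.grid.lat_centers[rows]
        one = covariate_frame(world.stack, lon, lat, 6, world.colonies[:1])
        two = covariate_frame(world.stack, lon, lat, 6, world.colonies)
        assert (two["CDIST"] <= one["CDIST"] + 1e-12).all()

    def test_monthly_surface_uses_that_months_layer(self, world, domain):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 1, 400)
        y = (rng.random(400) < expit(2 * z)).astype(int)
        model = fit_binomial_gam(pd.DataFrame({"label": y, "SST": z}), ["SST"])
        s5 = sh.predict_surface(model, world.stack, world.colonies, domain, month=5)
        s9 = sh.predict_surface(model, world.stack, world.colonies, domain, month=9)
        assert np.nanmax(np.abs(s5.probabilities - s9.probabilities)) > 0


class TestThresholdMask:
    def test_uniform_surface_masks(self, domain):
        surf = uniform_surface(domain, 0.6)
        m50 = sh.threshold_mask(surf, 0.50)
        m95 = sh.threshold_mask(surf, 0.95)
        assert m50.mask.sum() == domain.mask.sum()
        assert abs(m50.area_km2 - domain.area_km2) < 1e-6
        assert m95.mask.sum() == 0 and m95.area_km2 == 0.0

    def test_threshold_is_strict(self, domain):
        surf = uniform_surface(domain, 0.5)
        assert sh.threshold_mask(surf, 0.50).mask.sum() == 0

    def test_checkerboard_areas_match_cell_count_oracle(self, domain):
        g = domain.grid
        rr, cc = np.meshgrid(np.arange(g.n_rows), np.arange(g.n_cols), indexing="ij")
        board = np.where((rr + cc) % 2 == 0, 0.96, 0.4)
        probs = np.where(domain.mask, board, np.nan)
        surf = PredictionSurface(domain=domain, probabilities=probs)
        areas = g.cell_areas_km2()
        for level in (0.50, 0.95):
            mask = sh.threshold_mask(surf, level)
            want_cells = domain.mask & ((rr + cc) % 2 == 0)
            np.testing.assert_array_equal(mask.mask, want_cells)
            assert abs(mask.area_km2 - areas[want_cells].sum()) < 1e-9

    def test_nested_masks_on_random_surfaces(self, domain):
        rng = np.random.default_rng(3)
        for _ in range(100):
            probs = np.where(domain.mask, rng.random(domain.mask.shape), np.nan)
            surf = PredictionSurface(domain=domain, probabilities=probs)
            m50 = sh.threshold_mask(surf, 0.50)
            m95 = sh.threshold_mask(surf, 0.95)
            assert np.all(m50.mask[m95.mask])       # mask(0.95) subset of mask(0.50)
            assert m95.area_km2 <= m50.area_km2


class TestOverlapSummary:
    def test_no_hauls_all_zero(self, domain):
        mask = sh.threshold_mask(uniform_surface(domain, 0.7), 0.5)
        s = sh.overlap_summary(mask, pd.DataFrame(columns=["lon", "lat", "catch_t"]),
                               domain)
        assert s.footprint_km2 == 0 and s.catch_within_t == 0
        assert s.footprint_pct_of_model_area == 0 and s.catch_pct_of_total == 0

    def test_two_haul_arithmetic(self, domain):
        g = domain.grid
        mask = sh.threshold_mask(uniform_surface(domain, 0.7), 0.5)
        rows, cols = np.nonzero(mask.mask)
        (r1, c1), (r2, c2) = (rows[0], cols[0]), (rows[-1], cols[-1])
        hauls = pd.DataFrame({
            "lon": [g.lon_centers[c1], g.lon_centers[c2]],
            "lat": [g.lat_centers[r1], g.lat_centers[r2]],
            "catch_t": [10.0, 30.0]})
        s = sh.overlap_summary(mask, hauls, domain, total_catch_reference=100.0)
        areas = g.cell_areas_km2()
        assert abs(s.footprint_km2 - (areas[r1, c1] + areas[r2, c2])) < 1e-9
        assert s.catch_within_t == 40.0
        assert s.catch_pct_of_total == 40.0

    def test_haul_outside_grid_counts_toward_total_only(self, domain):
        mask = sh.threshold_mask(uniform_surface(domain, 0.7), 0.5)
        hauls = pd.DataFrame({"lon": [0.0], "lat": [0.0], "catch_t": [50.0]})
        s = sh.overlap_summary(mask, hauls, domain)
        assert s.footprint_km2 == 0.0
        assert s.total_catch_t == 50.0
        assert s.n_hauls_outside_grid == 1

    def test_matches_per_haul_loop_oracle(self, domain):
        rng = np.random.default_rng(4)
        for seed in range(5):
            probs = np.where(domain.mask, rng.random(domain.mask.shape), np.nan)
            surf = PredictionSurface(domain=domain, probabilities=probs)
            mask = sh.threshold_mask(surf, 0.5)
            hauls = random_hauls(domain, 80, seed=seed)
            s = sh.overlap_summary(mask, hauls, domain)
            fp, cin, pct = overlap_by_haul_loop(mask.mask, domain.grid, hauls,
                                                float(hauls["catch_t"].sum()))
            assert abs(s.footprint_km2 - fp) < 1e-9
            assert abs(s.catch_within_t - cin) < 1e-9
            assert abs(s.catch_pct_of_total - pct) < 1e-9

    def test_shrinking_mask_never_increases_overlap(self, domain):
        rng = np.random.default_rng(5)
        hauls = random_hauls(domain, 150, seed=6)
        probs = np.where(domain.mask, rng.random(domain.mask.shape), np.nan)
        surf = PredictionSurface(domain=domain, probabilities=probs)
        m50 = sh.threshold_mask(surf, 0.50)
        m95 = sh.threshold_mask(surf, 0.95)
        s50 = sh.overlap_summary(m50, hauls, domain)
        s95 = sh.overlap_summary(m95, hauls, domain)
        assert s95.footprint_km2 <= s50.footprint_km2
        assert s95.catch_within_t <= s50.catch_within_t


class TestCatchKernelDensity:
    def test_single_haul_density_peaks_at_haul(self, domain):
        g = domain.grid
        lon, lat = g.lon_centers[30], g.lat_centers[30]
        hauls = pd.DataFrame({"lon": [lon], "lat": [lat], "catch_t": [20.0]})
        dens = sh.catch_kernel_density(hauls, domain, bandwidth_km=20.0)
        r, c = np.unravel_index(np.argmax(dens), dens.shape)
        assert (r, c) == (30, 30)

    def test_density_integrates_to_total_catch(self, domain):
        hauls = random_hauls(domain, 40, seed=7)
        # keep hauls away from the grid boundary so no mass escapes
        g = domain.grid
        inner = ((hauls["lon"] > g.lon_edges[8]) & (hauls["lon"] < g.lon_edges[-8])
                 & (hauls["lat"] > g.lat_edges[8]) & (hauls["lat"] < g.lat_edges[-8]))
        hauls = hauls[inner]
        dens = sh.catch_kernel_density(hauls, domain, bandwidth_km=15.0)
        integral = float((dens * g.cell_areas_km2()).sum())
        total = float(hauls["catch_t"].sum())
        assert abs(integral - total) / total < 0.01

    def test_two_distant_hauls_match_two_gaussian_sum(self, domain):
        g = domain.grid
        proj = sh.DEFAULT_PROJECTION
        hauls = pd.DataFrame({
            "lon": [g.lon_centers[15], g.lon_centers[55]],
            "lat": [g.lat_centers[15], g.lat_centers[45]],
            "catch_t": [10.0, 10.0]})
        h = 20.0
        dens = sh.catch_kernel_density(hauls, domain, bandwidth_km=h)
        glon, glat = np.meshgrid(g.lon_centers, g.lat_centers)
        gx, gy = proj.forward(glon, glat)
        expected = np.zeros_like(gx)
        for _, row in hauls.iterrows():
            hx, hy = proj.forward(row["lon"], row["lat"])
            d2 = (gx - hx) ** 2 + (gy - hy) ** 2
            expected += row["catch_t"] * np.exp(-0.5 * d2 / h**2) / (2 * np.pi * h**2)
        np.testing.assert_allclose(dens, expected, rtol=1e-9, atol=1e-12)
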