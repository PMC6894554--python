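from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from denshab.grids import GridSpec, InvalidConfigurationError
from denshab.synthetic_world import (CapacityError, generate_landscape,
                                     simulate_recolonization, simulate_telemetry,
                                     simulate_track_survey)


class TestGenerateLandscape:
    def test_zero_sill_gives_constant_layer(self, small_grid):
        stack = generate_landscape(small_grid, [
            {"name": "flat", "spatial_range": 10.0, "sill": 0.0, "mean": 2.0}], seed=0)
        np.testing.assert_allclose(stack.layers["flat"], 2.0)

    def test_same_seed_reproduces_stack(self, small_grid):
        specs = [{"name": "a", "spatial_range": 15.0, "sill": 2.0}]
        s1 = generate_landscape(small_grid, specs, seed=42)
        s2 = generate_landscape(small_grid, specs, seed=42)
        np.testing.assert_array_equal(s1.layers["a"], s2.layers["a"])

    def test_invalid_range_rejected(self, small_grid):
        with pytest.raises(InvalidConfigurationError):
            generate_landscape(small_grid, [
                {"name": "a", "spatial_range": -5.0, "sill": 1.0}], seed=0)

    def test_variogram_sill_at_long_lag(self):
        """Monte-Carlo variogram: semivariance at lag >> range approaches the sill."""
        grid = GridSpec(0, 0, 1.0, 500, 500)
        sill, rng_km = 2.0, 20.0
        stack = generate_landscape(grid, [
            {"name": "a", "spatial_range": rng_km, "sill": sill}], seed=9)
        f = stack.layers["a"]
        lag = 100  # cells = 100 km, five times the range
        gamma = 0.5 * np.mean((f[:, lag:] - f[:, :-lag]) ** 2)
        assert gamma == pytest.approx(sill, rel=0.25)


class TestRecolonization:
    def test_single_pack_no_overlap(self, landscape):
        hist = simulate_recolonization(
            landscape, years=1, growth={"N0": 4.0, "K": 16.0, "r": 0.3}, seed=0)
        assert len(hist.packs[0]) == 1

    def test_ipd_first_settler_takes_best_site(self, small_grid):
        """On a monotone suitability gradient the first pack's centre beats the second's."""
        x = np.tile(np.linspace(0, 1, small_grid.n_cols), (small_grid.n_rows, 1))
        stack = generate_landscape(small_grid, [
            {"name": "grad", "spatial_range": 10.0, "sill": 0.0, "weight": 1.0}], seed=0)
        stack.layers["grad"] = x
        hist = simulate_recolonization(
            stack, years=1, growth={"N0": 8.0, "K": 32.0, "r": 0.3}, seed=1)
        recs = hist.packs[0]
        assert len(recs) >= 2
        suits = [stack.suitability_at(r.polygon.centroid.x, r.polygon.centroid.y)
                 for r in recs[:2]]
        assert suits[0] > suits[1]

    def test_settlement_order_tracks_suitability(self, landscape):
        """IPD: later settlement years occupy lower-suitability sites (negative rank
        correlation, pooled over seeds)."""
        rhos = []
        for seed in range(6):
            hist = simulate_recolonization(
                landscape, years=12, growth={"N0": 8.0, "K": 72.0, "r": 0.5}, seed=seed)
            last = hist.packs[hist.years[-1]]
            years = [hist.settlement_year[r.pack_id] for r in last]
            suits = [landscape.suitability_at(r.polygon.centroid.x, r.polygon.centroid.y)
                     for r in last]
            rhos.append(sps.spearmanr(years, suits).statistic)
        combined = sps.ttest_1samp(rhos, 0.0, alternative="less")
        assert combined.pvalue < 0.05
        assert np.mean(rhos) < 0

    def test_abundance_bounded_and_monotone(self, world):
        K = 64.0
        totals = [world.abundance(y) for y in world.years]
        assert max(totals) <= K
        for a, b in zip(totals, totals[1:]):
            if a < 0.95 * K:
                assert b >= a

    def test_zero_overlap_schedule_gives_disjoint_territories(self, landscape):
        hist = simulate_recolonization(
            landscape, years=8, growth={"N0": 8.0, "K": 48.0, "r": 0.4},
            overlap_schedule={t: 0.0 for t in range(8)}, seed=3)
        recs = hist.packs[7]
        for a, b in combinations(recs, 2):
            assert a.polygon.intersection(b.polygon).area == pytest.approx(0.0, abs=1e-9)

    def test_overlap_tracks_schedule(self, world):
        for year in (5, 10, 14):
            recs = world.packs[year]
            inter = sum(a.polygon.intersection(b.polygon).area
                        for a, b in combinations(recs, 2))
            total = sum(r.polygon.area for r in recs)
            assert inter / total == pytest.approx(world.overlap_schedule[year], abs=0.05)

    def test_capacity_error_on_tiny_landscape(self):
        g = GridSpec(0, 0, 1.0, 5, 5)
        stack = generate_landscape(g, [
            {"name": "a", "spatial_range": 3.0, "sill": 1.0, "weight": 1.0}], seed=0)
        with pytest.raises(CapacityError):
            simulate_recolonization(stack, years=1,
                                    growth={"N0": 8.0, "K": 32.0, "r": 0.3}, seed=0)

    def test_pack_sizes_at_least_two(self, world):
        for year in world.years:
            assert all(r.size >= 2 for r in world.packs[year])


class TestTelemetry:
    def test_no_collars_no_fixes(self, world):
        locs = simulate_telemetry(world, 52, collared_fraction=0.0, seed=0)
        assert len(locs) == 0

    def test_fix_count_contract(self, world):
        locs = simulate_telemetry(world, fixes_per_pack_year=52,
                                  collared_fraction=1.0, seed=1)
        counts = locs.groupby(["pack_id", "year"]).size()
        assert (counts == 52).all()

    def test_fixes_inside_true_polygon(self, world, telemetry):
        truth = {(r.pack_id, y): r.polygon
                 for y in world.years for r in world.packs[y]}
        import shapely
        inside = 0
        for (pid, year), grp in telemetry.groupby(["pack_id", "year"]):
            poly = truth[(pid, year)]
            inside += shapely.contains_xy(
                poly, grp["x_km"].to_numpy(), grp["y_km"].to_numpy()).sum()
        assert inside / len(telemetry) >= 0.95

    def test_uncollared_packs_have_no_fixes(self, world):
        locs = simulate_telemetry(world, 40, collared_fraction=0.5, seed=2)
        collared = set(locs["pack_id"])
        assert len(collared) == round(0.5 * len(world.pack_ids()))


class TestTrackSurvey:
    def test_full_detection_matches_truth(self, world):
        matrix, _ = simulate_track_survey(world, detection_prob=1.0, seed=0)
        for year in world.years:
            truth = {r.pack_id: r.size for r in world.packs[year]}
            for pid in matrix.index:
                assert matrix.loc[pid, year] == truth.get(pid, 0.0)

    def test_panel_gap_recorded_not_surveyed(self, survey):
        matrix, _ = survey
        assert matrix[9].isna().all()
        assert not matrix[8].isna().any()

    def test_detection_rate_binomial(self, world):
        """Detected fraction of truly-present pack-years ~ detection_prob."""
        detected = present = 0
        for seed in range(8):
            matrix, _ = simulate_track_survey(world, detection_prob=0.8, seed=seed)
            for year in world.years:
                for r in world.packs[year]:
                    present += 1
                    if matrix.loc[r.pack_id, year] >= 2:
                        detected += 1
        assert detected / present == pytest.approx(0.8, abs=0.05)

    def test_tracks_enable_mcp(self, survey):
        _, tracks = survey
        assert (tracks.groupby(["pack_id", "year"]).size() >= 3).all()
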