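import numpy as np
import pytest
import shapely
from scipy import stats

from woodchange.errors import ConfigurationError, GridMismatchError, UndefinedResultError
from woodchange.grids import CoverTimeSeries, FractionalCoverMap, Grid
from woodchange.megafauna import (
    RichnessMap,
    SpeciesRange,
    archetype_composition,
    median_richness_per_archetype,
    range_cover_trajectory,
    rasterize_range,
    richness,
    richness_cover_correlation,
)


@pytest.fixture
def coarse_grid():
    return Grid(0, 0, 10.0, 6, 6)


def make_range(grid, presence, species_id="sp", threatened=False):
    return SpeciesRange(species_id, grid, np.asarray(presence, dtype=bool), threatened)


class TestRasterizeRange:
    def test_rectangle_covering_four_centers(self, coarse_grid):
        # centers at 5, 15, 25, ...; box around the four top-left centers
        geom = shapely.box(2.0, 2.0, 18.0, 18.0)
        out = rasterize_range(geom, coarse_grid, "sp", False)
        assert out.n_cells == 4
        assert out.presence[:2, :2].all()

    def test_whole_grid_saturation(self, coarse_grid):
        geom = shapely.box(-1, -1, 61, 61)
        out = rasterize_range(geom, coarse_grid, "sp", False)
        assert out.presence.all()

    def test_point_in_polygon_oracle(self, coarse_grid, rng):
        pts = rng.uniform(0, 60, (8, 2))
        geom = shapely.convex_hull(shapely.multipoints(pts))
        try:
            out = rasterize_range(geom, coarse_grid, "sp", False)
        except ConfigurationError:
            pytest.skip("degenerate polygon covers no center")
        for i in range(6):
            for j in range(6):
                x, y = coarse_grid.cell_center(i, j)
                assert out.presence[i, j] == geom.contains(shapely.points(x, y))

    def test_any_overlap_rule_superset(self, coarse_grid):
        geom = shapely.box(12.0, 12.0, 14.0, 14.0)  # inside one cell, misses centers
        with pytest.raises(ConfigurationError):
            rasterize_range(geom, coarse_grid, "sp", False, rule="center")
        out = rasterize_range(geom, coarse_grid, "sp", False, rule="any_overlap")
        assert out.n_cells == 1

    def test_empty_intersection_names_species(self, coarse_grid):
        geom = shapely.box(1000, 1000, 1001, 1001)
        with pytest.raises(ConfigurationError, match="leopard"):
            rasterize_range(geom, coarse_grid, "leopard", True)


class TestRichness:
    def test_single_species_identity(self, coarse_grid, rng):
        mask = rng.random((6, 6)) > 0.5
        mask[0, 0] = True
        out = richness([make_range(coarse_grid, mask)])
        np.testing.assert_array_equal(out.values, mask.astype(int))

    def test_disjoint_species_max_one(self, coarse_grid):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[:3], b[3:] = True, True
        out = richness([make_range(coarse_grid, a), make_range(coarse_grid, b)])
        assert out.values.max() == 1

    def test_summation_oracle(self, coarse_grid, rng):
        masks = rng.random((14, 6, 6)) > 0.6
        masks[:, 0, 0] = True  # every range non-empty
        ranges = [make_range(coarse_grid, m, f"s{i}", i < 7) for i, m in enumerate(masks)]
        out = richness(ranges, "all")
        np.testing.assert_array_equal(out.values, masks.sum(axis=0))

    def test_group_additivity(self, coarse_grid, rng):
        masks = rng.random((10, 6, 6)) > 0.5
        masks[:, 2, 2] = True
        ranges = [make_range(coarse_grid, m, f"s{i}", i % 2 == 0) for i, m in enumerate(masks)]
        total = richness(ranges, "all").values
        t = richness(ranges, "threatened").values
        nt = richness(ranges, "non_threatened").values
        np.testing.assert_array_equal(total, t + nt)

    def test_richness_bounds(self, coarse_grid, rng):
        masks = rng.random((5, 6, 6)) > 0.5
        masks[:, 1, 1] = True
        ranges = [make_range(coarse_grid, m, f"s{i}") for i, m in enumerate(masks)]
        out = richness(ranges)
        assert out.values.min() >= 0 and out.values.max() <= 5


class TestRichnessCoverCorrelation:
    def test_perfect_linearity(self, coarse_grid):
        cover = FractionalCoverMap(coarse_grid, np.linspace(0, 1, 36).reshape(6, 6))
        rich = RichnessMap(coarse_grid, (cover.values * 10).astype(int) + 1)
        # richness exactly proportional to (discretized) cover is not exactly
        # linear; build exact linearity instead
        rich = RichnessMap(coarse_grid, np.arange(36).reshape(6, 6))
        out = richness_cover_correlation(rich, cover)
        assert out.r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        grid = Grid(0, 0, 1.0, 1, 4)
        cover = FractionalCoverMap(grid, [[0.1, 0.2, 0.3, 0.4]])
        rich = RichnessMap(grid, [[4, 3, 2, 1]])
        out = richness_cover_correlation(rich, cover)
        assert out.r == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self, rng):
        grid = Grid(0, 0, 1.0, 1, 50)
        xs = rng.random(50)
        ys = rng.integers(0, 10, 50)
        out = richness_cover_correlation(
            RichnessMap(grid, ys.reshape(1, 50)), FractionalCoverMap(grid, xs.reshape(1, 50))
        )
        xc = xs - xs.mean()
        yc = ys - ys.mean()
        r_direct = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert out.r == pytest.approx(r_direct, abs=1e-12)
        t = r_direct * np.sqrt(48 / (1 - r_direct**2))
        p_direct = 2 * stats.t.sf(abs(t), 48)
        assert out.p == pytest.approx(p_direct, rel=1e-9)

    def test_zero_variance_is_error_not_zero(self, coarse_grid):
        cover = FractionalCoverMap(coarse_grid, np.full((6, 6), 0.5))
        rich = RichnessMap(coarse_grid, np.arange(36).reshape(6, 6))
        with pytest.raises(UndefinedResultError):
            richness_cover_correlation(rich, cover)

    def test_cell_order_invariance(self, rng):
        # correlation over cells is a set statistic: permuting the grid layout
        # of (cover, richness) pairs leaves r unchanged
        grid = Grid(0, 0, 1.0, 1, 30)
        xs = rng.random(30)
        ys = rng.integers(0, 8, 30)
        perm = rng.permutation(30)
        r1 = richness_cover_correlation(
            RichnessMap(grid, ys.reshape(1, -1)), FractionalCoverMap(grid, xs.reshape(1, -1))
        ).r
        r2 = richness_cover_correlation(
            RichnessMap(grid, ys[perm].reshape(1, -1)),
            FractionalCoverMap(grid, xs[perm].reshape(1, -1)),
        ).r
        assert r1 == pytest.approx(r2, abs=1e-14)

    def test_extra_mask_restricts_domain(self, coarse_grid, rng):
        cover = FractionalCoverMap(coarse_grid, rng.random((6, 6)))
        rich = RichnessMap(coarse_grid, rng.integers(0, 5, (6, 6)))
        mask = np.zeros((6, 6), bool)
        mask[0] = True
        out = richness_cover_correlation(rich, cover, extra_mask=mask)
        assert out.n == 30


class TestRangeCoverTrajectory:
    def make_series(self, stack, grid):
        stack = np.asarray(stack, float)
        epochs = list(range(2000, 2000 + len(stack)))
        return CoverTimeSeries(
            epochs, [FractionalCoverMap(grid, s, epoch_year=e) for s, e in zip(stack, epochs)]
        )

    def test_uniform_cover(self, coarse_grid, rng):
        series = self.make_series(np.full((3, 6, 6), 0.6), coarse_grid)
        mask = rng.random((6, 6)) > 0.5
        mask[0, 0] = True
        traj = range_cover_trajectory(make_range(coarse_grid, mask), series)
        np.testing.assert_allclose(traj.to_numpy(), 0.6)

    def test_single_cell_range(self, coarse_grid, rng):
        stack = rng.random((4, 6, 6))
        series = self.make_series(stack, coarse_grid)
        mask = np.zeros((6, 6), bool)
        mask[2, 3] = True
        traj = range_cover_trajectory(make_range(coarse_grid, mask), series)
        np.testing.assert_allclose(traj.to_numpy(), stack[:, 2, 3])

    def test_masked_mean_oracle(self, coarse_grid, rng):
        stack = rng.random((3, 6, 6))
        series = self.make_series(stack, coarse_grid)
        mask = rng.random((6, 6)) > 0.4
        mask[1, 1] = True
        traj = range_cover_trajectory(make_range(coarse_grid, mask), series)
        for i in range(3):
            assert traj.iloc[i] == pytest.approx(stack[i][mask].mean())


class TestArchetypeComposition:
    def test_containment(self, coarse_grid):
        labels = np.zeros((6, 6), int)
        mask = np.zeros((6, 6), bool)
        mask[1:3, 1:3] = True
        comp = archetype_composition(make_range(coarse_grid, mask), labels)
        assert comp == {0: 1.0}

    def test_even_split(self, coarse_grid):
        labels = np.zeros((6, 6), int)
        labels[:, 3:] = 1
        mask = np.zeros((6, 6), bool)
        mask[0, 2], mask[0, 3] = True, True
        comp = archetype_composition(make_range(coarse_grid, mask), labels)
        assert comp == {0: 0.5, 1: 0.5}

    def test_counting_oracle_and_normalization(self, coarse_grid, rng):
        labels = rng.integers(0, 4, (6, 6))
        mask = rng.random((6, 6)) > 0.4
        mask[0, 0] = True
        comp = archetype_composition(make_range(coarse_grid, mask), labels)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-12)
        for a, share in comp.items():
            assert share == pytest.approx((labels[mask] == a).mean())

    def test_nodata_labels_excluded(self, coarse_grid):
        labels = np.full((6, 6), -1)
        labels[0, 0] = 2
        mask = np.ones((6, 6), bool)
        comp = archetype_composition(make_range(coarse_grid, mask), labels)
        assert comp == {2: 1.0}


class TestMedianRichness:
    def test_constant(self, coarse_grid):
        rich = RichnessMap(coarse_grid, np.full((6, 6), 3))
        labels = np.tile([0, 1], (6, 3))
        out = median_richness_per_archetype(rich, labels)
        assert out == {0: 3.0, 1: 3.0}

    def test_odd_count_median(self):
        grid = Grid(0, 0, 1.0, 1, 3)
        rich = RichnessMap(grid, [[1, 2, 9]])
        out = median_richness_per_archetype(rich, np.zeros((1, 3), int))
        assert out == {0: 2.0}

    def test_even_count_midpoint(self):
        grid = Grid(0, 0, 1.0, 1, 4)
        rich = RichnessMap(grid, [[1, 2, 5, 9]])
        out = median_richness_per_archetype(rich, np.zeros((1, 4), int))
        assert out == {0: 3.5}

    def test_sort_and_pick_oracle(self, coarse_grid, rng):
        rich = RichnessMap(coarse_grid, rng.integers(0, 12, (6, 6)))
        labels = rng.integers(0, 3, (6, 6))
        out = median_richness_per_archetype(rich, labels)
        for a in range(3):
            vals = sorted(rich.values[labels == a])
            n = len(vals)
            expected = vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
            assert out[a] == pytest.approx(expected)

    def test_empty_archetype_absent(self, coarse_grid):
        rich = RichnessMap(coarse_grid, np.zeros((6, 6), int))
        labels = np.zeros((6, 6), int)  # archetype 1 never occurs
        out = median_richness_per_archetype(rich, labels)
        assert 1 not in out


class TestSpeciesRangeValidation:
    def test_empty_range_rejected(self, coarse_grid):
        with pytest.raises(ConfigurationError):
            make_range(coarse_grid, np.zeros((6, 6), bool))

    def test_grid_mismatch(self, coarse_grid, rng):
        r = make_range(coarse_grid, np.ones((6, 6), bool))
        other = FractionalCoverMap(Grid(0, 0, 5.0, 6, 6), rng.random((6, 6)))
        with pytest.raises(GridMismatchError):
            richness_cover_correlation(RichnessMap(coarse_grid, np.ones((6, 6), int)), other)
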