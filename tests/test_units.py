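import datetime as dt
import math

import numpy as np
import pytest
from conftest import brute_force_min_cost, scipy_graph_min_cost

from rxsmoke.grid import ACRE_M2, RasterGrid
from rxsmoke.synthetic import DEVELOPED, FIREBREAK_CLASSES, FOREST_DECIDUOUS, WATER, make_landscape
from rxsmoke.units import (
    BurnUnit,
    FirebreakSpec,
    dilate,
    firebreak_mask,
    partition_units,
    polygonize,
    uniform_cost_boundary,
    zigzag_schedule,
)

SPEC = FirebreakSpec(firebreak_classes=FIREBREAK_CLASSES)


class TestFirebreakMask:
    def test_all_water_is_all_firebreak(self):
        lc = RasterGrid(np.full((4, 4), WATER), 30.0)
        assert firebreak_mask(lc, SPEC).values.sum() == 16

    def test_forest_only_is_zero(self):
        lc = RasterGrid(np.full((4, 4), FOREST_DECIDUOUS), 30.0)
        assert firebreak_mask(lc, SPEC).values.sum() == 0

    def test_road_column_counts(self):
        lc = np.full((5, 5), FOREST_DECIDUOUS)
        lc[:, 2] = DEVELOPED
        mask = firebreak_mask(RasterGrid(lc, 30.0), SPEC)
        assert mask.values.sum() == 5
        assert mask.values[:, 2].all()


class TestDilate:
    def test_radius_zero_is_identity(self):
        m = RasterGrid((np.arange(25).reshape(5, 5) % 3 == 0).astype(np.uint8), 30.0)
        assert np.array_equal(dilate(m, 0).values, m.values)

    def test_single_center_becomes_block(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 2] = 1
        out = dilate(RasterGrid(m, 30.0), 1).values
        expected = np.zeros((5, 5))
        expected[1:4, 1:4] = 1
        assert np.array_equal(out, expected)

    def test_all_ones_absorbs(self):
        m = RasterGrid(np.ones((6, 6), dtype=np.uint8), 30.0)
        assert dilate(m, 2).values.all()

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            dilate(RasterGrid(np.ones((3, 3)), 30.0), -1)


class TestUniformCostBoundary:
    def test_adjacent_on_target(self):
        target = np.ones((3, 3), dtype=bool)
        path, cost = uniform_cost_boundary(target, (0, 0), (0, 1))
        assert path == [(0, 0), (0, 1)]
        assert cost == pytest.approx(1.0)

    def test_follows_L_shaped_target(self):
        # L of target cells down column 0 then along row 3
        target = np.zeros((4, 4), dtype=bool)
        target[:, 0] = True
        target[3, :] = True
        path, cost = uniform_cost_boundary(target, (0, 0), (3, 3), off_target_penalty=1000.0)
        assert all(target[r, c] for r, c in path)
        assert cost == pytest.approx(brute_force_min_cost(target, (0, 0), (3, 3), 1000.0))

    def test_no_path_with_infinite_penalty(self):
        target = np.zeros((4, 4), dtype=bool)
        target[0, 0] = target[3, 3] = True  # disconnected target islands
        with pytest.raises(RuntimeError):
            uniform_cost_boundary(target, (0, 0), (3, 3), off_target_penalty=math.inf)

    def test_endpoint_validation(self):
        target = np.ones((3, 3), dtype=bool)
        with pytest.raises(ValueError):
            uniform_cost_boundary(target, (0, 0), (0, 0))
        with pytest.raises(ValueError):
            uniform_cost_boundary(target, (0, 0), (5, 5))

    def test_path_is_simple_and_cost_decomposes(self):
        rng = np.random.default_rng(3)
        target = rng.random((6, 6)) < 0.5
        path, cost = uniform_cost_boundary(target, (0, 0), (5, 5), 2.5)
        assert len(set(path)) == len(path)
        total = 0.0
        for (r0, c0), (r1, c1) in zip(path, path[1:]):
            assert max(abs(r1 - r0), abs(c1 - c0)) == 1  # 8-connected steps
            base = math.sqrt(2) if (r1 != r0 and c1 != c0) else 1.0
            total += base if target[r1, c1] else base * 3.5
        assert cost == pytest.approx(total)

    def test_matches_exhaustive_and_graph_oracles(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            nr, nc = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            target = rng.random((nr, nc)) < rng.uniform(0.2, 0.8)
            cells = [(r, c) for r in range(nr) for c in range(nc)]
            i, j = rng.choice(len(cells), size=2, replace=False)
            penalty = float(rng.choice([1.0, 2.5, 10.0, 1000.0]))
            _, cost = uniform_cost_boundary(target, cells[i], cells[j], penalty)
            assert cost == pytest.approx(brute_force_min_cost(target, cells[i], cells[j], penalty))
            assert cost == pytest.approx(scipy_graph_min_cost(target, cells[i], cells[j], penalty))

    def test_penalty_weighted_off_target_cost_is_monotone(self):
        """Raising the off-target penalty never increases the path's
        penalty-weighted off-target step cost (scalarization argument)."""
        rng = np.random.default_rng(21)
        for _ in range(30):
            target = rng.random((6, 6)) < 0.5
            cells = [(r, c) for r in range(6) for c in range(6)]
            i, j = rng.choice(len(cells), size=2, replace=False)
            prev_off = None
            for penalty in (0.5, 2.0, 8.0, 1000.0):
                path, _ = uniform_cost_boundary(target, cells[i], cells[j], penalty)
                off = 0.0
                for (r0, c0), (r1, c1) in zip(path, path[1:]):
                    if not target[r1, c1]:
                        off += math.sqrt(2) if (r1 != r0 and c1 != c0) else 1.0
                if prev_off is not None:
                    assert off <= prev_off + 1e-9
                prev_off = off


class TestPartitionUnits:
    def test_small_component_returned_unsplit(self, one_acre_cell):
        lc = np.full((40, 40), WATER, dtype=np.int16)
        lc[5:35, 5:35] = FOREST_DECIDUOUS  # 900 cells = 900 acres
        slope = RasterGrid(np.full((40, 40), 10.0), one_acre_cell)
        spec = FirebreakSpec(firebreak_classes=FIREBREAK_CLASSES, dilation_radius=0)
        units = partition_units(RasterGrid(lc, one_acre_cell), slope, spec)
        assert len(units) == 1
        assert units[0].area_acres == pytest.approx(900.0)
        assert not units[0].oversize_flag

    def test_dumbbell_splits_through_gentle_neck(self, dumbbell_landscape):
        lc, slope = dumbbell_landscape
        spec = FirebreakSpec(firebreak_classes=FIREBREAK_CLASSES, dilation_radius=0)
        units = partition_units(lc, slope, spec)
        assert len(units) >= 2
        assert all(not u.oversize_flag for u in units)
        assert all(u.area_acres < 1000.0 for u in units)

    def test_unsplittable_component_is_flagged_oversize(self, one_acre_cell):
        # 1600-acre block, uniformly steep: no gentle corridor exists
        lc = np.full((44, 44), WATER, dtype=np.int16)
        lc[2:42, 2:42] = FOREST_DECIDUOUS
        slope = RasterGrid(np.full((44, 44), 35.0), one_acre_cell)
        spec = FirebreakSpec(firebreak_classes=FIREBREAK_CLASSES, dilation_radius=0)
        units = partition_units(
            RasterGrid(lc, one_acre_cell), slope, spec, off_target_penalty=math.inf
        )
        assert len(units) == 1
        assert units[0].oversize_flag
        assert units[0].area_acres > 1000.0

    def test_no_burnable_cells_gives_empty_list(self, one_acre_cell):
        lc = RasterGrid(np.full((20, 20), WATER, dtype=np.int16), one_acre_cell)
        slope = lc.with_values(np.zeros((20, 20)))
        assert partition_units(lc, slope, SPEC) == []

    def test_cell_accounting_and_disjointness(self, dumbbell_landscape):
        """Units + split paths + firebreak cells tile the whole grid."""
        lc, slope = dumbbell_landscape
        spec = FirebreakSpec(firebreak_classes=FIREBREAK_CLASSES, dilation_radius=0)
        units = partition_units(lc, slope, spec)
        fb_cells = int(firebreak_mask(lc, spec).values.sum())
        unit_cells = sum(u.n_cells for u in units)
        seen = set()
        for u in units:
            cells = {tuple(rc) for rc in u.cells}
            assert not cells & seen  # pairwise disjoint
            seen |= cells
        n_total = lc.n_rows * lc.n_cols
        split_cells = n_total - fb_cells - unit_cells
        assert split_cells >= 0  # split paths are the only unaccounted cells
        burnable = n_total - fb_cells
        assert unit_cells + split_cells == burnable

    def test_seeded_landscapes_satisfy_area_limit(self):
        for seed in range(5):
            lc, slope = make_landscape(48, 48, 150.0, seed)
            units = partition_units(lc, slope, SPEC)
            for u in units:
                if not u.oversize_flag:
                    assert u.area_acres <= SPEC.max_unit_area_acres + 1e-9


class TestZigzag:
    @staticmethod
    def unit_at(uid, r, c):
        return BurnUnit(uid, np.array([[r, c]]), 1.0)

    def dates(self, n):
        return [dt.date(2016, 1, 1) + dt.timedelta(days=i) for i in range(n)]

    def test_single_unit(self):
        plan = zigzag_schedule([self.unit_at(0, 3, 3)], self.dates(2))
        assert len(plan) == 1 and plan.units[0].burn_date == dt.date(2016, 1, 1)

    def test_four_corners_serpentine(self):
        corners = [(0, 0), (0, 10), (10, 10), (10, 0)]
        units = [self.unit_at(i, r, c) for i, (r, c) in enumerate(corners)]
        # worst input order: diagonal zig (0,0) -> (10,10) -> (0,10) -> (10,0)
        shuffled = [units[0], units[2], units[1], units[3]]
        plan = zigzag_schedule(shuffled, self.dates(4))
        cents = [u.centroid_rc() for u in plan.units]
        total = sum(math.hypot(b[0] - a[0], b[1] - a[1]) for a, b in zip(cents, cents[1:]))
        assert total == pytest.approx(30.0)  # 3 sides, not 2 sides + diagonal

    def test_serpentine_order_is_idempotent(self):
        units = [self.unit_at(0, 0, 0), self.unit_at(1, 0, 5), self.unit_at(2, 6, 5),
                 self.unit_at(3, 6, 0)]
        plan = zigzag_schedule(units, self.dates(4))
        replay = zigzag_schedule(plan.units, self.dates(4))
        assert [u.unit_id for u in replay.units] == [u.unit_id for u in plan.units]

    def test_never_longer_than_input_order(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            units = [
                self.unit_at(i, int(rng.integers(0, 30)), int(rng.integers(0, 30)))
                for i in range(8)
            ]
            plan = zigzag_schedule(units, self.dates(8))

            def total(us):
                cents = [u.centroid_rc() for u in us]
                return sum(math.hypot(b[0] - a[0], b[1] - a[1]) for a, b in zip(cents, cents[1:]))

            assert total(plan.units) <= total(units) + 1e-9

    def test_dates_shortfall_is_an_error(self):
        units = [self.unit_at(i, i, i) for i in range(3)]
        with pytest.raises(ValueError, match="short by 1"):
            zigzag_schedule(units, self.dates(2))

    def test_plan_dates_strictly_increase(self):
        units = [self.unit_at(i, i, 2 * i) for i in range(5)]
        plan = zigzag_schedule(units, self.dates(7))
        ds = plan.dates
        assert all(b > a for a, b in zip(ds, ds[1:]))


class TestPolygonize:
    def test_single_cell_square(self):
        grid = RasterGrid(np.zeros((4, 4)), 30.0)
        unit = BurnUnit(0, np.array([[1, 2]]), grid.cell_area_acres)
        poly = polygonize(unit, grid)
        assert poly.area == pytest.approx(900.0)
        assert poly.bounds == (60.0, -60.0, 90.0, -30.0)

    def test_block_and_L_shape_areas(self):
        grid = RasterGrid(np.zeros((5, 5)), 30.0)
        block = BurnUnit(0, np.array([[0, 0], [0, 1], [1, 0], [1, 1]]), 4 * grid.cell_area_acres)
        assert polygonize(block, grid).area == pytest.approx(4 * 900.0)
        ell = BurnUnit(1, np.array([[2, 2], [3, 2], [3, 3]]), 3 * grid.cell_area_acres)
        poly = polygonize(ell, grid)
        assert poly.area == pytest.approx(3 * 900.0)
        assert len(poly.exterior.coords) - 1 == 6  # hexagonal outline
        # polygon area agrees with the acre bookkeeping
        assert poly.area / ACRE_M2 == pytest.approx(ell.area_acres)
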