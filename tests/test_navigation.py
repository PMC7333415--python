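"""Grid planner: rasterization, optimality against brute force, invariants."""

import math
from dataclasses import replace

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orsim import fixtures
from orsim.geometry import Furniture, load_layout
from orsim.navigation import (
    NavGrid,
    UnreachableError,
    distance_map,
    rasterize,
    shortest_path,
)

SQRT2 = math.sqrt(2.0)


def empty_grid(n=50, cell=0.1):
    return NavGrid(cell_size=cell, occupancy=np.zeros((n, n), dtype=bool))


def grid_from_occupancy(occ, cell=1.0):
    return NavGrid(cell_size=cell, occupancy=np.asarray(occ, dtype=bool))


def oracle_length(grid: NavGrid, start, goal):
    """Brute-force uniform-cost search on the full move graph via networkx."""
    occ = grid.occupancy
    ny, nx_ = occ.shape
    g = nx.Graph()
    for j in range(ny):
        for i in range(nx_):
            if occ[j, i]:
                continue
            for dj, di in ((0, 1), (1, 0), (1, 1), (1, -1)):
                nj, ni = j + dj, i + di
                if not (0 <= nj < ny and 0 <= ni < nx_) or occ[nj, ni]:
                    continue
                if dj != 0 and di != 0 and (occ[j + dj, i] or occ[j, i + di]):
                    continue
                g.add_edge((j, i), (nj, ni), weight=(SQRT2 if dj and di else 1.0))
    try:
        return nx.dijkstra_path_length(g, grid.cell_of(start), grid.cell_of(goal)) * grid.cell_size
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return None


class TestRasterize:
    def test_room_without_solids_is_free(self, minimal_doc):
        layout = load_layout(minimal_doc)
        bare = replace(layout, furniture=(), plan=replace(layout.plan, obstacles=()))
        grid = rasterize(bare)
        assert not grid.occupancy.any()

    def test_inflation_blocks_at_least_the_grown_footprint(self, minimal_doc):
        layout = load_layout(minimal_doc)
        table = Furniture(id="solo", kind="equipment", center=(3.0, 3.0), footprint=(1.0, 1.0))
        solo = replace(layout, furniture=(table,), plan=replace(layout.plan, obstacles=()))
        grid = rasterize(solo, cell_size=0.1, agent_radius=0.3)
        blocked_cols = np.flatnonzero(grid.occupancy.any(axis=0))
        blocked_rows = np.flatnonzero(grid.occupancy.any(axis=1))
        # 1 m footprint + 0.3 m inflation on both sides -> >= 1.6 m across
        assert (blocked_cols.max() - blocked_cols.min() + 1) * 0.1 >= 1.6
        assert (blocked_rows.max() - blocked_rows.min() + 1) * 0.1 >= 1.6

    def test_tka2_left_workplace2_is_crowded_shut(self):
        layout = fixtures.load_fixture("TKA2", "left")
        grid = rasterize(layout)
        assert grid.blocked(layout.plan.destinations["WP2"])

    def test_coarse_cells_warn(self, minimal_doc):
        layout = load_layout(minimal_doc)
        with pytest.warns(UserWarning, match="coarse"):
            rasterize(layout, cell_size=1.0)


class TestShortestPath:
    def test_straight_line_in_empty_room(self):
        grid = empty_grid()
        path = shortest_path(grid, (1.0, 1.0), (4.0, 1.0))
        assert path.length == pytest.approx(3.0, abs=2 * grid.cell_size)
        assert all(not grid.blocked(p) for p in path.waypoints)

    def test_enclosed_goal_raises_unreachable(self):
        occ = np.zeros((10, 10), dtype=bool)
        occ[4:7, 4:7] = True
        occ[5, 5] = False  # free cell sealed inside a ring
        grid = grid_from_occupancy(occ)
        with pytest.raises(UnreachableError, match="goal"):
            shortest_path(grid, (0.5, 0.5), (5.5, 5.5))

    def test_blocked_endpoint_rejected(self):
        occ = np.zeros((10, 10), dtype=bool)
        occ[2, 2] = True
        grid = grid_from_occupancy(occ)
        with pytest.raises(ValueError, match="blocked"):
            shortest_path(grid, (2.5, 2.5), (8.5, 8.5))

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce_and_invariants(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        occ = rng.random((12, 12)) < 0.25
        occ[0, 0] = occ[-1, -1] = False
        grid = grid_from_occupancy(occ)
        start, goal = (0.5, 0.5), (11.5, 11.5)
        expected = oracle_length(grid, start, goal)
        if expected is None:
            with pytest.raises(UnreachableError):
                shortest_path(grid, start, goal)
            return
        path = shortest_path(grid, start, goal)
        assert path.length == pytest.approx(expected, abs=1e-9)
        # symmetry and the Euclidean lower bound
        assert shortest_path(grid, goal, start).length == pytest.approx(path.length, abs=1e-9)
        assert path.length >= math.hypot(goal[0] - start[0], goal[1] - start[1]) - 1e-9

    @given(data=st.data())
    @settings(max_examples=20, deadline=None)
    def test_removing_an_obstacle_never_lengthens_the_path(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        occ = rng.random((10, 10)) < 0.2
        occ[0, 0] = occ[-1, -1] = False
        grid = grid_from_occupancy(occ)
        start, goal = (0.5, 0.5), (9.5, 9.5)
        if oracle_length(grid, start, goal) is None:
            return
        base = shortest_path(grid, start, goal).length
        blocked = np.argwhere(occ)
        if len(blocked) == 0:
            return
        j, i = blocked[rng.integers(len(blocked))]
        occ2 = occ.copy()
        occ2[j, i] = False
        assert shortest_path(grid_from_occupancy(occ2), start, goal).length <= base + 1e-9


class TestDistanceMap:
    def test_agrees_with_point_to_point_search(self):
        rng = np.random.default_rng(7)
        occ = rng.random((15, 15)) < 0.2
        occ[0, 0] = False
        grid = grid_from_occupancy(occ)
        dist = distance_map(grid, (0.5, 0.5))
        for j, i in [(14, 14), (3, 11), (10, 2)]:
            if occ[j, i]:
                continue
            goal = grid.center_of((j, i))
            if math.isinf(dist[j, i]):
                with pytest.raises(UnreachableError):
                    shortest_path(grid, (0.5, 0.5), goal)
            else:
                assert dist[j, i] == pytest.approx(
                    shortest_path(grid, (0.5, 0.5), goal).length, abs=1e-9
                )
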