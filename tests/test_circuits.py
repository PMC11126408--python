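import math

import numpy as np
import pandas as pd
import pytest

from ginet import (
    BarrierMap,
    CircuitGraph,
    Corridor,
    Grid,
    barrier_scan,
    cost_distance,
    hub_centrality,
    improvement_area_table,
    improvement_shares,
    least_cost_path,
    pinchpoint_map,
    solve_pair,
)
from ginet.circuits import grid_circuit
from ginet.patches import Patch

from oracles import dense_circuit_solve


def strip_patch(i, rows, cols):
    return Patch(i, "core", np.asarray(rows), np.asarray(cols), len(np.asarray(rows)) * 0.09)


class TestSolvePair:
    def test_series_chain(self):
        g = CircuitGraph(3, [[0, 1], [1, 2]], [1.0, 1.0])
        sol = solve_pair(g, [0], [2], current=1.0)
        assert sol.node_currents[1] == pytest.approx(1.0)
        assert sol.effective_resistance == pytest.approx(2.0)

    def test_parallel_paths(self):
        g = CircuitGraph(4, [[0, 1], [1, 3], [0, 2], [2, 3]], [1.0] * 4)
        sol = solve_pair(g, [0], [3], current=1.0)
        assert np.allclose(np.abs(sol.branch_currents), 0.5)
        assert sol.effective_resistance == pytest.approx(1.0)

    def test_matches_dense_solver_on_random_graphs(self, rng):
        """Potentials agree with a dense reduced-Laplacian solve on 8 nodes."""
        for _ in range(5):
            edges = []
            for i in range(8):
                for j in range(i + 1, 8):
                    if rng.random() < 0.5:
                        edges.append((i, j))
            edges.extend((i, i + 1) for i in range(7))  # ensure connectivity
            edges = sorted(set(edges))
            res = rng.uniform(0.5, 5.0, len(edges))
            g = CircuitGraph(8, np.array(edges), res)
            sol = solve_pair(g, [0], [7], current=1.0)
            v = dense_circuit_solve(8, edges, res, 0, 7, 1.0)
            assert np.allclose(sol.potentials, v, atol=1e-9)

    def test_reciprocity(self, rng):
        edges = [(0, 1), (1, 2), (2, 3), (0, 2), (1, 3)]
        res = rng.uniform(0.5, 3.0, len(edges))
        g = CircuitGraph(4, np.array(edges), res)
        fwd = solve_pair(g, [0], [3])
        rev = solve_pair(g, [3], [0])
        assert np.allclose(fwd.branch_currents, -rev.branch_currents, atol=1e-12)
        assert np.allclose(fwd.node_currents, rev.node_currents, atol=1e-12)
        assert fwd.effective_resistance == pytest.approx(rev.effective_resistance)

    def test_effective_resistance_below_least_cost_path(self, rng):
        """Parallel routes only help: R_eff <= cheapest single-path resistance."""
        res = rng.uniform(1.0, 10.0, (7, 7))
        grid = Grid(res, 30.0)
        src = strip_patch(0, [0], [0])
        tgt = strip_patch(1, [6], [6])
        cd = cost_distance(grid, src)
        lcp = least_cost_path(cd, tgt, 30.0)
        circuit, node_of = grid_circuit(grid, np.ones((7, 7), bool))
        sol = solve_pair(circuit, [node_of[0]], [node_of[6 * 7 + 6]])
        assert sol.effective_resistance <= lcp.mcr + 1e-9

    def test_disconnected_components_fail(self):
        g = CircuitGraph(4, [[0, 1], [2, 3]], [1.0, 1.0])
        with pytest.raises(ValueError, match="component"):
            solve_pair(g, [0], [3])

    def test_contracted_patch_sets(self):
        # two cells contracted into the source behave as one node
        g = CircuitGraph(4, [[0, 2], [1, 2], [2, 3]], [2.0, 2.0, 1.0])
        sol = solve_pair(g, [0, 1], [3])
        assert sol.effective_resistance == pytest.approx(2.0)  # 2||2 + 1


class TestHubCentrality:
    def test_two_hubs_symmetric(self):
        cors = [Corridor(pair=(5, 9), mcr=100.0, length_m=10.0)]
        t = hub_centrality(cors, [5, 9])
        assert t.centrality.nunique() == 1

    def test_chain_middle_highest(self):
        cors = [
            Corridor(pair=(0, 1), mcr=50.0, length_m=1.0),
            Corridor(pair=(1, 2), mcr=50.0, length_m=1.0),
        ]
        t = hub_centrality(cors, [0, 1, 2]).set_index("hub")
        assert t.loc[1, "centrality"] > t.loc[0, "centrality"]
        assert t.loc[0, "centrality"] == pytest.approx(t.loc[2, "centrality"])

    def test_star_center_highest_leaves_equal(self):
        cors = [Corridor(pair=(0, k), mcr=10.0, length_m=1.0) for k in range(1, 6)]
        t = hub_centrality(cors, list(range(6))).set_index("hub")
        leaves = t.loc[1:, "centrality"]
        assert np.allclose(leaves, leaves.iloc[0])
        assert t.loc[0, "centrality"] > leaves.iloc[0]
        assert t.loc[0, "level"] == "high"

    def test_fewer_than_two_hubs(self):
        with pytest.raises(ValueError):
            hub_centrality([], [1])


class TestPinchPoints:
    def test_single_cell_neck_carries_full_current(self):
        """A 1-cell cut between the hubs must carry the entire injected ampere."""
        res = np.full((7, 9), -9999.0)
        res[:, :3] = 1.0
        res[:, 6:] = 1.0
        res[3, 3:6] = 1.0  # the only crossing
        grid = Grid(res, 30.0, nodata=-9999.0)
        a = strip_patch(0, [3], [0])
        b = strip_patch(1, [3], [8])
        cd = cost_distance(grid, a)
        cor = least_cost_path(cd, b, 30.0)
        out = pinchpoint_map(grid, [a, b], [cor], swath_cutoff=5.0)
        cur = np.asarray(out.current.values)
        assert cur[3, 4] == pytest.approx(1.0, abs=1e-8)
        assert (3, 4) in set(map(tuple, out.pinch_cells))

    def test_wide_uniform_swath_has_no_hotspot(self):
        """An 11-cell-wide uniform corridor spreads current: no cell above 2x mean."""
        res = np.ones((11, 30))
        grid = Grid(res, 30.0)
        a = strip_patch(0, np.arange(11), np.zeros(11, int))
        b = strip_patch(1, np.arange(11), np.full(11, 29))
        cd = cost_distance(grid, a)
        cor = least_cost_path(cd, b, 30.0)
        out = pinchpoint_map(grid, [a, b], [cor], swath_cutoff=10.0)
        cur = np.asarray(out.current.values)
        interior = cur[:, 5:25]
        assert interior.max() <= 2.0 * interior.mean()


class TestBarriers:
    def test_window_far_from_swath_is_zero(self):
        res = np.ones((20, 40))
        res[:, 18:22] = 300.0
        grid = Grid(res, 30.0)
        a = strip_patch(0, [10], [2])
        b = strip_patch(1, [10], [37])
        cd = cost_distance(grid, a)
        cor = least_cost_path(cd, b, 30.0)
        bm = barrier_scan(grid, [a, b], [cor], search_radius_m=60.0)
        ismap = np.asarray(bm.improvement.values)
        assert ismap[0, 0] == 0.0  # corner far from the corridor
        assert np.all(ismap >= 0.0)  # dLCD >= 0 everywhere
        # the expensive crossing is where improvement concentrates
        r, c = np.unravel_index(np.argmax(ismap), ismap.shape)
        assert 16 <= c <= 24

    def test_improvement_score_arithmetic(self):
        """IS = dLCD / D, checked on a strip whose dLCD is hand-computable."""
        res = np.ones((1, 7))
        res[0, 3] = 301.0
        grid = Grid(res, 30.0)
        a = strip_patch(0, [0], [0])
        b = strip_patch(1, [0], [6])
        cd = cost_distance(grid, a)
        cor = least_cost_path(cd, b, 30.0)
        # LCD0 = 30 * (1 + 1 + 151 + 151 + 1 + 1) = 9180
        assert cor.mcr == pytest.approx(9180.0)
        bm = barrier_scan(grid, [a, b], [cor], search_radius_m=60.0, swath_cutoff=0.5)
        # window at the expensive cell spans cells 1..5: LCD1 = cd_a(1) + cd_b(5)
        # = 30 + 30, so dLCD = 9120 and IS = 9120 / 60 = 152
        assert bm.improvement.values[0, 3] == pytest.approx(9120.0 / 60.0)

    def test_radius_below_cell_size_rejected(self):
        with pytest.raises(ValueError):
            barrier_scan(Grid(np.ones((4, 4)), 30.0), [], [Corridor((0, 1), 1.0, 1.0)], 10.0)


class TestImprovementTable:
    def test_level_shares(self):
        assert improvement_shares({1: 100.0, 2: 100.0, 3: 200.0}) == {
            1: 25.0, 2: 25.0, 3: 50.0,
        }

    def test_single_region(self):
        cls = np.zeros((10, 10), dtype=np.uint8)
        cls[4, :] = 0
        cls[2, 2:7] = 1
        cls[3, 2:7] = 1
        bm = BarrierMap(
            improvement=Grid(np.zeros((10, 10)), 30.0),
            classes=Grid(cls, 30.0),
            search_radius_m=60.0,
            breaks=np.empty(0),
        )
        t = improvement_area_table(bm).set_index("level")
        assert t.loc[1, "region_count"] == 1
        assert t.loc[1, "area_ha"] == pytest.approx(0.90)
        assert t.loc[1, "pct_of_improvement_area"] == 100.0

    def test_empty(self):
        bm = BarrierMap(
            improvement=Grid(np.zeros((4, 4)), 30.0),
            classes=Grid(np.zeros((4, 4), dtype=np.uint8), 30.0),
            search_radius_m=60.0,
            breaks=np.empty(0),
        )
        assert len(improvement_area_table(bm)) == 0
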