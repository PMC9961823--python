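import math

import numpy as np
import pytest

from econet.corridors import (
    Corridor,
    cost_distance,
    gravity_matrix,
    least_cost_corridors,
    rank_corridors,
)
from econet.geometry import GridGeometry
from econet.resistance import ResistanceSurface

from conftest import patch_from_cells
from oracles import brute_cost_distance


def surface(values, cell: float = 30.0) -> ResistanceSurface:
    values = np.asarray(values, dtype=float)
    g = GridGeometry(values.shape[0], values.shape[1], cell)
    return ResistanceSurface(geometry=g, values=values)


class TestCostDistance:
    def test_uniform_rook_line(self):
        s = surface(np.full((1, 11), 2.0))
        cdm = cost_distance(s, [(0, 0)])
        assert cdm.cost[0, 10] == pytest.approx(600.0)  # 10 steps * 30 m * R 2

    def test_source_cost_zero(self):
        s = surface(np.full((6, 6), 3.0))
        cdm = cost_distance(s, [(2, 3), (5, 5)])
        assert cdm.cost[2, 3] == 0.0
        assert cdm.cost[5, 5] == 0.0

    def test_diagonal_step_cost(self):
        s = surface(np.full((2, 2), 1.0))
        cdm = cost_distance(s, [(0, 0)])
        assert cdm.cost[1, 1] == pytest.approx(30.0 * math.sqrt(2.0))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_dijkstra(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(1.0, 5.0, size=(15, 15))
        s = surface(vals)
        src = [(int(rng.integers(15)), int(rng.integers(15)))]
        cdm = cost_distance(s, src)
        expected = brute_cost_distance(vals, 30.0, src)
        np.testing.assert_allclose(cdm.cost, expected, rtol=1e-10)

    def test_backtrack_path_cost_consistent(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1.0, 5.0, size=(12, 12))
        s = surface(vals)
        cdm = cost_distance(s, [(0, 0)])
        path = cdm.backtrack(11, 11)
        assert path[0] == (0, 0) and path[-1] == (11, 11)
        total = 0.0
        for (r1, c1), (r2, c2) in zip(path[:-1], path[1:]):
            m = math.sqrt(2.0) if (r1 != r2 and c1 != c2) else 1.0
            total += 30.0 * m * 0.5 * (vals[r1, c1] + vals[r2, c2])
        assert total == pytest.approx(cdm.cost[11, 11])

    def test_empty_sources_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cost_distance(surface(np.ones((3, 3))), [])

    def test_nonpositive_resistance_rejected(self):
        g = GridGeometry(3, 3, 30.0)
        vals = np.ones((3, 3))
        vals[1, 1] = 0.0
        with pytest.raises(ValueError):
            # bypass ResistanceSurface validation to hit the graph check
            bad = ResistanceSurface.__new__(ResistanceSurface)
            object.__setattr__(bad, "geometry", g)
            object.__setattr__(bad, "values", vals)
            cost_distance(bad, [(0, 0)])


class TestLeastCostCorridors:
    def test_count_law(self, geom):
        g = GridGeometry(20, 20, 30.0)
        s = ResistanceSurface(geometry=g, values=np.ones(g.shape))
        rng = np.random.default_rng(0)
        cells = rng.choice(400, size=5, replace=False)
        patches = [patch_from_cells(k, [(c // 20, c % 20)], g) for k, c in enumerate(cells)]
        corridors = least_cost_corridors(s, patches)
        assert len(corridors) == 5 * 4 // 2

    def test_two_sources_uniform_straight_path(self):
        s = surface(np.ones((9, 9)))
        a = patch_from_cells(1, [(4, 0)], s.geometry)
        b = patch_from_cells(2, [(4, 8)], s.geometry)
        (c,) = least_cost_corridors(s, [a, b])
        rows = {p[0] for p in c.path}
        assert rows == {4}  # pure rook line along the shared row
        assert c.cost == pytest.approx(8 * 30.0)

    def test_wall_with_gap_routes_through_gap(self):
        vals = np.ones((11, 11))
        vals[:, 3:8] = 5.0
        vals[9, 3:8] = 1.0  # the gap row
        s = surface(vals)
        a = patch_from_cells(1, [(1, 1)], s.geometry)
        b = patch_from_cells(2, [(1, 9)], s.geometry)
        (c,) = least_cost_corridors(s, [a, b])
        wall_cells = [p for p in c.path if 3 <= p[1] <= 7]
        assert all(p[0] == 9 for p in wall_cells)
        # and the cost matches the independent Dijkstra oracle
        expected = brute_cost_distance(vals, 30.0, [(1, 1)])[1, 9]
        assert c.cost == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(1.0, 5.0, size=(14, 14))
        s = surface(vals)
        patches = [
            patch_from_cells(1, [(2, 2), (2, 3)], s.geometry),
            patch_from_cells(2, [(11, 11)], s.geometry),
        ]
        (fwd,) = least_cost_corridors(s, patches)
        (rev,) = least_cost_corridors(s, patches[::-1])
        assert fwd.cost == pytest.approx(rev.cost, abs=1e-9)

    def test_single_source_rejected(self):
        s = surface(np.ones((4, 4)))
        with pytest.raises(ValueError, match="two source"):
            least_cost_corridors(s, [patch_from_cells(1, [(0, 0)], s.geometry)])

    @pytest.mark.parametrize("trial", range(5))
    def test_raising_resistance_never_lowers_costs(self, trial):
        rng = np.random.default_rng(200 + trial)
        vals = rng.uniform(1.0, 4.0, size=(12, 12))
        s = surface(vals)
        patches = [
            patch_from_cells(1, [(1, 1)], s.geometry),
            patch_from_cells(2, [(10, 10)], s.geometry),
            patch_from_cells(3, [(1, 10)], s.geometry),
        ]
        base = {(c.i, c.j): c.cost for c in least_cost_corridors(s, patches)}
        r, c_ = rng.integers(12), rng.integers(12)
        vals2 = vals.copy()
        vals2[r, c_] = min(5.0, vals2[r, c_] + rng.uniform(0.5, 1.0))
        bumped = {(c.i, c.j): c.cost for c in least_cost_corridors(surface(vals2), patches)}
        for pair, cost in base.items():
            assert bumped[pair] >= cost - 1e-9


class TestGravity:
    def _uniform_setup(self, n_cells_each=31):
        # each patch ~ e hectares so ln(S) = 1 exactly when cell area is e/n ha
        cell = math.sqrt(math.e * 1e4 / n_cells_each)
        g = GridGeometry(10, 50, cell)
        a = patch_from_cells(1, [(1, c) for c in range(n_cells_each)], g)
        b = patch_from_cells(2, [(8, c) for c in range(n_cells_each)], g)
        s = ResistanceSurface(geometry=g, values=np.ones(g.shape))
        return g, s, a, b

    def test_unit_case_g_equals_one(self):
        _, s, a, b = self._uniform_setup()
        corridors = [Corridor(i=1, j=2, path=((1, 0), (8, 0)), cost=1234.5)]
        gm = gravity_matrix([a, b], corridors, s)
        assert gm.S_ha[0] == pytest.approx(math.e)
        assert gm.P[0] == pytest.approx(1.0)
        assert gm.G[0, 1] == pytest.approx(1.0)  # L == L_max, ln S = 1, P = 1

    def test_monotone_decreasing_in_cost(self, geom):
        g = geom(20, 20)
        s = ResistanceSurface(geometry=g, values=np.ones(g.shape))
        patches = [patch_from_cells(k, [(k * 4, c) for c in range(20)], g) for k in (1, 2, 3, 4)]
        corridors = [
            Corridor(i=i, j=j, path=(), cost=1000.0 * (i + j))
            for a_, i in enumerate((1, 2, 3, 4))
            for j in (2, 3, 4)
            if j > i
        ]
        gm = gravity_matrix(patches, corridors, s)
        # equal masses: G ordering is the reverse of the L ordering
        ids = {pid: k for k, pid in enumerate(gm.ids)}
        costs = {(c.i, c.j): c.cost for c in corridors}
        pairs = sorted(costs, key=lambda p: costs[p])
        gs = [gm.G[ids[i], ids[j]] for i, j in pairs]
        assert all(x >= y - 1e-12 for x, y in zip(gs[:-1], gs[1:]))

    def test_matches_direct_formula(self, geom):
        g = geom(30, 30)
        rng = np.random.default_rng(7)
        vals = rng.uniform(1.0, 5.0, size=g.shape)
        s = ResistanceSurface(geometry=g, values=vals)
        patches = [
            patch_from_cells(k + 1, [(k * 6 + r, c) for r in range(3) for c in range(5)], g)
            for k in range(4)
        ]
        corridors = []
        for x in range(4):
            for y in range(x + 1, 4):
                corridors.append(Corridor(i=x + 1, j=y + 1, path=(), cost=float(rng.uniform(500, 5000))))
        gm = gravity_matrix(patches, corridors, s)
        L = {(c.i, c.j): c.cost for c in corridors}
        L_max = max(L.values())
        for x in range(4):
            for y in range(x + 1, 4):
                S_x = patches[x].n_cells * g.cell_area_m2 * 1e-4
                S_y = patches[y].n_cells * g.cell_area_m2 * 1e-4
                P_x = vals[patches[x].rows, patches[x].cols].mean()
                P_y = vals[patches[y].rows, patches[y].cols].mean()
                expected = L_max**2 * math.log(S_x) * math.log(S_y) / (
                    L[(x + 1, y + 1)] ** 2 * P_x * P_y
                )
                assert gm.G[x, y] == pytest.approx(expected, rel=1e-12)
        np.testing.assert_allclose(gm.G, gm.G.T, atol=1e-9)
        np.testing.assert_allclose(gm.L, gm.L.T, atol=1e-9)
        assert (np.diag(gm.G) == 0).all()

    def test_small_patch_rejected(self, geom):
        g = geom(5, 5, cell_size=30.0)  # single 30 m cell = 0.09 ha < 1 ha
        s = ResistanceSurface(geometry=g, values=np.ones(g.shape))
        patches = [patch_from_cells(1, [(0, 0)], g), patch_from_cells(2, [(4, 4)], g)]
        corridors = [Corridor(i=1, j=2, path=(), cost=100.0)]
        with pytest.raises(ValueError, match="1 ha"):
            gravity_matrix(patches, corridors, s)

    def test_sum_mode(self, geom):
        g = geom(10, 10, cell_size=200.0)
        s = ResistanceSurface(geometry=g, values=np.full(g.shape, 2.0))
        patches = [
            patch_from_cells(1, [(0, c) for c in range(3)], g),
            patch_from_cells(2, [(9, c) for c in range(3)], g),
        ]
        corridors = [Corridor(i=1, j=2, path=(), cost=700.0)]
        gm = gravity_matrix(patches, corridors, s, patch_resistance="sum")
        assert gm.P[0] == pytest.approx(6.0)


class TestRankCorridors:
    def _ranked(self, n=10, top_k=3, seed=0):
        g = GridGeometry(40, 40, 60.0)
        s = ResistanceSurface(geometry=g, values=np.ones(g.shape))
        rng = np.random.default_rng(seed)
        patches = [
            patch_from_cells(k + 1, [(3 * k, c) for c in range(6)], g) for k in range(n)
        ]
        corridors = [
            Corridor(i=i + 1, j=j + 1, path=(), cost=float(rng.uniform(1000, 9000)))
            for i in range(n)
            for j in range(i + 1, n)
        ]
        gm = gravity_matrix(patches, corridors, s)
        return rank_corridors(gm, corridors, top_k=top_k)

    def test_flag_counts(self):
        ranked = self._ranked(n=10, top_k=15)
        assert len(ranked) == 45
        assert sum(c.important for c in ranked) == 15

    def test_top_k_zero(self):
        ranked = self._ranked(top_k=0)
        assert not any(c.important for c in ranked)

    def test_sorted_by_gravity(self):
        ranked = self._ranked(top_k=5)
        gs = [c.gravity for c in ranked]
        assert gs == sorted(gs, reverse=True)
        assert [c.rank for c in ranked] == list(range(1, len(ranked) + 1))

    def test_all_equal_gravity_tie_order(self, geom):
        g = geom(30, 30, cell_size=100.0)
        s = ResistanceSurface(geometry=g, values=np.ones(g.shape))
        patches = [patch_from_cells(k, [(5 * (k - 1), c) for c in range(4)], g) for k in (1, 2, 3)]
        corridors = [
            Corridor(i=1, j=2, path=(), cost=2000.0),
            Corridor(i=1, j=3, path=(), cost=2000.0),
            Corridor(i=2, j=3, path=(), cost=2000.0),
        ]
        gm = gravity_matrix(patches, corridors, s)
        ranked = rank_corridors(gm, corridors, top_k=2)
        assert [(c.i, c.j) for c in ranked] == [(1, 2), (1, 3), (2, 3)]
        assert [c.important for c in ranked] == [True, True, False]
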