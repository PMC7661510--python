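"""Transition graph and least-cost distances, checked against brute force."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from reefadapt import graph, synthetic
from reefadapt.core import CurrentField, ReefGrid


def _uniform_field(ny, nx, u=0.0, v=0.0, res=1.0, sea=None):
    sea = np.ones((ny, nx), bool) if sea is None else sea
    return CurrentField(u=np.where(sea, u, np.nan), v=np.where(sea, v, np.nan),
                        resolution_km=res, sea_mask=sea)


def _line_grid(n, res=1.0):
    """n reef cells along a 1-row raster, cell i at pixel (0, i)."""
    cells = pd.DataFrame({"cell_id": np.arange(n), "x": np.arange(n),
                          "y": 0, "area_km2": 1.0})
    return ReefGrid(cells=cells, shape=(1, n), resolution_km=res)


def _graph_from_matrix(cost: np.ndarray) -> graph.TransitionGraph:
    """A transition graph with explicit edge costs, nodes on a 1-row raster."""
    n = cost.shape[0]
    node_index = np.full((1, n), -1, dtype=np.int64)
    node_index[0] = np.arange(n)
    return graph.TransitionGraph(costs=sp.csr_matrix(cost),
                                 node_index=node_index,
                                 node_yx=np.column_stack([np.zeros(n, int),
                                                          np.arange(n)]),
                                 resolution_km=1.0)


class TestTemporalMean:
    def test_constant_and_single_day(self):
        u = np.full((1, 2, 2), 0.3)
        f = graph.temporal_mean_field(u, -u, 1.0)
        np.testing.assert_allclose(f.u, 0.3)
        np.testing.assert_allclose(f.v, -0.3)

    def test_alternating_mean_zero(self):
        u = np.stack([np.ones((2, 2)), -np.ones((2, 2))] * 3)
        f = graph.temporal_mean_field(u, u, 1.0)
        np.testing.assert_allclose(f.u, 0.0)

    def test_pixel_without_observations_marked_non_sea(self):
        u = np.full((3, 2, 2), 0.1)
        u[:, 0, 0] = np.nan
        f = graph.temporal_mean_field(u, u, 1.0)
        assert not f.sea_mask[0, 0] and f.sea_mask[1, 1]


class TestResample:
    def test_constant_preserved(self):
        f = graph.resample_bilinear(_uniform_field(3, 3, u=0.2, res=3.0), 1.0)
        np.testing.assert_allclose(f.u, 0.2)
        assert f.shape == (9, 9)
        assert f.resolution_km == 1.0

    def test_linear_ramp_reproduced(self):
        # bilinear interpolation is exact for affine fields (inside the hull
        # of source centers; the rim is constant-extrapolated)
        ny, nx, res = 4, 5, 2.0
        xs = (np.arange(nx) + 0.5) * res
        u = np.tile(0.1 * xs, (ny, 1))
        field = CurrentField(u=u, v=np.zeros_like(u), resolution_km=res,
                             sea_mask=np.ones((ny, nx), bool))
        fine = graph.resample_bilinear(field, 1.0)
        fx = (np.arange(nx * 2) + 0.5) * 1.0
        expected = 0.1 * np.clip(fx, xs[0], xs[-1])
        np.testing.assert_allclose(fine.u[2], expected, atol=1e-12)

    def test_source_centers_preserved_odd_factor(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(3, 4))
        field = CurrentField(u=u, v=u, resolution_km=3.0,
                             sea_mask=np.ones((3, 4), bool))
        fine = graph.resample_bilinear(field, 1.0)
        np.testing.assert_allclose(fine.u[1::3, 1::3], u, atol=1e-12)

    def test_coarser_target_rejected(self):
        with pytest.raises(ValueError):
            graph.resample_bilinear(_uniform_field(3, 3, res=1.0), 2.0)


class TestLandMask:
    def test_all_sea_unchanged(self):
        f = _uniform_field(3, 3, u=0.1)
        g = graph.apply_land_mask(f, np.zeros((3, 3), bool))
        np.testing.assert_allclose(g.u, f.u)

    def test_land_pixel_absent_from_graph(self):
        f = _uniform_field(1, 3)
        land = np.zeros((1, 3), bool)
        land[0, 1] = True
        tg = graph.build_transition_graph(graph.apply_land_mask(f, land), 8, 0.01)
        assert tg.n_nodes == 2
        assert tg.costs.nnz == 0  # end pixels are no longer adjacent

    def test_land_wall_disconnects(self):
        f = _uniform_field(3, 5)
        land = np.zeros((3, 5), bool)
        land[:, 2] = True
        tg = graph.build_transition_graph(graph.apply_land_mask(f, land), 8, 0.01)
        grid = _line_grid(5)
        d = graph.least_cost_matrix(tg, grid).d
        assert np.isinf(d[0, 4]) and np.isinf(d[4, 0])
        assert np.isfinite(d[0, 1])

    def test_all_land_rejected(self):
        with pytest.raises(ValueError):
            graph.apply_land_mask(_uniform_field(2, 2), np.ones((2, 2), bool))


class TestTransitionGraph:
    def test_downstream_cheaper_than_upstream(self):
        tg = graph.build_transition_graph(_uniform_field(1, 2, u=0.1), 4, 0.01)
        east = tg.costs[0, 1]
        west = tg.costs[1, 0]
        assert east == pytest.approx(1.0 / 0.11)
        assert west == pytest.approx(1.0 / 0.01)

    def test_zero_current_symmetric(self):
        tg = graph.build_transition_graph(_uniform_field(3, 3), 8, 0.01)
        dense = tg.costs.toarray()
        np.testing.assert_allclose(dense, dense.T)
        assert dense[0, 1] == pytest.approx(1.0 / 0.01)
        # diagonal steps cost sqrt(2) more
        d01 = tg.node_index[0, 1]
        d11 = tg.node_index[1, 1]
        assert dense[tg.node_index[0, 0], d11] == pytest.approx(np.sqrt(2) / 0.01)

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            graph.build_transition_graph(_uniform_field(2, 2), 8, 0.0)


class TestLeastCost:
    def test_three_node_shortcut(self):
        cost = np.array([[0.0, 1.0, 4.0], [0.0, 0.0, 2.0], [0.0, 0.0, 0.0]])
        tg = _graph_from_matrix(cost)
        d = graph.least_cost_matrix(tg, _line_grid(3)).d
        assert d[0, 2] == pytest.approx(3.0)  # min(4, 1 + 2)
        assert np.isinf(d[2, 0])
        assert d[0, 0] == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        dense = np.zeros((n, n))
        mask = rng.random((n, n)) < 0.3
        np.fill_diagonal(mask, False)
        dense[mask] = rng.uniform(0.5, 2.0, mask.sum())
        tg = _graph_from_matrix(dense)
        d = graph.least_cost_matrix(tg, _line_grid(n)).d
        G = nx.from_numpy_array(dense, create_using=nx.DiGraph)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                best = np.inf
                for path in nx.all_simple_paths(G, i, j):
                    w = sum(dense[a, b] for a, b in zip(path, path[1:]))
                    best = min(best, w)
                assert d[i, j] == pytest.approx(best) or (
                    np.isinf(d[i, j]) and np.isinf(best))

    def test_current_reversal_transposes_matrix(self, small_grid):
        u, v = synthetic.gen_current_field(small_grid, 0.05, -0.03, 0.04, 10, seed=2)
        f = graph.temporal_mean_field(u, v, small_grid.resolution_km)
        rev = CurrentField(u=-f.u, v=-f.v, resolution_km=f.resolution_km,
                           sea_mask=f.sea_mask)
        d_fwd = graph.least_cost_matrix(
            graph.build_transition_graph(f, 8, 0.01), small_grid).d
        d_rev = graph.least_cost_matrix(
            graph.build_transition_graph(rev, 8, 0.01), small_grid).d
        np.testing.assert_allclose(d_rev, d_fwd.T)

    def test_directed_triangle_inequality(self, small_grid):
        u, v = synthetic.gen_current_field(small_grid, -0.05, 0.0, 0.03, 10, seed=4)
        f = graph.temporal_mean_field(u, v, small_grid.resolution_km)
        d = graph.least_cost_matrix(
            graph.build_transition_graph(f, 8, 0.01), small_grid).d
        n = d.shape[0]
        via = d[:, :, None] + d[None, :, :]        # d(i,j) + d(j,k)
        assert np.all(d[:, None, :] <= via.transpose(0, 1, 2) + 1e-9)

    def test_stronger_drift_monotone(self):
        grid = _line_grid(4)
        weak = graph.build_transition_graph(_uniform_field(1, 4, u=0.05), 4, 0.01)
        strong = graph.build_transition_graph(_uniform_field(1, 4, u=0.2), 4, 0.01)
        d_w = graph.least_cost_matrix(weak, grid).d
        d_s = graph.least_cost_matrix(strong, grid).d
        iu = np.triu_indices(4, 1)
        assert np.all(d_s[iu] <= d_w[iu])          # downstream (eastward) cheaper
        il = np.tril_indices(4, -1)
        assert np.all(d_s[il] >= d_w[il])          # upstream never cheaper


class TestBorderDistances:
    def test_adjacent_downstream_edge(self):
        # reef at the center of a 3x3 raster; every other pixel is border
        tg = graph.build_transition_graph(_uniform_field(3, 3, u=0.1), 4, 0.01)
        cells = pd.DataFrame({"cell_id": [0], "x": [1], "y": [1], "area_km2": [1.0]})
        grid = ReefGrid(cells=cells, shape=(3, 3), resolution_km=1.0)
        b = graph.border_distances(tg, grid)
        assert b.loc[0, "to_border"] == pytest.approx(1.0 / 0.11)   # go east
        assert b.loc[0, "from_border"] == pytest.approx(1.0 / 0.11)  # arrive from west

    def test_zero_current_to_equals_from(self, small_grid):
        f = _uniform_field(*small_grid.shape, res=small_grid.resolution_km)
        tg = graph.build_transition_graph(f, 8, 0.01)
        b = graph.border_distances(tg, small_grid)
        np.testing.assert_allclose(b["to_border"], b["from_border"])

    def test_empty_border_rejected(self, small_grid):
        f = _uniform_field(*small_grid.shape, res=small_grid.resolution_km)
        tg = graph.build_transition_graph(f, 8, 0.01)
        with pytest.raises(ValueError):
            graph.border_distances(tg, small_grid, border_nodes=np.array([], int))


def test_cost_matrix_csv_roundtrip(tmp_path, small_grid):
    u, v = synthetic.gen_current_field(small_grid, -0.05, 0.0, 0.02, 5, seed=0)
    f = graph.temporal_mean_field(u, v, small_grid.resolution_km)
    cm = graph.least_cost_matrix(graph.build_transition_graph(f, 8, 0.01),
                                 small_grid)
    path = tmp_path / "costs.csv"
    cm.to_csv(path)
    back = graph.CostMatrix.from_csv(path)
    np.testing.assert_allclose(back.d, cm.d)
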