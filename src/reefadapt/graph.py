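"""Directed, current-driven transition graph and least-cost distances.

The sea is discretized into pixels; each ordered pair of adjacent sea
pixels gets a directed edge whose cost is the pixel-center distance divided
by a conductance.  Conductance is the downstream-projected mean current
between the two pixels plus a small base term ε (m/s) representing
current-independent diffusion, so transport with the current is cheap and
against it costs at most L/ε.  This is the package's codification of
"transition costs inversely proportional to the transition frequency
implied by the currents"; ε is the main modelling knob.

Axes convention: column index increases eastward, row index increases
northward (u is the eastward, v the northward velocity).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import distance_transform_edt
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from reefadapt.core import CurrentField, ReefGrid

DEFAULT_EPSILON = 0.01  # m/s; base conductance

_OFFSETS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
_OFFSETS_8 = _OFFSETS_4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


@dataclass
class TransitionGraph:
    """Sparse directed graph over sea pixels.

    ``costs`` is CSR with strictly positive finite entries on edges;
    ``node_index`` maps (row, col) to node id (−1 off-sea);
    ``node_yx`` is (n_nodes, 2) of (row, col).
    """

    costs: sp.csr_matrix
    node_index: np.ndarray
    node_yx: np.ndarray
    resolution_km: float

    @property
    def n_nodes(self) -> int:
        return self.costs.shape[0]

    def node_centers_km(self) -> np.ndarray:
        """(n_nodes, 2) pixel-center coordinates (x_east_km, y_north_km)."""
        return np.column_stack([
            (self.node_yx[:, 1] + 0.5) * self.resolution_km,
            (self.node_yx[:, 0] + 0.5) * self.resolution_km,
        ])

    def nearest_nodes(self, coords_km: np.ndarray) -> np.ndarray:
        """Node ids of the sea pixels nearest the given (x, y) km points."""
        tree = cKDTree(self.node_centers_km())
        _, idx = tree.query(np.atleast_2d(coords_km))
        return idx

    def border_nodes(self) -> np.ndarray:
        """Node ids of sea pixels on the raster boundary (the study-area border)."""
        ny = self.node_index.shape[0]
        nx = self.node_index.shape[1]
        yx = self.node_yx
        on_edge = (yx[:, 0] == 0) | (yx[:, 0] == ny - 1) | (yx[:, 1] == 0) | (yx[:, 1] == nx - 1)
        nodes = np.flatnonzero(on_edge)
        if nodes.size == 0:
            raise ValueError("no sea pixels on the raster boundary")
        return nodes


@dataclass
class CostMatrix:
    """Directed least-cost distances between reef cells (cost units).

    ``d[i, j]`` is the cheapest directed path cost from cell i to cell j;
    unreachable pairs are +inf.
    """

    cell_ids: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.cell_ids), len(self.cell_ids)):
            raise ValueError("cost matrix shape does not match cell_ids")

    def to_csv(self, path: str | Path) -> None:
        n = len(self.cell_ids)
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        pd.DataFrame({
            "from_cell": np.asarray(self.cell_ids)[ii.ravel()],
            "to_cell": np.asarray(self.cell_ids)[jj.ravel()],
            "cost": self.d.ravel(),
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CostMatrix":
        long = pd.read_csv(path)
        wide = long.pivot(index="from_cell", columns="to_cell", values="cost")
        wide = wide.sort_index().sort_index(axis=1)
        return cls(cell_ids=wide.index.to_numpy(), d=wide.to_numpy())


def temporal_mean_field(u_stack: np.ndarray, v_stack: np.ndarray,
                        resolution_km: float,
                        sea_mask: np.ndarray | None = None) -> CurrentField:
    """Collapse daily u/v stacks to one static field by per-pixel means.

    Missing days (NaN) are excluded; a pixel with zero observations is
    marked non-sea.
    """
    u_stack = np.asarray(u_stack, dtype=float)
    v_stack = np.asarray(v_stack, dtype=float)
    if u_stack.ndim != 3 or u_stack.shape != v_stack.shape:
        raise ValueError("u/v stacks must be (time, ny, nx) and congruent")
    n_obs = np.isfinite(u_stack).sum(axis=0)
    denom = np.maximum(n_obs, 1)
    u = np.where(n_obs > 0, np.nansum(u_stack, axis=0) / denom, np.nan)
    v = np.where(n_obs > 0, np.nansum(v_stack, axis=0) / denom, np.nan)
    mask = n_obs > 0
    if sea_mask is not None:
        mask = mask & np.asarray(sea_mask, dtype=bool)
        u = np.where(mask, u, np.nan)
        v = np.where(mask, v, np.nan)
    return CurrentField(u=u, v=v, resolution_km=resolution_km, sea_mask=mask)


def _fill_from_sea(arr: np.ndarray, sea: np.ndarray) -> np.ndarray:
    """Replace non-sea values by the nearest sea value (for interpolation)."""
    if sea.all():
        return arr
    _, (iy, ix) = distance_transform_edt(~sea, return_indices=True)
    return arr[iy, ix]


def resample_bilinear(field: CurrentField, target_resolution_km: float) -> CurrentField:
    """Refine a current field by bilinear interpolation of u and v.

    The target resolution must divide the source resolution into an integer
    number of sub-pixels; source-pixel center values are preserved when the
    refinement factor is odd.  The sea mask is refined by pixel containment
    (each fine pixel inherits its coarse parent), and interpolation near
    the coast draws on nearest-sea values before re-masking.
    """
    if target_resolution_km >= field.resolution_km:
        raise ValueError("target resolution must be finer than the source")
    factor = field.resolution_km / target_resolution_km
    f = int(round(factor))
    if abs(factor - f) > 1e-9:
        raise ValueError("source resolution must be an integer multiple of the target")
    ny, nx = field.shape
    src_y = np.arange(ny) + 0.5
    src_x = np.arange(nx) + 0.5
    fine_y = (np.arange(ny * f) + 0.5) / f
    fine_x = (np.arange(nx * f) + 0.5) / f
    # clamp to the outermost centers: constant extrapolation at the rim
    fy = np.clip(fine_y, src_y[0], src_y[-1])
    fx = np.clip(fine_x, src_x[0], src_x[-1])
    pts = np.stack(np.meshgrid(fy, fx, indexing="ij"), axis=-1)
    out = []
    for arr in (field.u, field.v):
        interp = RegularGridInterpolator((src_y, src_x),
                                         _fill_from_sea(arr, field.sea_mask),
                                         method="linear")
        out.append(interp(pts))
    fine_mask = np.repeat(np.repeat(field.sea_mask, f, axis=0), f, axis=1)
    u, v = (np.where(fine_mask, a, np.nan) for a in out)
    return CurrentField(u=u, v=v, resolution_km=target_resolution_km,
                        sea_mask=fine_mask)


def apply_land_mask(field: CurrentField, land_mask: np.ndarray) -> CurrentField:
    """Remove velocity values on land pixels; those pixels leave the graph."""
    land = np.asarray(land_mask, dtype=bool)
    if land.shape != field.shape:
        raise ValueError("land mask shape does not match the field")
    sea = field.sea_mask & ~land
    if not sea.any():
        raise ValueError("land mask removes every sea pixel")
    return CurrentField(u=np.where(sea, field.u, np.nan),
                        v=np.where(sea, field.v, np.nan),
                        resolution_km=field.resolution_km, sea_mask=sea)


def build_transition_graph(field: CurrentField, neighborhood: int = 8,
                           base_conductance: float = DEFAULT_EPSILON) -> TransitionGraph:
    """Directed edges between adjacent sea pixels, cost = L / conductance.

    For the ordered pair i→j with unit direction d̂ and center distance L
    (km), conductance = max(0, mean(current_i, current_j)·d̂) + ε.
    """
    if base_conductance <= 0:
        raise ValueError("base conductance must be > 0 (costs would be infinite)")
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    sea = field.sea_mask
    if sea.sum() < 2:
        raise ValueError("need at least 2 sea pixels")
    ny, nx = field.shape
    node_index = np.full((ny, nx), -1, dtype=np.int64)
    node_yx = np.argwhere(sea)
    node_index[sea] = np.arange(len(node_yx))
    offsets = _OFFSETS_4 if neighborhood == 4 else _OFFSETS_8
    rows, cols, costs = [], [], []
    u = np.nan_to_num(field.u)
    v = np.nan_to_num(field.v)
    for dy, dx in offsets:
        # slices of overlapping source/destination pixels for this offset
        src_y = slice(max(0, -dy), ny - max(0, dy))
        src_x = slice(max(0, -dx), nx - max(0, dx))
        dst_y = slice(max(0, dy), ny - max(0, -dy))
        dst_x = slice(max(0, dx), nx - max(0, -dx))
        ok = sea[src_y, src_x] & sea[dst_y, dst_x]
        if not ok.any():
            continue
        i = node_index[src_y, src_x][ok]
        j = node_index[dst_y, dst_x][ok]
        norm = np.hypot(dx, dy)
        e_hat, n_hat = dx / norm, dy / norm  # row + = north, col + = east
        w_dot = 0.5 * ((u[src_y, src_x][ok] + u[dst_y, dst_x][ok]) * e_hat
                       + (v[src_y, src_x][ok] + v[dst_y, dst_x][ok]) * n_hat)
        conduct = np.maximum(0.0, w_dot) + base_conductance
        length = field.resolution_km * norm
        rows.append(i)
        cols.append(j)
        costs.append(length / conduct)
    if rows:
        mat = sp.csr_matrix(
            (np.concatenate(costs), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(node_yx), len(node_yx)))
    else:
        mat = sp.csr_matrix((len(node_yx), len(node_yx)))
    return TransitionGraph(costs=mat, node_index=node_index, node_yx=node_yx,
                           resolution_km=field.resolution_km)


def reef_cell_nodes(graph: TransitionGraph, grid: ReefGrid) -> np.ndarray:
    """Representative sea node per reef cell: nearest sea pixel to its centroid."""
    cx = (grid.cells["x"].to_numpy() + 0.5) * grid.resolution_km
    cy = (grid.cells["y"].to_numpy() + 0.5) * grid.resolution_km
    if graph.n_nodes == 0:
        raise ValueError("empty transition graph")
    return graph.nearest_nodes(np.column_stack([cx, cy]))


def least_cost_matrix(graph: TransitionGraph, grid: ReefGrid) -> CostMatrix:
    """Directed least-cost distance between every ordered pair of reef cells."""
    nodes = reef_cell_nodes(graph, grid)
    dist = dijkstra(graph.costs, directed=True, indices=nodes)
    d = dist[:, nodes]
    np.fill_diagonal(d, 0.0)
    return CostMatrix(cell_ids=grid.cell_ids, d=d)


def border_distances(graph: TransitionGraph, grid: ReefGrid,
                     border_nodes: np.ndarray | None = None) -> pd.DataFrame:
    """Minimum directed cost from each reef cell to/from the border.

    Returns a DataFrame (cell_id, to_border, from_border); the global
    minima over cells feed the CDt selection rule.
    """
    if border_nodes is None:
        border_nodes = graph.border_nodes()
    border_nodes = np.asarray(border_nodes)
    if border_nodes.size == 0:
        raise ValueError("border node set is empty")
    nodes = reef_cell_nodes(graph, grid)
    # multi-source passes: distances from the border (forward graph) and to
    # the border (reversed graph)
    from_border = dijkstra(graph.costs, directed=True, indices=border_nodes,
                           min_only=True)
    to_border = dijkstra(graph.costs.T.tocsr(), directed=True,
                         indices=border_nodes, min_only=True)
    return pd.DataFrame({
        "cell_id": grid.cell_ids,
        "to_border": to_border[nodes],
        "from_border": from_border[nodes],
    })
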