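"""Per-reef dispersal indices from the least-cost matrix.

OCI (outbound connectivity index) of a reef cell is the total area (km²)
of the other reef cells it can reach within a cost-distance threshold CDt;
ICI (inbound) is the total area of the cells that can reach it.  CDt is
calibrated against the minimum cost distances to and from the study-area
border so that no cell's dispersal neighborhood is clipped by the border.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from reefadapt.graph import CostMatrix

DEFAULT_GRANULARITY = 100.0  # cost units


def select_cdt(min_to_border: float, min_from_border: float,
               granularity: float = DEFAULT_GRANULARITY) -> float:
    """Largest multiple of ``granularity`` strictly below both border minima.

    Maximizes the dispersal neighborhood without border effects: any
    threshold below the closest border distance cannot leak over the edge
    of the study area.
    """
    if min_to_border <= 0 or min_from_border <= 0:
        raise ValueError("border minima must be positive")
    m = min(min_to_border, min_from_border)
    cdt = granularity * math.floor(m / granularity)
    if cdt >= m:  # m is an exact multiple: step down to stay strictly below
        cdt -= granularity
    if cdt <= 0:
        raise ValueError(
            f"border minima ({min_to_border:g}, {min_from_border:g}) leave no "
            f"valid threshold at granularity {granularity:g}")
    return cdt


def _area_vector(costs: CostMatrix, areas) -> np.ndarray:
    areas = np.asarray(areas, dtype=float)
    if areas.shape != (len(costs.cell_ids),):
        raise ValueError("areas must give one value per reef cell")
    if (areas <= 0).any():
        raise ValueError("areas must be positive")
    return areas


def outbound_index(costs: CostMatrix, areas, cdt: float,
                   include_self: bool = False) -> np.ndarray:
    """OCI per cell: total area of cells j≠i with d(i→j) ≤ cdt."""
    if cdt <= 0:
        raise ValueError("cdt must be > 0")
    areas = _area_vector(costs, areas)
    within = costs.d <= cdt
    if not include_self:
        np.fill_diagonal(within, False)
    return within @ areas


def inbound_index(costs: CostMatrix, areas, cdt: float,
                  include_self: bool = False) -> np.ndarray:
    """ICI per cell: total area of cells j≠i with d(j→i) ≤ cdt."""
    if cdt <= 0:
        raise ValueError("cdt must be > 0")
    areas = _area_vector(costs, areas)
    within = costs.d <= cdt
    if not include_self:
        np.fill_diagonal(within, False)
    return within.T @ areas


def connectivity_table(costs: CostMatrix, areas, cdt: float) -> pd.DataFrame:
    """(cell_id, oci_km2, ici_km2, cdt) table for the whole grid."""
    return pd.DataFrame({
        "cell_id": costs.cell_ids,
        "oci_km2": outbound_index(costs, areas, cdt),
        "ici_km2": inbound_index(costs, areas, cdt),
        "cdt": cdt,
    })
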