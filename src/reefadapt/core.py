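"""Shared domain containers, the synthetic 365-day calendar and file I/O.

The synthetic calendar has no leap days: every year is 365 days with the
usual month lengths (February = 28).  This keeps planted thermal truths in
closed form; real-data ingestion would attach true calendars to the same
containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

# Month lengths of the no-leap synthetic calendar.
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
DAYS_PER_YEAR = int(MONTH_LENGTHS.sum())  # 365

#: month index (1..12) for each day-of-year (0..364)
_DOY_MONTH = np.repeat(np.arange(1, 13), MONTH_LENGTHS)


def day_of_year_to_month(doy: np.ndarray) -> np.ndarray:
    """Map day-of-year indices (0-based, 0..364) to month numbers 1..12."""
    return _DOY_MONTH[np.asarray(doy) % DAYS_PER_YEAR]


def spawn_seed(seed: int, *tags: object) -> int:
    """Derive a child seed (< 2**31) deterministically from a parent seed.

    One global seed fans out to per-stage child seeds so every stochastic
    stage is independently reproducible.  Tags are hashed with a stable
    (process-independent) digest.
    """
    import zlib

    tag_ints = [zlib.crc32(repr(t).encode()) & 0x7FFFFFFF for t in tags]
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *tag_ints])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class ReefGrid:
    """Reef cells on a regular raster: the spatial backbone of every stage.

    ``cells`` has one row per reef cell with columns ``cell_id``, ``x``,
    ``y`` (0-based column/row indices on the raster) and ``area_km2``.
    ``shape`` is the full raster shape ``(ny, nx)`` and ``resolution_km``
    the pixel edge length.
    """

    cells: pd.DataFrame
    shape: tuple[int, int]
    resolution_km: float

    def __post_init__(self) -> None:
        required = {"cell_id", "x", "y", "area_km2"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"reef grid missing columns: {sorted(missing)}")
        if (self.cells["area_km2"] <= 0).any():
            raise ValueError("reef cell areas must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells["cell_id"].to_numpy()

    def reef_mask(self) -> np.ndarray:
        """Binary (ny, nx) array, 1 where a reef cell sits."""
        m = np.zeros(self.shape, dtype=bool)
        m[self.cells["y"].to_numpy(), self.cells["x"].to_numpy()] = True
        return m

    def to_csv(self, path: str | Path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, shape: tuple[int, int] | None = None,
                 resolution_km: float = 5.0) -> "ReefGrid":
        cells = pd.read_csv(path)
        if shape is None:
            shape = (int(cells["y"].max()) + 1, int(cells["x"].max()) + 1)
        return cls(cells=cells, shape=shape, resolution_km=resolution_km)


@dataclass
class SstSeries:
    """Daily sea-surface temperature per reef cell.

    ``values`` is (n_days, n_cells) in °C; NaN marks missing observations.
    ``years`` / ``months`` / ``doy`` give each day's calendar position.
    """

    values: np.ndarray
    years: np.ndarray
    months: np.ndarray
    doy: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.months = np.asarray(self.months, dtype=int)
        self.doy = np.asarray(self.doy, dtype=int)
        self.cell_ids = np.asarray(self.cell_ids)
        n = len(self.years)
        if self.values.shape[0] != n or len(self.months) != n or len(self.doy) != n:
            raise ValueError("SST values and calendar arrays disagree on length")
        if self.values.shape[1] != len(self.cell_ids):
            raise ValueError("SST values and cell_ids disagree on cell count")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_daily(cls, values: np.ndarray, start_year: int, cell_ids) -> "SstSeries":
        """Build a series from a dense (n_days, n_cells) block starting on
        day 0 of ``start_year`` in the no-leap calendar."""
        values = np.asarray(values, dtype=float)
        n_days = values.shape[0]
        day_idx = np.arange(n_days)
        years = start_year + day_idx // DAYS_PER_YEAR
        doy = day_idx % DAYS_PER_YEAR
        months = day_of_year_to_month(doy)
        return cls(values=values, years=years, months=months, doy=doy,
                   cell_ids=np.asarray(cell_ids))


@dataclass
class CurrentField:
    """Static surface-current field on a raster.

    ``u`` (eastward) and ``v`` (northward) are (ny, nx) in m/s; NaN on
    non-sea pixels.  ``sea_mask`` is boolean, True = sea.
    """

    u: np.ndarray
    v: np.ndarray
    resolution_km: float
    sea_mask: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.sea_mask = np.asarray(self.sea_mask, dtype=bool)
        if not (self.u.shape == self.v.shape == self.sea_mask.shape):
            raise ValueError("u, v and sea_mask must share one shape")
        if not np.all(np.isfinite(self.u[self.sea_mask])) or not np.all(np.isfinite(self.v[self.sea_mask])):
            raise ValueError("current velocities must be finite on sea pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the synthetic generators.

    planted_alert_days: per-cell sorted day indices truly under bleaching
    alert (reproducible from the noise-free signal by the thermal
    definitions); true_gea_coefficients: (intercept, slope) per adaptive
    genotype; true_cover_coefficients: fixed effects, station-intercept sd
    and beta precision of the survey model; rng_seed: the seed used.
    """

    rng_seed: int
    planted_alert_days: dict[object, np.ndarray] = field(default_factory=dict)
    true_gea_coefficients: dict[object, tuple[float, float]] = field(default_factory=dict)
    true_cover_coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, (a, b) in self.true_gea_coefficients.items():
            if not (np.isfinite(a) and np.isfinite(b)):
                raise ValueError(f"non-finite planted coefficients for genotype {g}")
        for k, v in self.true_cover_coefficients.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite planted cover coefficient {k}")


# ---------------------------------------------------------------------------
# NetCDF / CSV I/O (NetCDF3 through xarray's scipy backend)
# ---------------------------------------------------------------------------

def write_sst_netcdf(path: str | Path, sst_raster: np.ndarray, start_year: int,
                     sea_mask: np.ndarray | None = None) -> None:
    """Write a (time, y, x) SST stack (°C) with calendar coordinates."""
    n_days = sst_raster.shape[0]
    day_idx = np.arange(n_days)
    years = start_year + day_idx // DAYS_PER_YEAR
    doy = day_idx % DAYS_PER_YEAR
    data = {"sst": (("time", "y", "x"), np.asarray(sst_raster, dtype="f8"))}
    if sea_mask is not None:
        data["sea_mask"] = (("y", "x"), np.asarray(sea_mask, dtype="i1"))
    ds = xr.Dataset(
        data,
        coords={"time": day_idx, "year": ("time", years), "doy": ("time", doy)},
        attrs={"calendar": "noleap-365", "units_sst": "degC"},
    )
    ds.to_netcdf(path, engine="scipy")


def read_sst_netcdf(path: str | Path, grid: ReefGrid) -> SstSeries:
    """Extract the per-reef-cell daily series from an SST raster stack."""
    with xr.open_dataset(path, engine="scipy") as ds:
        sst = ds["sst"].values
        years = ds["year"].values
        doy = ds["doy"].values
    values = sst[:, grid.cells["y"].to_numpy(), grid.cells["x"].to_numpy()]
    months = day_of_year_to_month(doy)
    return SstSeries(values=values, years=years, months=months, doy=doy,
                     cell_ids=grid.cell_ids)


def write_currents_netcdf(path: str | Path, u: np.ndarray, v: np.ndarray,
                          sea_mask: np.ndarray, resolution_km: float) -> None:
    """Write daily (time, y, x) u/v velocity stacks (m/s) plus the sea mask."""
    ds = xr.Dataset(
        {
            "uo": (("time", "y", "x"), np.asarray(u, dtype="f8")),
            "vo": (("time", "y", "x"), np.asarray(v, dtype="f8")),
            "sea_mask": (("y", "x"), np.asarray(sea_mask, dtype="i1")),
        },
        coords={"time": np.arange(u.shape[0])},
        attrs={"resolution_km": float(resolution_km), "units_velocity": "m s-1"},
    )
    ds.to_netcdf(path, engine="scipy")


def read_currents_netcdf(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Read daily u/v stacks; returns (u, v, sea_mask, resolution_km)."""
    with xr.open_dataset(path, engine="scipy") as ds:
        u = ds["uo"].values
        v = ds["vo"].values
        mask = ds["sea_mask"].values.astype(bool)
        res = float(ds.attrs.get("resolution_km", 1.0))
    return u, v, mask, res
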