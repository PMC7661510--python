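"""Synthetic seascape generators with recorded ground truth.

Builds toy archipelagos end to end: a connected reef grid, daily SST with a
sinusoidal annual cycle plus planted heat anomalies, smooth directed
current fields, genotype tables drawn from a known logistic
genotype-environment law, and coral-cover surveys drawn from a known
beta-regression mixed model.  Every generator is a pure function of its
arguments and seed, and every planted signal is recorded in a
:class:`~reefadapt.core.SyntheticTruth` so downstream stages can be tested
against closed-form expectations without external data.

The planted alert days are derived here from the *noise-free* SST signal
with a deliberately independent implementation of the thermal definitions
(trailing-window maximum instead of running sums) so that agreement with
:mod:`reefadapt.thermal` is a genuine cross-check.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from reefadapt.core import (
    DAYS_PER_YEAR,
    CurrentField,
    ReefGrid,
    SstSeries,
    SyntheticTruth,
    day_of_year_to_month,
    spawn_seed,
)
from reefadapt.adaptation import GenotypeTable

#: default day-of-year (0-based) of the climatological SST maximum;
#: mid-February, so the maximal monthly mean falls in month 2.
DEFAULT_PEAK_DOY = 45

_NEIGHBORS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def gen_reef_grid(n_x: int, n_y: int, reef_fraction: float = 1.0,
                  cell_area_km2: float = 25.0, seed: int = 0,
                  resolution_km: float = 5.0) -> ReefGrid:
    """Generate a reef grid whose reef cells form one 8-connected component.

    Cells are chosen by random region growth from a random start pixel until
    ``round(reef_fraction * n_x * n_y)`` cells are placed, which guarantees
    connectivity by construction.
    """
    if not (0 < reef_fraction <= 1):
        raise ValueError("reef_fraction must be in (0, 1]")
    if n_x * n_y < 4:
        raise ValueError("grid must have at least 4 pixels")
    n_target = int(round(reef_fraction * n_x * n_y))
    if n_target < 1:
        raise ValueError(
            f"reef_fraction {reef_fraction} gives no reef cells on a {n_x}x{n_y} grid")
    rng = np.random.default_rng(seed)
    start = (int(rng.integers(n_y)), int(rng.integers(n_x)))
    chosen: set[tuple[int, int]] = {start}
    frontier = deque([start])
    while len(chosen) < n_target:
        if not frontier:  # pragma: no cover - region growth cannot strand on a rectangle
            raise ValueError("could not grow a connected reef region")
        y, x = frontier[0]
        candidates = [(y + dy, x + dx) for dy, dx in _NEIGHBORS_8
                      if 0 <= y + dy < n_y and 0 <= x + dx < n_x
                      and (y + dy, x + dx) not in chosen]
        if not candidates:
            frontier.popleft()
            continue
        pick = candidates[int(rng.integers(len(candidates)))]
        chosen.add(pick)
        frontier.append(pick)
        if rng.random() < 0.3:  # rotate the frontier for rougher shapes
            frontier.rotate(-1)
    cells = sorted(chosen)
    df = pd.DataFrame({
        "cell_id": np.arange(len(cells)),
        "x": [c[1] for c in cells],
        "y": [c[0] for c in cells],
        "area_km2": float(cell_area_km2),
    })
    return ReefGrid(cells=df, shape=(n_y, n_x), resolution_km=resolution_km)


def _noise_free_sst(n_days: int, n_cells: int, baseline_temp: float,
                    seasonal_amplitude: float, peak_doy: int,
                    anomalies: list[tuple[int, int, int, float]],
                    cell_index: dict) -> np.ndarray:
    doy = np.arange(n_days) % DAYS_PER_YEAR
    cycle = baseline_temp + seasonal_amplitude * np.cos(
        2 * np.pi * (doy - peak_doy) / DAYS_PER_YEAR)
    sst = np.tile(cycle[:, None], (1, n_cells))
    for cell, start_day, duration, magnitude in anomalies:
        if duration < 1:
            raise ValueError("anomaly duration must be >= 1 day")
        if start_day < 0 or start_day + duration > n_days:
            raise ValueError(
                f"anomaly [{start_day}, {start_day + duration}) outside the "
                f"{n_days}-day series")
        sst[start_day:start_day + duration, cell_index[cell]] += magnitude
    return sst


def _alert_days_from_signal(sst: np.ndarray, window_days: int = 84) -> list[np.ndarray]:
    """Apply the thermal definitions to a clean signal, independently.

    Climatology by calendar month, MMM as its max, hotspots at the
    inclusive 1 °C excess rule, and alert when the trailing window
    (current day included) contains any hotspot — computed with a
    sliding-window maximum rather than running sums.
    """
    n_days, n_cells = sst.shape
    months = day_of_year_to_month(np.arange(n_days) % DAYS_PER_YEAR)
    clim = np.stack([sst[months == m].mean(axis=0) for m in range(1, 13)])
    mmm = clim.max(axis=0)
    hot = np.where(sst - mmm >= 1.0, sst - mmm, 0.0)
    padded = np.pad(hot, ((window_days - 1, 0), (0, 0)))
    trailing_max = sliding_window_view(padded, window_days, axis=0).max(axis=-1)
    return [np.flatnonzero(trailing_max[:, c] > 0) for c in range(n_cells)]


def gen_sst_series(grid: ReefGrid, n_years: int, baseline_temp: float = 26.0,
                   seasonal_amplitude: float = 3.0,
                   anomalies: list[tuple[int, int, int, float]] | None = None,
                   seed: int = 0, noise_sd: float = 0.1,
                   start_year: int = 1981,
                   peak_doy: int = DEFAULT_PEAK_DOY) -> tuple[SstSeries, SyntheticTruth]:
    """Daily per-cell SST: sinusoidal annual cycle + planted anomalies + noise.

    ``anomalies`` lists (cell_id, start_day, duration_days, magnitude_degC).
    The returned truth's ``planted_alert_days`` are exactly the days the
    thermal definitions flag on the noise-free signal.
    """
    if n_years < 2:
        raise ValueError("need at least 2 years of SST")
    anomalies = list(anomalies or [])
    n_days = n_years * DAYS_PER_YEAR
    cell_index = {cid: i for i, cid in enumerate(grid.cell_ids)}
    clean = _noise_free_sst(n_days, grid.n_cells, baseline_temp,
                            seasonal_amplitude, peak_doy, anomalies, cell_index)
    rng = np.random.default_rng(seed)
    values = clean + noise_sd * rng.standard_normal(clean.shape)
    series = SstSeries.from_daily(values, start_year, grid.cell_ids)
    alert_days = _alert_days_from_signal(clean)
    truth = SyntheticTruth(
        rng_seed=seed,
        planted_alert_days={cid: alert_days[i] for cid, i in cell_index.items()},
    )
    return series, truth


def sst_to_raster(grid: ReefGrid, series: SstSeries, fill: float = np.nan) -> np.ndarray:
    """Scatter a per-cell series back onto the (time, y, x) raster."""
    ras = np.full((series.n_days, *grid.shape), fill)
    ras[:, grid.cells["y"].to_numpy(), grid.cells["x"].to_numpy()] = series.values
    return ras


def gen_current_field(grid: ReefGrid, drift_east: float = -0.05,
                      drift_north: float = 0.0, noise_sd: float = 0.02,
                      n_days: int = 30, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Daily u/v stacks (n_days, ny, nx) in m/s: constant drift plus noise.

    The default drift is weakly westward, the prevailing transport of the
    emulated region.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    shape = (n_days, *grid.shape)
    u = drift_east + noise_sd * rng.standard_normal(shape)
    v = drift_north + noise_sd * rng.standard_normal(shape)
    return u, v


def gen_genotype_data(site_baf: dict, n_per_site: int, n_adaptive: int,
                      intercepts, slopes, n_neutral: int = 0, seed: int = 0,
                      species: str = "A") -> tuple[GenotypeTable, SyntheticTruth]:
    """Per-individual binary genotype table from a planted logistic law.

    Each individual at site *s* carries adaptive genotype *g* with
    probability ``expit(intercept_g + slope_g * BAF_s)``; neutral genotypes
    are Bernoulli with BAF-independent frequencies drawn once per genotype
    from U(0.1, 0.9).
    """
    if not site_baf:
        raise ValueError("site_baf must name at least one site")
    intercepts = np.asarray(intercepts, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    if len(intercepts) != n_adaptive or len(slopes) != n_adaptive:
        raise ValueError("intercepts/slopes must have length n_adaptive")
    if n_per_site < 5:
        raise ValueError("n_per_site must be >= 5 (site retention threshold)")
    rng = np.random.default_rng(seed)
    sites = list(site_baf)
    neutral_freq = rng.uniform(0.1, 0.9, size=n_neutral)
    rows = []
    for s in sites:
        baf = site_baf[s]
        p_adapt = expit(intercepts + slopes * baf)
        for k in range(n_per_site):
            ind = f"{species}_{s}_{k}"
            pres_a = rng.random(n_adaptive) < p_adapt
            for g in range(n_adaptive):
                rows.append((ind, s, species, f"adaptive_{g}", int(pres_a[g])))
            if n_neutral:
                pres_n = rng.random(n_neutral) < neutral_freq
                for g in range(n_neutral):
                    rows.append((ind, s, species, f"neutral_{g}", int(pres_n[g])))
    df = pd.DataFrame(rows, columns=["individual_id", "site_id", "species",
                                     "genotype_id", "presence"])
    truth = SyntheticTruth(
        rng_seed=seed,
        true_gea_coefficients={f"adaptive_{g}": (float(intercepts[g]), float(slopes[g]))
                               for g in range(n_adaptive)},
    )
    return GenotypeTable(table=df, site_env=dict(site_baf)), truth


#: coefficient names accepted by :func:`gen_survey_data`; all on the
#: standardized-covariate scale of the fitted models.
SURVEY_TERMS = ("intercept", "baf_prev", "pa", "oci", "ici",
                "baf_prev:pa", "baf_prev:oci", "baf_prev:ici")

#: defaults emulating the study conditions: cover around 30%, a weak
#: negative effect of previous-year heat stress, precision calibrated so the
#: fitted coefficient standard errors reproduce the reported ±0.03 scale,
#: and a moderate station effect.
DEFAULT_SURVEY_EFFECTS = {"intercept": -0.85, "baf_prev": -0.06}
DEFAULT_STATION_SD = 0.5
DEFAULT_PRECISION = 18.0


def gen_survey_data(n_stations: int = 60, years_per_station: tuple[int, int] = (3, 14),
                    fixed_effects: dict | None = None,
                    station_sd: float = DEFAULT_STATION_SD,
                    precision: float = DEFAULT_PRECISION,
                    seed: int = 0,
                    first_year: int = 2003) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Coral-cover survey records from a beta-regression mixed model.

    Covariates (baf_prev per record; pa/oci/ici per station) are drawn with
    realistic correlation, standardized, and fed through
    ``logit(mu) = fixed effects + station intercept``; cover is
    ``Beta(mu*phi, (1-mu)*phi)``.  Stations have unequal visit histories.
    """
    if precision <= 0:
        raise ValueError("precision must be > 0")
    if station_sd < 0:
        raise ValueError("station_sd must be >= 0")
    effects = dict(DEFAULT_SURVEY_EFFECTS if fixed_effects is None else fixed_effects)
    unknown = set(effects) - set(SURVEY_TERMS)
    if unknown:
        raise ValueError(f"unknown survey effect terms: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    lo, hi = years_per_station
    n_years = rng.integers(lo, hi + 1, size=n_stations)
    # station-level latent field: correlated PA / OCI / ICI and a thermal
    # propensity that drives the yearly BAF_prev draws
    corr = np.array([[1.0, 0.4, 0.2, 0.2],
                     [0.4, 1.0, 0.2, 0.2],
                     [0.2, 0.2, 1.0, 0.4],
                     [0.2, 0.2, 0.4, 1.0]])
    latent = rng.multivariate_normal(np.zeros(4), corr, size=n_stations,
                                     method="cholesky")
    therm, pa_lat, oci_lat, ici_lat = latent.T
    station_pa = expit(pa_lat + 0.8 * therm)           # in (0,1) like PA_HEAT
    # connectivity indices are bounded by the total reef area inside the
    # dispersal neighborhood: mildly skewed, bounded draws
    station_oci = 500.0 * expit(-0.5 + 0.8 * oci_lat)  # km²
    station_ici = 500.0 * expit(-0.5 + 0.8 * ici_lat)
    b = station_sd * rng.standard_normal(n_stations)

    rows = []
    for i in range(n_stations):
        years = first_year + np.sort(rng.choice(hi + 1, size=n_years[i], replace=False))
        baf_prev = np.clip(0.12 + 0.04 * therm[i] + 0.05 * rng.standard_normal(n_years[i]),
                           0.0, 1.0)
        for y, bp in zip(years, baf_prev):
            rows.append((f"st{i:03d}", int(y), i, bp, station_pa[i],
                         station_oci[i], station_ici[i]))
    df = pd.DataFrame(rows, columns=["station_id", "year", "_i", "baf_prev",
                                     "pa", "oci", "ici"])

    z = {c: (df[c] - df[c].mean()) / df[c].std(ddof=0)
         for c in ("baf_prev", "pa", "oci", "ici")}
    eta = np.full(len(df), effects.get("intercept", 0.0))
    for term, beta in effects.items():
        if term == "intercept":
            continue
        parts = term.split(":")
        val = np.ones(len(df))
        for p in parts:
            val = val * z[p].to_numpy()
        eta += beta * val
    eta += b[df["_i"].to_numpy()]
    mu = expit(eta)
    cover = rng.beta(mu * precision, (1 - mu) * precision)
    df["cover_rate"] = cover
    df = df.drop(columns="_i")
    truth = SyntheticTruth(
        rng_seed=seed,
        true_cover_coefficients={**effects, "station_sd": float(station_sd),
                                 "precision": float(precision)},
    )
    return df, truth
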