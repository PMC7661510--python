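"""Coral-Reef-Watch-style heat-stress metrics from daily SST.

Pipeline per reef cell: monthly climatology -> maximal monthly mean (MMM,
the bleaching reference temperature) -> daily hotspot values (SST − MMM,
retained only when the excess is at least 1 °C) -> bleaching-alert flags
(a day is under alert when the cumulated hotspot over the trailing 84-day
window, current day included, is positive) -> yearly alert frequencies
(BAF_year) and their long-run mean (BAF_overall).

Early calendar years are excluded from BAF to avoid bias from estimating
the MMM on a short record; by default the first valid BAF year is 1985 for
a series starting in 1981.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from reefadapt.core import ReefGrid, SstSeries

HOTSPOT_MIN_EXCESS = 1.0  # °C; retention rule for hotspot values
DEFAULT_WINDOW_DAYS = 84


@dataclass
class ThermalSummary:
    """Per-cell thermal stress summary.

    mmm: (n_cells,) maximal monthly mean in °C; hotspot: (n_days, n_cells)
    daily hotspot values; alert_flag: (n_days, n_cells) binary (NaN where
    SST missing); baf_year: DataFrame indexed by year, one column per cell;
    baf_overall: (n_cells,) mean of BAF_year over the valid range.
    """

    cell_ids: np.ndarray
    mmm: np.ndarray
    hotspot: np.ndarray
    alert_flag: np.ndarray
    baf_year: pd.DataFrame
    baf_overall: np.ndarray

    def baf_overall_series(self) -> pd.Series:
        return pd.Series(self.baf_overall, index=pd.Index(self.cell_ids, name="cell_id"),
                         name="baf_overall")


def monthly_climatology(sst: SstSeries, baseline_years: tuple[int, int] | None = None) -> np.ndarray:
    """Per-cell mean SST for each calendar month, (12, n_cells) in °C.

    ``baseline_years`` is an inclusive (first, last) year range; default is
    the full series.  Missing days are excluded from the means.  A month
    with zero observations in the baseline raises.
    """
    keep = np.ones(sst.n_days, dtype=bool)
    if baseline_years is not None:
        first, last = baseline_years
        keep = (sst.years >= first) & (sst.years <= last)
        if not keep.any():
            raise ValueError(f"baseline years {baseline_years} not covered by the series")
    clim = np.empty((12, sst.n_cells))
    for m in range(1, 13):
        sel = keep & (sst.months == m)
        if not sel.any():
            raise ValueError(f"no observations for calendar month {m} in the baseline")
        block = sst.values[sel]
        n_obs = np.sum(np.isfinite(block), axis=0)
        if np.any(n_obs == 0):
            bad = np.flatnonzero(n_obs == 0)
            raise ValueError(f"month {m}: only missing values at cell index {bad[0]}")
        clim[m - 1] = np.nanmean(block, axis=0)
    return clim


def maximal_monthly_mean(climatology: np.ndarray) -> np.ndarray:
    """MMM per cell: the warmest month's climatological mean."""
    clim = np.asarray(climatology, dtype=float)
    if clim.shape[0] != 12 or not np.all(np.isfinite(clim)):
        raise ValueError("climatology must be (12, n_cells) with finite entries")
    return clim.max(axis=0)


def hotspot_series(sst: SstSeries, mmm: np.ndarray) -> np.ndarray:
    """Daily hotspot values (°C): SST − MMM where SST ≥ MMM + 1 °C, else 0.

    The 1 °C retention threshold is inclusive. Missing SST gives a missing
    hotspot.
    """
    mmm = np.asarray(mmm, dtype=float)
    if not np.all(np.isfinite(mmm)):
        raise ValueError("MMM must be finite")
    excess = sst.values - mmm[np.newaxis, :]
    hot = np.where(excess >= HOTSPOT_MIN_EXCESS, excess, 0.0)
    hot[~np.isfinite(sst.values)] = np.nan
    return hot


def alert_flags(hotspot: np.ndarray, window_days: int = DEFAULT_WINDOW_DAYS) -> np.ndarray:
    """Daily bleaching-alert flags from the hotspot series.

    flag(t) = 1 iff the cumulated hotspot over the window of ``window_days``
    days ending at and including day t is > 0.  Days with less history than
    the window use the available prefix.  Since hotspots are non-negative
    this is equivalent to "any positive hotspot in the window".  Missing
    hotspots are ignored in the sum; a day whose own SST is missing still
    gets a flag from its window.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    hot = np.asarray(hotspot, dtype=float)
    filled = np.nan_to_num(hot, nan=0.0)
    csum = np.cumsum(filled, axis=0)
    window_sum = csum.copy()
    if hot.shape[0] > window_days:
        window_sum[window_days:] = csum[window_days:] - csum[:-window_days]
    return (window_sum > 0).astype(np.int8)


def annual_alert_frequency(flags: np.ndarray, years: np.ndarray,
                           first_valid_year: int = 1985,
                           observed: np.ndarray | None = None) -> pd.DataFrame:
    """BAF_year: per-cell fraction of days under alert, per calendar year.

    Years before ``first_valid_year`` are omitted.  ``observed`` (boolean,
    same shape as flags) restricts the denominator to observed days;
    default: every day counts.
    """
    years = np.asarray(years)
    flags = np.asarray(flags)
    valid = years >= first_valid_year
    if not valid.any():
        raise ValueError("no days at or after first_valid_year")
    if observed is None:
        observed = np.ones_like(flags, dtype=bool)
    yrs = np.unique(years[valid])
    out = np.empty((len(yrs), flags.shape[1]))
    for i, y in enumerate(yrs):
        sel = years == y
        n_obs = observed[sel].sum(axis=0)
        with np.errstate(invalid="ignore"):
            out[i] = np.where(n_obs > 0,
                              (flags[sel] * observed[sel]).sum(axis=0) / np.maximum(n_obs, 1),
                              np.nan)
    return pd.DataFrame(out, index=pd.Index(yrs, name="year"))


def overall_baf(baf_year: pd.DataFrame, year_range: tuple[int, int] | None = None) -> np.ndarray:
    """BAF_overall: unweighted mean of BAF_year over an inclusive year range."""
    if year_range is None:
        sub = baf_year
    else:
        first, last = year_range
        wanted = np.arange(first, last + 1)
        missing = np.setdiff1d(wanted, baf_year.index.to_numpy())
        if missing.size:
            raise ValueError(f"BAF_year missing requested years: {missing.tolist()}")
        sub = baf_year.loc[wanted]
    if len(sub) == 0:
        raise ValueError("empty year range")
    return sub.mean(axis=0).to_numpy()


def survey_thermal_covariates(baf_year: pd.DataFrame, survey_year: int) -> tuple[np.ndarray, np.ndarray]:
    """Record-level thermal covariates for a survey in ``survey_year``.

    Returns (BAF_previous_year, BAF_overall_to_lag2): the alert frequency of
    the year preceding the survey, and the mean alert frequency from the
    first valid year up to two years before the survey.
    """
    first_valid = int(baf_year.index.min())
    if survey_year - 2 < first_valid:
        raise ValueError(
            f"survey year {survey_year} needs BAF history back to {survey_year - 2}, "
            f"but the first valid BAF year is {first_valid}")
    if survey_year - 1 not in baf_year.index:
        raise ValueError(f"BAF_year missing {survey_year - 1}")
    baf_prev = baf_year.loc[survey_year - 1].to_numpy()
    baf_overall = overall_baf(baf_year, (first_valid, survey_year - 2))
    return baf_prev, baf_overall


def summarize(sst: SstSeries, window_days: int = DEFAULT_WINDOW_DAYS,
              first_valid_year: int | None = None,
              baseline_years: tuple[int, int] | None = None) -> ThermalSummary:
    """Run the full thermal pipeline on a per-cell SST series.

    ``first_valid_year`` defaults to the series' fifth calendar year (the
    first four are excluded from BAF).
    """
    clim = monthly_climatology(sst, baseline_years)
    mmm = maximal_monthly_mean(clim)
    hot = hotspot_series(sst, mmm)
    flags = alert_flags(hot, window_days)
    if first_valid_year is None:
        first_valid_year = int(sst.years.min()) + 4
        if first_valid_year > int(sst.years.max()):
            first_valid_year = int(sst.years.min())
    baf_year = annual_alert_frequency(flags, sst.years, first_valid_year)
    baf_overall = overall_baf(baf_year)
    return ThermalSummary(cell_ids=sst.cell_ids, mmm=mmm, hotspot=hot,
                          alert_flag=flags, baf_year=baf_year,
                          baf_overall=baf_overall)


def write_baf_tables(summary: ThermalSummary, out_dir) -> None:
    """Write (cell_id, year, baf) and (cell_id, baf_overall) CSV tables."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long = summary.baf_year.copy()
    long.columns = summary.cell_ids
    long = long.reset_index().melt(id_vars="year", var_name="cell_id", value_name="baf")
    long[["cell_id", "year", "baf"]].to_csv(out / "baf_year.csv", index=False)
    summary.baf_overall_series().reset_index().to_csv(out / "baf_overall.csv", index=False)
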