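"""Deterministic end-to-end orchestration of the seascape pipeline.

Stages: synthetic simulation (or user-supplied inputs) → thermal stress →
connectivity graph → connectivity indices → adaptation models → genetic
structure validation → coral-cover models.  Every stochastic stage draws a
child seed from the single global seed, all artifacts are plain CSV /
NetCDF / JSON, and a manifest records configuration, seeds and artifact
hashes so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from reefadapt import adaptation, cover, graph, indices, structure, synthetic, thermal
from reefadapt.core import (
    ReefGrid,
    read_currents_netcdf,
    read_sst_netcdf,
    spawn_seed,
    write_currents_netcdf,
    write_sst_netcdf,
)

log = logging.getLogger("reefadapt")


@dataclass
class PipelineConfig:
    """Flat, validated configuration for a pipeline run."""

    out_dir: str = "reefadapt_run"
    seed: int = 0
    # synthetic-world shape
    grid_nx: int = 12
    grid_ny: int = 10
    sea_margin: int = 3  # sea pixels between the reef area and the border
    reef_fraction: float = 0.45
    cell_area_km2: float = 25.0
    n_years: int = 12
    anomaly_years: tuple = (5, 7, 9)
    anomaly_magnitude: float = 2.5
    anomaly_duration: int = 20
    drift_east: float = -0.05
    drift_north: float = 0.0
    current_noise_sd: float = 0.02
    current_days: int = 30
    # thermal
    window_days: int = 84
    # graph
    epsilon: float = 0.01
    neighborhood: int = 8
    # indices
    cdt: float | None = None
    cdt_granularity: float = 100.0
    # adaptation
    n_sites: int = 8
    n_per_site: int = 20
    n_adaptive: int = 5
    n_neutral: int = 40
    baseline_draws: int = 100
    gea_slope: float = 15.0
    gea_intercept: float = -1.5
    # structure
    n_perm: int = 199
    pca_threshold: float = 0.8
    # cover
    n_stations: int = 30
    years_per_station: tuple = (2, 4)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_years < 6:
            raise ValueError("n_years must be >= 6 (four excluded years + history)")
        if not (0 < self.reef_fraction <= 1):
            raise ValueError("reef_fraction must be in (0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    def child_seed(self, stage: str) -> int:
        return spawn_seed(self.seed, stage)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"stage '{name}' failed: {e}") from e
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


@_stage("simulate")
def stage_simulate(cfg: PipelineConfig, out: Path) -> ReefGrid:
    grid = synthetic.gen_reef_grid(cfg.grid_nx, cfg.grid_ny, cfg.reef_fraction,
                                   cfg.cell_area_km2, seed=cfg.child_seed("grid"))
    if cfg.sea_margin > 0:  # keep open sea between the reefs and the border
        m = cfg.sea_margin
        cells = grid.cells.copy()
        cells["x"] += m
        cells["y"] += m
        grid = ReefGrid(cells=cells,
                        shape=(grid.shape[0] + 2 * m, grid.shape[1] + 2 * m),
                        resolution_km=grid.resolution_km)
    # heat anomalies with an east-west magnitude gradient, so BAF_overall
    # varies spatially (emulating the contrast between coasts)
    x = grid.cells["x"].to_numpy()
    frac = (x - x.min()) / max(x.max() - x.min(), 1)
    anomalies = []
    for ay in cfg.anomaly_years:
        start = ay * 365 + 30  # within the warm season of that year
        for cid, f in zip(grid.cell_ids, frac):
            anomalies.append((int(cid), start, cfg.anomaly_duration,
                              cfg.anomaly_magnitude * (0.2 + 1.3 * f)))
    series, truth = synthetic.gen_sst_series(grid, cfg.n_years,
                                             anomalies=anomalies,
                                             seed=cfg.child_seed("sst"))
    sea_mask = np.ones(grid.shape, dtype=bool)
    write_sst_netcdf(out / "sst.nc", synthetic.sst_to_raster(grid, series),
                     start_year=1981, sea_mask=sea_mask)
    grid.to_csv(out / "grid.csv")
    u, v = synthetic.gen_current_field(grid, cfg.drift_east, cfg.drift_north,
                                       cfg.current_noise_sd, cfg.current_days,
                                       seed=cfg.child_seed("currents"))
    write_currents_netcdf(out / "currents.nc", u, v, sea_mask, grid.resolution_km)
    with open(out / "planted_alerts.json", "w") as fh:
        json.dump({str(k): np.asarray(v).tolist()
                   for k, v in truth.planted_alert_days.items()}, fh)
    return grid


@_stage("thermal")
def stage_thermal(cfg: PipelineConfig, out: Path, grid: ReefGrid) -> thermal.ThermalSummary:
    series = read_sst_netcdf(out / "sst.nc", grid)
    summary = thermal.summarize(series, window_days=cfg.window_days)
    thermal.write_baf_tables(summary, out)
    return summary


@_stage("graph")
def stage_graph(cfg: PipelineConfig, out: Path, grid: ReefGrid):
    u, v, sea_mask, res = read_currents_netcdf(out / "currents.nc")
    field = graph.temporal_mean_field(u, v, res, sea_mask)
    tg = graph.build_transition_graph(field, cfg.neighborhood, cfg.epsilon)
    costs = graph.least_cost_matrix(tg, grid)
    costs.to_csv(out / "cost_matrix.csv")
    borders = graph.border_distances(tg, grid)
    borders.to_csv(out / "border_distances.csv", index=False)
    return tg, costs, borders


@_stage("indices")
def stage_indices(cfg: PipelineConfig, out: Path, grid: ReefGrid,
                  costs: graph.CostMatrix, borders: pd.DataFrame) -> pd.DataFrame:
    if cfg.cdt is not None:
        cdt = cfg.cdt
    else:
        cdt = indices.select_cdt(borders["to_border"].min(),
                                 borders["from_border"].min(),
                                 cfg.cdt_granularity)
    table = indices.connectivity_table(costs, grid.cells["area_km2"].to_numpy(), cdt)
    table.to_csv(out / "connectivity_indices.csv", index=False)
    return table


@_stage("adapt")
def stage_adapt(cfg: PipelineConfig, out: Path, grid: ReefGrid,
                summary: thermal.ThermalSummary):
    baf = summary.baf_overall
    # sampling sites spread across the BAF range (quantile-spaced cells)
    order = np.argsort(baf, kind="stable")
    n_sites = min(cfg.n_sites, grid.n_cells)
    site_cells = order[np.linspace(0, grid.n_cells - 1, n_sites).round().astype(int)]
    if len(np.unique(baf[site_cells])) < 2:
        raise ValueError("synthetic BAF field is constant across candidate sites")
    site_baf = {f"site{i}": float(baf[c]) for i, c in enumerate(site_cells)}
    rng2 = np.random.default_rng(cfg.child_seed("gea_coef"))
    intercepts = cfg.gea_intercept + 0.3 * rng2.standard_normal(cfg.n_adaptive)
    slopes = cfg.gea_slope + 2.0 * rng2.standard_normal(cfg.n_adaptive)
    table, truth = synthetic.gen_genotype_data(site_baf, cfg.n_per_site,
                                               cfg.n_adaptive, intercepts, slopes,
                                               n_neutral=cfg.n_neutral,
                                               seed=cfg.child_seed("genotypes"))
    table.table.to_csv(out / "genotypes.csv", index=False)
    pd.Series(site_baf, name="baf_overall").rename_axis("site_id").reset_index() \
        .to_csv(out / "site_baf.csv", index=False)

    adaptive = table.subset_genotypes([g for g in table.table["genotype_id"].unique()
                                       if str(g).startswith("adaptive")])
    neutral = table.subset_genotypes([g for g in table.table["genotype_id"].unique()
                                      if str(g).startswith("neutral")])
    cv = adaptation.loo_population_cv(adaptive)
    cv.to_csv(out / "cv_report.csv", index=False)
    adaptation.summarize_cv(cv).to_csv(out / "cv_summary.csv", index=False)
    adaptation.random_genotype_baseline(neutral, n_draws=cfg.baseline_draws,
                                        seed=cfg.child_seed("baseline")) \
        .to_csv(out / "cv_baseline.csv", index=False)
    pooled = adaptation.fit_pooled_glmm(adaptive)
    pa = adaptation.predict_pa_heat(pooled, baf)
    pd.DataFrame({"cell_id": grid.cell_ids, "baf_overall": baf, "pa_heat": pa}) \
        .to_csv(out / "pa_heat.csv", index=False)
    with open(out / "pooled_model.json", "w") as fh:
        json.dump({"intercept": pooled.intercept, "slope": pooled.slope,
                   "variances": pooled.variances, "loglik": pooled.loglik,
                   "converged": pooled.converged}, fh, indent=1)
    site_cell_map = {f"site{i}": int(grid.cell_ids[c]) for i, c in enumerate(site_cells)}
    return table, pooled, site_cell_map


@_stage("structure")
def stage_structure(cfg: PipelineConfig, out: Path, grid: ReefGrid,
                    tg, table: adaptation.GenotypeTable, site_cell_map: dict):
    calls = table.table.pivot(index="individual_id", columns="genotype_id",
                              values="presence")
    sites = table.table.groupby("individual_id")["site_id"].first().loc[calls.index]
    sfm = structure.site_allele_frequencies(calls, sites.to_numpy(),
                                            min_samples=5)
    hell = structure.hellinger_transform(sfm.freq)
    Y = structure.pca_cumulative(hell, cfg.pca_threshold)
    cell_pos = grid.cells.set_index("cell_id")
    coords = np.array([[(cell_pos.loc[site_cell_map[s], "x"] + 0.5) * grid.resolution_km,
                        (cell_pos.loc[site_cell_map[s], "y"] + 0.5) * grid.resolution_km]
                       for s in sfm.freq.index])
    dist = structure.site_cost_distances(tg, coords)
    basis = structure.dbmem(dist)
    selected = structure.forward_select_rda(Y, basis, n_perm=cfg.n_perm,
                                            seed=cfg.child_seed("rda"))
    report = {"n_sites": int(len(sfm.freq)), "n_pcs": int(Y.shape[1]),
              "n_dbmem": int(basis.vectors.shape[1]), "selected": selected}
    if selected:
        res = structure.rda_anova(Y, basis.vectors[:, selected], n_perm=cfg.n_perm,
                                  seed=cfg.child_seed("rda_anova"))
        report.update({"r2": res.r2, "adj_r2": res.adj_r2,
                       "pseudo_f": res.pseudo_f, "p_value": res.p_value})
    with open(out / "structure_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


@_stage("cover")
def stage_cover(cfg: PipelineConfig, out: Path, grid: ReefGrid,
                summary: thermal.ThermalSummary, pooled, indices_table: pd.DataFrame):
    surveys, _ = synthetic.gen_survey_data(
        n_stations=cfg.n_stations, years_per_station=cfg.years_per_station,
        seed=cfg.child_seed("surveys"),
        first_year=1981 + 7)  # leaves >= 2 valid BAF years before any survey
    surveys[["station_id", "year", "cover_rate"]].to_csv(out / "surveys.csv",
                                                         index=False)
    rng = np.random.default_rng(cfg.child_seed("station_cells"))
    stations = surveys["station_id"].unique()
    station_cell = {s: int(grid.cell_ids[rng.integers(grid.n_cells)])
                    for s in stations}
    pd.DataFrame(station_cell.items(), columns=["station_id", "cell_id"]) \
        .to_csv(out / "station_cells.csv", index=False)
    baf_year = summary.baf_year.copy()
    baf_year.columns = summary.cell_ids
    records = cover.join_covariates(surveys[["station_id", "year", "cover_rate"]],
                                    station_cell, baf_year, pooled, indices_table)
    records.to_csv(out / "cover_records.csv", index=False)
    fits = cover.univariate_screen(records) + cover.interaction_models(records)
    rows = []
    for f in fits:
        for t, est, se, p in zip(f.terms, f.estimates, f.se, f.p_values):
            rows.append((f.label, t, est, se, p, f.aic, f.loglik))
    pd.DataFrame(rows, columns=["model", "term", "estimate", "se", "p", "aic",
                                "loglik"]).to_csv(out / "cover_models.csv",
                                                  index=False)
    cover.compare_models(fits).to_csv(out / "cover_model_ranking.csv", index=False)
    return fits


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage on a synthetic seascape; returns the artifact directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = stage_simulate(cfg, out)
    summary = stage_thermal(cfg, out, grid)
    tg, costs, borders = stage_graph(cfg, out, grid)
    idx_table = stage_indices(cfg, out, grid, costs, borders)
    table, pooled, site_cell_map = stage_adapt(cfg, out, grid, summary)
    stage_structure(cfg, out, grid, tg, table, site_cell_map)
    stage_cover(cfg, out, grid, summary, pooled, idx_table)

    artifacts = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "seeds": {s: cfg.child_seed(s) for s in
                  ("grid", "sst", "currents", "genotypes", "baseline", "rda",
                   "surveys", "station_cells")},
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def report(artifact_dir: str | Path) -> pd.DataFrame:
    """Collate per-reef indicators: baf_overall, pa_heat, oci, ici."""
    out = Path(artifact_dir)
    needed = ["baf_overall.csv", "pa_heat.csv", "connectivity_indices.csv"]
    for name in needed:
        if not (out / name).exists():
            raise FileNotFoundError(f"missing artifact: {name}")
    baf = pd.read_csv(out / "baf_overall.csv")[["cell_id", "baf_overall"]]
    pa = pd.read_csv(out / "pa_heat.csv")[["cell_id", "pa_heat"]]
    idx = pd.read_csv(out / "connectivity_indices.csv")
    return baf.merge(pa, on="cell_id").merge(
        idx[["cell_id", "oci_km2", "ici_km2"]], on="cell_id")
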