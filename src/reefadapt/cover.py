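"""Coral-cover change versus heat stress, adaptation and connectivity.

Survey records (station, year, cover rate in [0, 1]) are joined to four
record-level covariates — BAF of the previous year, PA_HEAT computed from
the record's own BAF history, and the cell's inbound/outbound connectivity
indices — and modelled with beta-regression mixed models: Beta likelihood
with logit mean link and a single precision φ, a Gaussian random intercept
per station, and standardized fixed effects.  The marginal likelihood
integrates the station intercept by adaptive Gauss–Hermite quadrature
(15 nodes by default).  Models are screened univariately and with
BAF_previous-year × moderator interactions (no moderator main effect) and
ranked by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln
from scipy.stats import norm

from reefadapt.adaptation import PooledAdaptationModel, predict_pa_heat
from reefadapt.thermal import survey_thermal_covariates

COVARIATES = ("baf_prev", "pa", "oci", "ici")
DEFAULT_NODES = 15


@dataclass
class MixedFit:
    """A fitted beta-regression mixed model.

    Fixed-effect arrays are aligned with ``terms`` (intercept first);
    ``station_sd`` is the random-intercept standard deviation and
    ``precision`` the beta precision φ.  ``n_params`` counts every
    estimated parameter, so AIC = 2·n_params − 2·loglik exactly.
    """

    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p_values: np.ndarray
    station_sd: float
    precision: float
    loglik: float
    aic: float
    n_params: int
    converged: bool
    n_records: int
    records_key: int
    label: str

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "estimate": self.estimates,
                             "se": self.se, "z": self.z, "p": self.p_values})


def standardize(x) -> np.ndarray:
    """Center to mean 0 and scale to sd 1 (population sd)."""
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / x.std()


def squeeze_unit_interval(y: np.ndarray) -> np.ndarray:
    """Pull boundary rates off 0/1: (y·(n−1) + 0.5)/n."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    return (y * (n - 1) + 0.5) / n


def join_covariates(surveys: pd.DataFrame, station_cell: dict,
                    baf_year: pd.DataFrame, pa_model: PooledAdaptationModel,
                    indices: pd.DataFrame) -> pd.DataFrame:
    """One analysis record per (station, year) with its four covariates.

    ``baf_year`` is years × reef-cell columns (as produced by the thermal
    stage); ``indices`` has columns cell_id, oci_km2, ici_km2.  PA_HEAT is
    computed from each record's own BAF_overall-to-lag-2 through the pooled
    model.  Unmappable stations or records with insufficient BAF history
    fail with the offenders listed.
    """
    idx = indices.set_index("cell_id")
    problems = []
    rows = []
    for _, rec in surveys.iterrows():
        st, year = rec["station_id"], int(rec["year"])
        cell = station_cell.get(st)
        if cell is None or cell not in baf_year.columns or cell not in idx.index:
            problems.append(f"station {st}: no mapped reef cell with artifacts")
            continue
        try:
            baf_prev, baf_overall = survey_thermal_covariates(baf_year[[cell]], year)
        except ValueError as e:
            problems.append(f"station {st}, year {year}: {e}")
            continue
        rows.append({
            "station_id": st, "year": year, "cover_rate": rec["cover_rate"],
            "baf_prev": float(baf_prev[0]),
            "baf_overall": float(baf_overall[0]),
            "pa": float(predict_pa_heat(pa_model, baf_overall[0])),
            "oci": float(idx.loc[cell, "oci_km2"]),
            "ici": float(idx.loc[cell, "ici_km2"]),
        })
    if problems:
        raise ValueError("could not join covariates:\n  " + "\n  ".join(problems))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta-regression mixed model
# ---------------------------------------------------------------------------

def _design(records: pd.DataFrame, fixed_terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + standardized covariates and their products."""
    cols = {}
    for term in fixed_terms:
        parts = term.split(":")
        val = np.ones(len(records))
        for p in parts:
            if p not in records.columns:
                raise ValueError(f"unknown covariate '{p}' in term '{term}'")
            val = val * standardize(records[p])
        cols[term] = val
    X = np.column_stack([np.ones(len(records))] + [cols[t] for t in fixed_terms])
    return X, ["intercept", *fixed_terms]


class _BetaGlmmLikelihood:
    """Marginal log-likelihood with the station intercept integrated out by
    adaptive Gauss–Hermite quadrature."""

    def __init__(self, y: np.ndarray, X: np.ndarray, station_idx: np.ndarray,
                 n_nodes: int = DEFAULT_NODES):
        self.y = y
        self.X = X
        self.idx = station_idx
        self.n_stations = int(station_idx.max()) + 1
        z, w = hermegauss(n_nodes)  # nodes/weights for weight exp(-z²/2)
        self.nodes = z
        self.logw = np.log(w)
        self.logit_y = np.log(y) - np.log1p(-y)

    def _row_loglik(self, eta: np.ndarray, phi: float) -> np.ndarray:
        mu = expit(eta)
        a, b = mu * phi, (1 - mu) * phi
        return (gammaln(phi) - gammaln(a) - gammaln(b)
                + (a - 1) * np.log(self.y) + (b - 1) * np.log1p(-self.y))

    def _row_score_eta(self, eta: np.ndarray, phi: float) -> np.ndarray:
        mu = expit(eta)
        return phi * mu * (1 - mu) * (self.logit_y - digamma(mu * phi)
                                      + digamma((1 - mu) * phi))

    def _station_sum(self, vals: np.ndarray) -> np.ndarray:
        return np.bincount(self.idx, weights=vals, minlength=self.n_stations)

    def loglik(self, params: np.ndarray) -> float:
        p = self.X.shape[1]
        beta = params[:p]
        phi = np.exp(params[p])
        sigma = np.exp(params[p + 1])
        eta_fix = self.X @ beta
        if sigma < 1e-7:  # effectively a fixed-effects beta regression
            return float(self._row_loglik(eta_fix, phi).sum())
        # mode of each station's integrand by damped Newton (numeric curvature)
        b = np.zeros(self.n_stations)
        delta = 1e-5
        for _ in range(60):
            g = self._station_sum(self._row_score_eta(eta_fix + b[self.idx], phi)) - b / sigma ** 2
            g_hi = self._station_sum(self._row_score_eta(eta_fix + (b + delta)[self.idx], phi))
            g_lo = self._station_sum(self._row_score_eta(eta_fix + (b - delta)[self.idx], phi))
            curv = -(g_hi - g_lo) / (2 * delta) + 1 / sigma ** 2
            curv = np.maximum(curv, 0.5 / sigma ** 2)
            step = g / curv
            step = np.clip(step, -2.0, 2.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-10:
                break
        g_hi = self._station_sum(self._row_score_eta(eta_fix + (b + delta)[self.idx], phi))
        g_lo = self._station_sum(self._row_score_eta(eta_fix + (b - delta)[self.idx], phi))
        h = np.maximum(-(g_hi - g_lo) / (2 * delta) + 1 / sigma ** 2, 0.5 / sigma ** 2)
        scale = 1.0 / np.sqrt(h)
        # log ∫ exp(g(b)) db ≈ log Σ_k w_k exp(g(b̂+scale·z_k) + z_k²/2) + log scale
        contrib = np.empty((len(self.nodes), self.n_stations))
        for k, (z, lw) in enumerate(zip(self.nodes, self.logw)):
            bk = b + scale * z
            joint = (self._station_sum(self._row_loglik(eta_fix + bk[self.idx], phi))
                     - 0.5 * (bk / sigma) ** 2)
            contrib[k] = lw + joint + 0.5 * z ** 2
        m = contrib.max(axis=0)
        log_int = m + np.log(np.exp(contrib - m).sum(axis=0)) + np.log(scale)
        # Gaussian density normalization of the random intercept
        log_int -= 0.5 * np.log(2 * np.pi) + np.log(sigma)
        return float(log_int.sum())


def _num_hessian(fun, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            f_pp = fun(x + ei + ej)
            f_pm = fun(x + ei - ej)
            f_mp = fun(x - ei + ej)
            f_mm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * step ** 2)
    return H


def fit_beta_glmm(records: pd.DataFrame, fixed_terms: list[str],
                  squeeze: bool = True, n_nodes: int = DEFAULT_NODES,
                  label: str | None = None) -> MixedFit:
    """Fit a beta-regression mixed model with a station random intercept.

    ``fixed_terms`` name covariate columns or ':'-joined interactions; all
    are standardized before entering the linear predictor.  Cover rates of
    exactly 0 or 1 are squeezed off the boundary when ``squeeze`` is true,
    otherwise they raise.
    """
    if records["station_id"].nunique() < 2:
        raise ValueError("need at least 2 stations")
    y = records["cover_rate"].to_numpy(dtype=float)
    if ((y <= 0) | (y >= 1)).any():
        if not squeeze:
            raise ValueError("cover rates on the boundary 0/1: enable the "
                             "squeeze transform (y·(n−1)+0.5)/n")
        y = squeeze_unit_interval(y)
    X, terms = _design(records, fixed_terms)
    station_idx = pd.Categorical(records["station_id"]).codes.astype(int)
    lik = _BetaGlmmLikelihood(y, X, station_idx, n_nodes)

    # starting values from the fixed-effects beta regression
    from statsmodels.othermod.betareg import BetaModel
    try:
        start = BetaModel(y, X).fit(disp=False)
        beta0 = start.params[:X.shape[1]]
        phi0 = float(np.exp(start.params[-1]))
    except Exception:
        beta0 = np.zeros(X.shape[1])
        beta0[0] = np.log(y.mean() / (1 - y.mean()))
        phi0 = 5.0
    x0 = np.concatenate([beta0, [np.log(phi0)], [np.log(0.3)]])

    def objective(pvec):
        return -lik.loglik(pvec)

    p = X.shape[1]
    bounds = [(None, None)] * p + [(np.log(1e-2), np.log(1e4)), (np.log(1e-6), np.log(10.0))]
    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 400, "ftol": 1e-11})
    loglik = float(-res.fun)
    H = _num_hessian(lambda v: -lik.loglik(v), res.x)
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_all = np.full(len(res.x), np.nan)
    est = res.x[:p]
    se = se_all[:p]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    pvals = 2 * norm.sf(np.abs(z))
    n_params = p + 2  # fixed effects + precision + station variance
    aic = 2 * n_params - 2 * loglik
    return MixedFit(terms=terms, estimates=est, se=se, z=z, p_values=pvals,
                    station_sd=float(np.exp(res.x[p + 1])),
                    precision=float(np.exp(res.x[p])),
                    loglik=loglik, aic=float(aic), n_params=n_params,
                    converged=bool(res.success), n_records=len(records),
                    records_key=hash(tuple(zip(records["station_id"], records["year"]))),
                    label=label or "+".join(fixed_terms))


def univariate_screen(records: pd.DataFrame, **kwargs) -> list[MixedFit]:
    """One single-fixed-effect model per covariate (BAF_prev, PA, ICI, OCI)."""
    return [fit_beta_glmm(records, [c], label=c, **kwargs) for c in COVARIATES]


def interaction_models(records: pd.DataFrame, **kwargs) -> list[MixedFit]:
    """BAF_prev plus its interaction with each moderator (no moderator main
    effect), one model per moderator."""
    fits = []
    for m in ("pa", "oci", "ici"):
        fits.append(fit_beta_glmm(records, ["baf_prev", f"baf_prev:{m}"],
                                  label=f"baf_prev*{m}", **kwargs))
    return fits


def compare_models(fits: list[MixedFit]) -> pd.DataFrame:
    """Rank fits on identical records by AIC (ascending), with ΔAIC."""
    if not fits:
        raise ValueError("no fits to compare")
    keys = {f.records_key for f in fits}
    if len(keys) > 1:
        raise ValueError("fits were made on differing record sets")
    out = pd.DataFrame({
        "model": [f.label for f in fits],
        "aic": [f.aic for f in fits],
        "loglik": [f.loglik for f in fits],
        "n_params": [f.n_params for f in fits],
    }).sort_values("aic", kind="stable").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out
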