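"""Genotype–environment association models and the pooled adaptation model.

Per putatively adaptive genotype, a logistic model links the probability
that an individual carries the variant to the bleaching-alert frequency
(BAF_overall) at its sampling site.  Model skill is assessed by
leave-one-population-out cross-validation (refit without one site, predict
that site's genotype frequency, correlate predicted with observed across
sites) and contrasted with the same procedure applied to randomly selected
neutral genotypes.  A pooled Bernoulli mixed model with crossed random
intercepts for genotype, individual and species turns all adaptive
genotypes into one probability-of-adaptation curve, PA_HEAT(BAF), mapped
over reef cells at the population level (random effects at zero).

The mixed model maximizes a Laplace approximation to the marginal
likelihood; the inner mode over random effects is found by Newton
iterations on a variance-scaled system that stays well conditioned as any
variance component collapses to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import pearsonr

DEFAULT_RIDGE = 1e-4
_RANDOM_FACTORS = ("genotype_id", "individual_id", "species")


@dataclass
class GenotypeTable:
    """Per-individual binary presence of genotypes, with site BAF values.

    ``table`` columns: individual_id, site_id, species, genotype_id,
    presence (0/1).  ``site_env`` maps site_id -> BAF_overall.
    """

    table: pd.DataFrame
    site_env: dict

    def __post_init__(self) -> None:
        required = {"individual_id", "site_id", "species", "genotype_id", "presence"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"genotype table missing columns: {sorted(missing)}")
        if not set(self.table["presence"].unique()) <= {0, 1}:
            raise ValueError("presence must be binary")
        absent = set(self.table["site_id"].unique()) - set(self.site_env)
        if absent:
            raise ValueError(f"sites without a BAF value: {sorted(map(str, absent))}")
        dup = self.table.duplicated(["individual_id", "genotype_id"])
        if dup.any():
            raise ValueError("duplicate (individual, genotype) rows")

    def baf_column(self) -> np.ndarray:
        return self.table["site_id"].map(self.site_env).to_numpy(dtype=float)

    def subset_genotypes(self, genotype_ids) -> "GenotypeTable":
        sub = self.table[self.table["genotype_id"].isin(set(genotype_ids))]
        return GenotypeTable(table=sub.reset_index(drop=True), site_env=self.site_env)


@dataclass
class GeaModel:
    """One genotype's logistic model: logit(P presence) = a + b·BAF.

    Standard errors come from the inverse observed information of the
    unpenalized likelihood at the (possibly ridge-penalized) estimate.
    """

    genotype_id: object
    intercept: float
    slope: float
    ridge: float
    converged: bool
    se_intercept: float = np.nan
    se_slope: float = np.nan


@dataclass
class PooledAdaptationModel:
    """Pooled logistic mixed model over all adaptive genotypes.

    Fixed intercept and BAF slope; ``variances`` holds the random-intercept
    variance per factor (0 where pinned), ``log`` the fitting trace.
    """

    intercept: float
    slope: float
    variances: dict[str, float]
    loglik: float
    converged: bool
    log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-genotype logistic fits
# ---------------------------------------------------------------------------

def _logistic_newton(n_trials: np.ndarray, n_success: np.ndarray,
                     baf: np.ndarray, ridge: float,
                     max_iter: int = 200) -> tuple[np.ndarray, bool]:
    """Ridge-penalized logistic MLE on per-site binomial counts."""
    X = np.column_stack([np.ones_like(baf), baf])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        grad = X.T @ (n_success - n_trials * p) - 2 * ridge * beta
        w = n_trials * p * (1 - p)
        hess = X.T @ (X * w[:, None]) + 2 * ridge * np.eye(2)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, False
        # step-halving on the penalized log-likelihood
        def pll(b):
            e = X @ b
            return float(n_success @ e - n_trials @ np.logaddexp(0, e) - ridge * b @ b)
        f0 = pll(beta)
        t = 1.0
        while t > 1e-8 and pll(beta + t * step) < f0 - 1e-12:
            t /= 2
        beta = beta + t * step
        if np.max(np.abs(grad)) < 1e-9 and np.max(np.abs(t * step)) < 1e-9:
            return beta, True
        if ridge == 0 and np.max(np.abs(beta)) > 50:
            return beta, False  # heading to separation
    return beta, np.max(np.abs(grad)) < 1e-6


def fit_genotype_logistic(presence: np.ndarray, baf: np.ndarray,
                          ridge: float = DEFAULT_RIDGE,
                          genotype_id: object = None) -> GeaModel:
    """Fit logit(P presence) = a + b·BAF for one genotype.

    ``ridge`` adds a λ‖(a, b)‖² penalty; with λ = 0 complete separation is
    reported as non-convergence rather than silently returning divergent
    coefficients.
    """
    presence = np.asarray(presence, dtype=float)
    baf = np.asarray(baf, dtype=float)
    if presence.shape != baf.shape:
        raise ValueError("presence and baf must be congruent vectors")
    if len(np.unique(baf)) < 2:
        raise ValueError("need at least 2 distinct BAF values")
    if ridge < 0:
        raise ValueError("ridge penalty must be >= 0")
    if ridge == 0 and presence.min() == presence.max():
        raise ValueError("single-class presence requires ridge > 0")
    # collapse to per-BAF binomial counts: same likelihood, faster Newton
    uniq, inv = np.unique(baf, return_inverse=True)
    n_trials = np.bincount(inv).astype(float)
    n_success = np.bincount(inv, weights=presence)
    beta, ok = _logistic_newton(n_trials, n_success, uniq, ridge)
    X = np.column_stack([np.ones_like(uniq), uniq])
    p = expit(X @ beta)
    w = n_trials * p * (1 - p)
    info = X.T @ (X * w[:, None])
    try:
        se = np.sqrt(np.diag(np.linalg.inv(info)))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    return GeaModel(genotype_id=genotype_id, intercept=float(beta[0]),
                    slope=float(beta[1]), ridge=ridge, converged=bool(ok),
                    se_intercept=float(se[0]), se_slope=float(se[1]))


def predict_genotype_frequency(model: GeaModel, baf) -> np.ndarray | float:
    """Expected genotype frequency at a BAF value: expit(a + b·BAF)."""
    if not model.converged:
        raise ValueError(f"model for genotype {model.genotype_id} did not converge")
    out = expit(model.intercept + model.slope * np.asarray(baf, dtype=float))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# leave-one-population-out cross-validation
# ---------------------------------------------------------------------------

def _cv_one_genotype(site_ids: np.ndarray, presence: np.ndarray,
                     site_env: dict, ridge: float) -> float | None:
    """Pearson r between observed and LOO-predicted site frequencies.

    Returns None when the observed frequencies have zero variance (r is
    undefined).
    """
    sites = np.unique(site_ids)
    observed = np.array([presence[site_ids == s].mean() for s in sites])
    if np.allclose(observed, observed[0]):
        return None
    predicted = np.empty(len(sites))
    for i, s in enumerate(sites):
        keep = site_ids != s
        model = fit_genotype_logistic(presence[keep],
                                      np.array([site_env[x] for x in site_ids[keep]]),
                                      ridge=ridge)
        predicted[i] = expit(model.intercept + model.slope * site_env[s])
    if np.allclose(predicted, predicted[0]):
        return None
    return float(pearsonr(predicted, observed)[0])


def loo_population_cv(table: GenotypeTable, ridge: float = DEFAULT_RIDGE) -> pd.DataFrame:
    """Leave-one-population-out CV for every genotype in the table.

    Returns one row per genotype: (genotype_id, species, r, n_sites);
    r is NaN where undefined (zero frequency variance).  Aggregate with
    :func:`summarize_cv`.
    """
    df = table.table
    out = []
    for (g, spp), sub in df.groupby(["genotype_id", "species"], sort=False):
        site_ids = sub["site_id"].to_numpy()
        n_sites = len(np.unique(site_ids))
        if n_sites < 3:
            raise ValueError(f"genotype {g}: need >= 3 sites for LOO-CV")
        r = _cv_one_genotype(site_ids, sub["presence"].to_numpy(dtype=float),
                             table.site_env, ridge)
        out.append((g, spp, np.nan if r is None else r, n_sites))
    return pd.DataFrame(out, columns=["genotype_id", "species", "r", "n_sites"])


def summarize_cv(cv: pd.DataFrame) -> pd.DataFrame:
    """Per-species mean ± sd of Pearson r over genotypes (NaNs excluded)."""
    g = cv.dropna(subset=["r"]).groupby("species")["r"]
    return g.agg(mean_r="mean", sd_r="std", n_genotypes="count").reset_index()


def random_genotype_baseline(neutral_table: GenotypeTable, n_draws: int = 1000,
                             seed: int = 0, ridge: float = DEFAULT_RIDGE) -> pd.DataFrame:
    """CV baseline: the same procedure on randomly selected genotypes.

    Samples ``n_draws`` genotype ids per species (with replacement when the
    pool is smaller) and returns the per-species summary of their CV
    correlations.
    """
    rng = np.random.default_rng(seed)
    df = neutral_table.table
    rows = []
    for spp, sub in df.groupby("species", sort=False):
        pool = sub["genotype_id"].unique()
        draws = rng.choice(pool, size=n_draws, replace=len(pool) < n_draws)
        uniq, counts = np.unique(draws, return_counts=True)
        r_by_geno = {}
        for g in uniq:
            gsub = sub[sub["genotype_id"] == g]
            r = _cv_one_genotype(gsub["site_id"].to_numpy(),
                                 gsub["presence"].to_numpy(dtype=float),
                                 neutral_table.site_env, ridge)
            r_by_geno[g] = np.nan if r is None else r
        rs = np.repeat([r_by_geno[g] for g in uniq], counts)
        rs = rs[np.isfinite(rs)]
        if rs.size == 0:
            rows.append((spp, np.nan, np.nan, 0))
        else:
            sd = float(np.std(rs, ddof=1)) if rs.size > 1 else np.nan
            rows.append((spp, float(np.mean(rs)), sd, len(rs)))
    return pd.DataFrame(rows, columns=["species", "mean_r", "sd_r", "n_genotypes"])


# ---------------------------------------------------------------------------
# pooled mixed model (Laplace)
# ---------------------------------------------------------------------------

def _active_factors(df: pd.DataFrame) -> list[str]:
    """Random factors with >= 2 levels and at least one replicated level."""
    active = []
    for f in _RANDOM_FACTORS:
        counts = df[f].value_counts()
        if len(counts) >= 2 and counts.max() >= 2:
            active.append(f)
    return active


class _LaplaceBernoulli:
    """Laplace-approximate marginal log-likelihood for the pooled model."""

    def __init__(self, y: np.ndarray, baf: np.ndarray, df: pd.DataFrame,
                 factors: list[str]):
        self.y = y
        self.X = np.column_stack([np.ones_like(baf), baf])
        self.factors = factors
        blocks = []
        self.block_sizes = []
        for f in factors:
            codes = pd.Categorical(df[f]).codes
            q = codes.max() + 1
            blocks.append(sp.csr_matrix(
                (np.ones(len(codes)), (np.arange(len(codes)), codes)),
                shape=(len(codes), q)))
            self.block_sizes.append(q)
        self.Z = sp.hstack(blocks).tocsr() if blocks else None
        self.q = int(sum(self.block_sizes))
        self._b = np.zeros(self.q)

    def _sigma_vec(self, log_sigma: np.ndarray) -> np.ndarray:
        return np.repeat(np.exp(log_sigma), self.block_sizes)

    def loglik(self, params: np.ndarray) -> float:
        beta, log_sigma = params[:2], params[2:]
        eta_fix = self.X @ beta
        if self.q == 0:
            return float(self.y @ eta_fix - np.logaddexp(0, eta_fix).sum())
        s = self._sigma_vec(log_sigma)
        Z = self.Z
        b = self._b.copy()
        # Newton on the joint mode over b, scaled by s for stability at s -> 0
        def joint(bvec):
            eta = eta_fix + Z @ bvec
            pen = 0.5 * np.sum((bvec / np.maximum(s, 1e-300)) ** 2)
            return float(self.y @ eta - np.logaddexp(0, eta).sum() - pen)
        ZT = Z.T
        for _ in range(100):
            eta = eta_fix + Z @ b
            p = expit(eta)
            grad = ZT @ (self.y - p) - b / np.maximum(s, 1e-300) ** 2
            w = p * (1 - p)
            A = (ZT @ sp.diags(w) @ Z).toarray()
            M = np.eye(self.q) + (s[:, None] * A) * s[None, :]
            rhs = s * grad
            try:
                c = cho_factor(M, lower=True)
            except np.linalg.LinAlgError:
                return -np.inf
            step = s * cho_solve(c, rhs)
            f0 = joint(b)
            t = 1.0
            while t > 1e-10 and joint(b + t * step) < f0 - 1e-12:
                t /= 2
            b = b + t * step
            if np.max(np.abs(t * step)) < 1e-10:
                break
        self._b = b
        eta = eta_fix + Z @ b
        p = expit(eta)
        w = p * (1 - p)
        A = (ZT @ sp.diags(w) @ Z).toarray()
        M = np.eye(self.q) + (s[:, None] * A) * s[None, :]
        sign, logdet_M = np.linalg.slogdet(M)
        if sign <= 0:
            return -np.inf
        # log|D| + log|Z'WZ + D^-1| = log|M|; the 2π terms cancel
        ll = (self.y @ eta - np.logaddexp(0, eta).sum()
              - 0.5 * np.sum((b / np.maximum(s, 1e-300)) ** 2)
              - 0.5 * logdet_M)
        return float(ll)


def fit_pooled_glmm(table: GenotypeTable) -> PooledAdaptationModel:
    """Fit the pooled Bernoulli-logit mixed model.

    Fixed effects: intercept and BAF_overall slope.  Crossed random
    intercepts for genotype, individual and species; a factor with fewer
    than 2 levels (or no replicated level) is pinned at variance 0 with a
    note in the fitting log.
    """
    df = table.table
    y = df["presence"].to_numpy(dtype=float)
    baf = table.baf_column()
    log: list[str] = []
    factors = _active_factors(df)
    for f in _RANDOM_FACTORS:
        if f not in factors:
            log.append(f"variance of {f} pinned at 0 (unidentifiable)")
    model = _LaplaceBernoulli(y, baf, df, factors)

    start_fit = fit_genotype_logistic(y, baf, ridge=DEFAULT_RIDGE)
    bounds = [(None, None)] * 2 + [(-8.0, 3.0)] * len(factors)

    def objective(p):
        return -model.loglik(p)

    # two principled starts: moderate and near-zero variance components
    res = None
    for ls0 in (np.log(0.5), -5.0):
        x0 = np.concatenate([[start_fit.intercept, start_fit.slope],
                             np.full(len(factors), ls0)])
        r = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                     options={"maxiter": 500, "ftol": 1e-11})
        if res is None or r.fun < res.fun:
            res = r
    converged = bool(res.success)
    if not converged:
        # restart from jittered initializations
        rng = np.random.default_rng(0)
        best = res
        for _ in range(3):
            x_j = x0 + 0.3 * rng.standard_normal(len(x0))
            r2 = minimize(objective, x_j, method="L-BFGS-B", bounds=bounds,
                          options={"maxiter": 500, "ftol": 1e-11})
            if r2.fun < best.fun:
                best = r2
        res = best
        converged = bool(res.success)
        if not converged:
            log.append(f"non-convergence: {res.message}")
    variances = dict.fromkeys(_RANDOM_FACTORS, 0.0)
    for f, ls in zip(factors, res.x[2:]):
        variances[f] = float(np.exp(2 * ls))
    log.append(f"loglik={-res.fun:.6f} nit={res.nit}")
    return PooledAdaptationModel(intercept=float(res.x[0]), slope=float(res.x[1]),
                                 variances=variances, loglik=float(-res.fun),
                                 converged=converged, log=log)


def predict_pa_heat(model: PooledAdaptationModel, baf_overall) -> np.ndarray | float:
    """Population-level PA_HEAT: expit(intercept + slope·BAF), random effects 0."""
    if not model.converged:
        raise ValueError("pooled model did not converge")
    out = expit(model.intercept + model.slope * np.asarray(baf_overall, dtype=float))
    return float(out) if out.ndim == 0 else out
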