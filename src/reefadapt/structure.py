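"""Seascape graph versus genetic structure: dbMEM + redundancy analysis.

Response: per-site minor-allele frequencies (sites with at least 5
samples), Hellinger-transformed, reduced to the leading principal
components that cumulatively explain 80% of the variance.  Predictors:
distance-based Moran's eigenvector maps (the classical PCNM construction)
of the symmetrized least-cost distances between sampling sites.  A forward
selection over the dbMEMs yields the "optimal" redundancy-analysis model,
whose global significance is assessed by a permutation ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree

from reefadapt.graph import TransitionGraph


@dataclass
class SiteFrequencyMatrix:
    """Minor-allele frequencies per retained site.

    ``freq`` is (sites × SNPs) in [0, 1]; ``n_samples`` the per-site sample
    count; ``dropped`` the sites excluded by the sample threshold.
    """

    freq: pd.DataFrame
    n_samples: pd.Series
    dropped: list


@dataclass
class DbMemBasis:
    """Positive-eigenvalue spatial eigenvectors of the truncated distances."""

    vectors: np.ndarray
    eigenvalues: np.ndarray
    truncation: float


@dataclass
class RdaResult:
    selected: list[int]
    r2: float
    adj_r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    site_scores: np.ndarray


def site_allele_frequencies(calls: pd.DataFrame, sites, min_samples: int = 5) -> SiteFrequencyMatrix:
    """Per-site frequency of the globally minor allele of every SNP.

    ``calls`` is individuals × SNPs with diploid copy counts 0/1/2 (NaN =
    missing call); ``sites`` labels each individual's sampling site.  The
    minor allele is defined globally across all sites, then frequencies are
    computed per site as copies / (2 · called samples).  Sites with fewer
    than ``min_samples`` individuals are dropped and reported.
    """
    calls = calls.astype(float)
    if not ((calls.isin([0, 1, 2])) | calls.isna()).all().all():
        raise ValueError("genotype calls must be 0/1/2 or missing")
    sites = pd.Series(np.asarray(sites), index=calls.index, name="site_id")
    # global orientation: flip SNPs where allele '1' is the major allele
    copies = calls.sum(axis=0)
    called = calls.notna().sum(axis=0)
    global_freq = copies / (2 * called)
    flip = (global_freq > 0.5).to_numpy()
    flipped = calls.copy()
    flipped.loc[:, flipped.columns[flip]] = 2 - calls.loc[:, flipped.columns[flip]]

    counts = sites.value_counts()
    keep_sites = counts[counts >= min_samples].index
    dropped = sorted(set(counts.index) - set(keep_sites), key=str)
    if len(keep_sites) == 0:
        raise ValueError(f"every site has fewer than {min_samples} samples")
    keep = sites.isin(keep_sites)
    grouped = flipped[keep].groupby(sites[keep])
    freq = grouped.sum() / (2 * grouped.count())
    return SiteFrequencyMatrix(freq=freq.sort_index(),
                               n_samples=counts[keep_sites].sort_index(),
                               dropped=dropped)


def hellinger_transform(freqs) -> np.ndarray:
    """Hellinger transform: sqrt(y_ij / row_sum_i); row squared sums are 1."""
    y = np.asarray(freqs, dtype=float)
    if (y < 0).any():
        raise ValueError("frequencies must be non-negative")
    row_sums = y.sum(axis=1)
    zero = np.flatnonzero(row_sums == 0)
    if zero.size:
        names = (list(freqs.index[zero]) if isinstance(freqs, pd.DataFrame)
                 else zero.tolist())
        raise ValueError(f"all-zero row(s) for site(s) {names}")
    return np.sqrt(y / row_sums[:, None])


def pca_cumulative(X: np.ndarray, threshold: float = 0.80) -> np.ndarray:
    """Scores of the minimal leading PCs reaching the cumulative-variance
    threshold."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for a PCA")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        raise ValueError("zero total variance")
    k = int(np.searchsorted(np.cumsum(var) / total, threshold - 1e-12) + 1)
    return U[:, :k] * s[:k]


def site_cost_distances(graph: TransitionGraph, site_coords_km: np.ndarray,
                        symmetrize: str = "mean") -> np.ndarray:
    """Symmetric least-cost distances between sampling sites.

    Directed distances are computed both ways on the transition graph and
    reconciled per pair by the arithmetic mean (or min/max).
    """
    nodes = graph.nearest_nodes(np.asarray(site_coords_km, dtype=float))
    directed = dijkstra(graph.costs, directed=True, indices=nodes)[:, nodes]
    if not np.all(np.isfinite(directed)):
        raise ValueError("some site pairs are mutually unreachable")
    if symmetrize == "mean":
        d = 0.5 * (directed + directed.T)
    elif symmetrize == "min":
        d = np.minimum(directed, directed.T)
    elif symmetrize == "max":
        d = np.maximum(directed, directed.T)
    else:
        raise ValueError("symmetrize must be 'mean', 'min' or 'max'")
    np.fill_diagonal(d, 0.0)
    return d


def dbmem(dist: np.ndarray, truncation: float | None = None) -> DbMemBasis:
    """Distance-based Moran's eigenvector maps (classical PCNM).

    Distances beyond the truncation t (default: the longest edge of the
    minimum spanning tree) are replaced by 4t; the truncated matrix is
    double-centered (−½D² Gower-centered) and eigendecomposed.  Columns
    with positive eigenvalues, scaled by sqrt(eigenvalue), form the basis.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sites for dbMEM")
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("dist must be square symmetric with zero diagonal")
    if truncation is None:
        mst = minimum_spanning_tree(D).toarray()
        truncation = float(mst.max())
    Dt = np.where(D > truncation, 4 * truncation, D)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-10
    pos = vals > tol
    return DbMemBasis(vectors=vecs[:, pos] * np.sqrt(vals[pos]),
                      eigenvalues=vals[pos], truncation=truncation)


# ---------------------------------------------------------------------------
# redundancy analysis
# ---------------------------------------------------------------------------

def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def _rss(Y: np.ndarray, Q: np.ndarray | None) -> float:
    """Residual sum of squares of centered Y on the orthonormal basis Q."""
    tot = float((Y ** 2).sum())
    if Q is None or Q.shape[1] == 0:
        return tot
    return tot - float(((Q.T @ Y) ** 2).sum())


def _adj_r2(r2: float, n: int, m: int) -> float:
    return 1 - (1 - r2) * (n - 1) / (n - m - 1)


def forward_select_rda(Y: np.ndarray, basis: DbMemBasis | np.ndarray,
                       alpha: float = 0.05, n_perm: int = 999,
                       seed: int = 0) -> list[int]:
    """Greedy forward selection of dbMEM predictors.

    Selection only starts if the full model is itself significant under the
    permutation test (the global pre-test guarding against best-of-k
    selection bias).  At each step the candidate giving the largest
    adjusted-R² increase is admitted if its marginal permutation p ≤ alpha
    and the running adjusted R² does not exceed the full-model adjusted R²
    (the double stopping rule).  Returns the selected column indices
    (possibly empty).
    """
    X = basis.vectors if isinstance(basis, DbMemBasis) else np.asarray(basis)
    Y = _center(np.asarray(Y, dtype=float))
    X = _center(X)
    n, k = X.shape
    if n <= 2:
        raise ValueError("need more than 2 sites")
    rng = np.random.default_rng(seed)
    tot = float((Y ** 2).sum())

    Q_full, R_full = np.linalg.qr(X)
    diag = np.abs(np.diag(R_full))
    rank = int(np.sum(diag > 1e-10 * max(1.0, diag.max())))
    full_r2 = 1 - _rss(Y, Q_full[:, :rank]) / tot
    full_adj = _adj_r2(full_r2, n, min(rank, n - 2))

    if rank < n - 1:  # global pre-test of the full model
        if rda_anova(Y, Q_full[:, :rank], n_perm=n_perm,
                     seed=int(rng.integers(2 ** 31))).p_value > alpha:
            return []

    selected: list[int] = []
    remaining = list(range(k))
    Q_cur = np.empty((n, 0))
    while remaining:
        rss_cur = _rss(Y, Q_cur)
        if rss_cur < 1e-12 * tot:
            break  # response fully explained; nothing left to test
        best, best_rss = None, np.inf
        for j in remaining:
            Xj = np.column_stack([Q_cur, X[:, j]])
            Qj, _ = np.linalg.qr(Xj)
            r = _rss(Y, Qj)
            if r < best_rss:
                best, best_rss, Q_best = j, r, Qj
        m_new = len(selected) + 1
        adj_new = _adj_r2(1 - best_rss / tot, n, m_new)
        if adj_new > full_adj + 1e-12:
            break
        df_res = n - m_new - 1
        if df_res <= 0:
            break
        f_obs = (rss_cur - best_rss) / (best_rss / df_res)
        # unrestricted row permutations of Y
        count = 0
        for _ in range(n_perm):
            Yp = Y[rng.permutation(n)]
            rp_cur = _rss(Yp, Q_cur)
            rp_new = _rss(Yp, Q_best)
            fp = (rp_cur - rp_new) / max(rp_new / df_res, 1e-300)
            if fp >= f_obs:
                count += 1
        p = (1 + count) / (n_perm + 1)
        if p > alpha:
            break
        selected.append(best)
        remaining.remove(best)
        Q_cur = Q_best
    return selected


def rda_anova(Y: np.ndarray, X_selected: np.ndarray, n_perm: int = 999,
              seed: int = 0) -> RdaResult:
    """Redundancy analysis with a permutation test of global significance.

    Y and X are column-centered; pseudo-F = (explained SS / m) /
    (residual SS / (n − m − 1)); the null distribution permutes rows of Y.
    Canonical site scores are the PCA of the fitted values.
    """
    Y = _center(np.asarray(Y, dtype=float))
    X = _center(np.atleast_2d(np.asarray(X_selected, dtype=float)))
    if X.shape[0] != Y.shape[0]:
        X = X.T
    n, m = X.shape
    if m == 0:
        raise ValueError("selected predictor set is empty")
    if m >= n - 1:
        raise ValueError("saturated model: as many predictors as residual df")
    Q, _ = np.linalg.qr(X)
    tot = float((Y ** 2).sum())
    rss = _rss(Y, Q)
    r2 = 1 - rss / tot
    f_obs = (tot - rss) / m / (rss / (n - m - 1))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        Yp = Y[rng.permutation(n)]
        rp = _rss(Yp, Q)
        fp = ((Yp ** 2).sum() - rp) / m / max(rp / (n - m - 1), 1e-300)
        if fp >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    fitted = Q @ (Q.T @ Y)
    U, s, _ = np.linalg.svd(fitted, full_matrices=False)
    n_axes = min(m, Y.shape[1])
    scores = U[:, :n_axes] * s[:n_axes]
    return RdaResult(selected=list(range(m)), r2=float(r2),
                     adj_r2=float(_adj_r2(r2, n, m)), pseudo_f=float(f_obs),
                     p_value=float(p), n_permutations=n_perm, site_scores=scores)
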