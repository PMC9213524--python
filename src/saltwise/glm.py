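"""Gene-wise negative-binomial GLMs on the strain x salinity factorial.

All genes share one design matrix, so fitting is vectorised: a single IRLS
loop updates every gene's coefficient vector simultaneously with batched
normal-equation solves.  The NB variance function is V(mu) = mu + phi*mu^2
with gene-wise dispersion phi; phi = 0 degenerates to Poisson.

Coefficients are reported on the log2 scale (the fold-change convention of
the rest of the pipeline); fitting happens internally in natural log.

Dispersion estimation follows the adjusted-profile-likelihood approach:
the Cox-Reid corrected profile likelihood is evaluated on a fixed grid of
dispersions for every gene, smoothed across genes ordered by average
abundance, and each gene's estimate maximises its own APL plus a
prior-weighted share of the local trend APL.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space
from scipy.special import gammaln

from .containers import (
    ContrastResult,
    ContrastSet,
    CountMatrix,
    ExperimentDesign,
    GeneFit,
)

__all__ = [
    "filter_genes",
    "normalization_factors",
    "tmm_factors",
    "estimate_dispersions",
    "fit_glm",
    "test_contrast",
    "test_contrasts",
    "constrained_deviance",
    "nb_loglik",
    "nb_deviance",
]

LN2 = np.log(2.0)
_ETA_MIN, _ETA_MAX = -40.0, 40.0
_MAX_ITER = 100
_REL_TOL = 1e-8


# ---------------------------------------------------------------------------
# filtering and normalisation


def filter_genes(
    counts: CountMatrix,
    design: ExperimentDesign | None = None,
    min_cpm: float = 1.0,
    min_samples: int = 3,
) -> CountMatrix:
    """Keep genes with CPM >= min_cpm in at least ``min_samples`` samples.

    Gene order is preserved.  An empty result triggers a warning rather
    than an error.
    """
    if min_samples > counts.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the number of samples "
            f"({counts.n_samples})"
        )
    totals = counts.values.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = np.asarray(counts.sample_ids)[totals == 0]
        raise ValueError(f"sample(s) with zero total count: {list(bad)}")
    cpm = counts.values / totals[None, :] * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("gene filter removed every gene", stacklevel=2)
    return CountMatrix(counts.counts.loc[keep])


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    M-values (log2 sample/reference count ratios, depth-normalised) and
    A-values (average log2 abundance) are computed on genes expressed in
    both samples; the upper and lower ``trim_m`` / ``trim_a`` fractions
    are discarded and the remaining M-values averaged with inverse
    asymptotic-variance weights.
    """
    Y = counts.values.astype(float)
    totals = Y.sum(axis=0)
    if (totals == 0).any():
        bad = np.asarray(counts.sample_ids)[totals == 0]
        raise ValueError(f"sample(s) with zero total count: {list(bad)}")
    n = counts.n_samples
    P = Y / totals[None, :]

    if reference is None:
        # reference = sample whose 75th percentile of scaled counts is
        # closest to the mean across samples
        uq = np.array([np.quantile(P[:, j][Y[:, j] > 0], 0.75) if (Y[:, j] > 0).any() else 0 for j in range(n)])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.sample_ids.index(reference)

    log_factors = np.zeros(n)
    pr = P[:, ref_idx]
    yr = Y[:, ref_idx]
    Nr = totals[ref_idx]
    for j in range(n):
        if j == ref_idx:
            continue
        pj, yj, Nj = P[:, j], Y[:, j], totals[j]
        ok = (yj > 0) & (yr > 0)
        if ok.sum() == 0:
            continue
        M = np.log2(pj[ok] / pr[ok])
        A = 0.5 * np.log2(pj[ok] * pr[ok])
        # asymptotic variance of M (delta method, binomial sampling)
        w = 1.0 / ((Nj - yj[ok]) / (Nj * yj[ok]) + (Nr - yr[ok]) / (Nr * yr[ok]))
        keep = np.ones(M.size, dtype=bool)
        if M.size > 10:
            m_lo, m_hi = np.quantile(M, [trim_m, 1 - trim_m])
            a_lo, a_hi = np.quantile(A, [trim_a, 1 - trim_a])
            keep = (M >= m_lo) & (M <= m_hi) & (A >= a_lo) & (A <= a_hi)
        if keep.sum() == 0:
            keep = np.ones(M.size, dtype=bool)
        log_factors[j] = np.sum(w[keep] * M[keep]) / np.sum(w[keep])

    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def normalization_factors(counts: CountMatrix, **kwargs) -> pd.Series:
    """Per-sample effective library sizes: total count x TMM factor."""
    factors = tmm_factors(counts, **kwargs)
    totals = pd.Series(
        counts.values.sum(axis=0).astype(float), index=counts.sample_ids
    )
    eff = totals * factors
    eff.name = "effective_library_size"
    return eff


def offsets_from_library_sizes(lib_sizes: pd.Series) -> pd.Series:
    """Natural-log offsets centred so that exp(offset) has geometric mean 1."""
    lo = np.log(lib_sizes.to_numpy(dtype=float))
    return pd.Series(lo - lo.mean(), index=lib_sizes.index, name="offset")


def average_log2_cpm(counts: CountMatrix, lib_sizes: np.ndarray, prior: float = 0.5) -> np.ndarray:
    """Mean log2 counts-per-million per gene with a small prior count."""
    cpm = (counts.values + prior) / (np.asarray(lib_sizes, float)[None, :] + 2 * prior) * 1e6
    return np.log2(cpm).mean(axis=1)


# ---------------------------------------------------------------------------
# NB likelihood machinery


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB log-likelihood summed over samples; rows are genes.

    phi may be a scalar or per-gene vector; phi = 0 entries use the
    Poisson limit.
    """
    y = np.atleast_2d(y)
    mu = np.maximum(np.atleast_2d(mu), 1e-300)
    phi = np.asarray(phi, float)
    if phi.ndim == 1:
        phi = phi.reshape(-1, 1)
    phi = np.broadcast_to(phi, y.shape)
    out = np.empty(y.shape)
    pois = phi < 1e-10
    if pois.any():
        out[pois] = y[pois] * np.log(mu[pois]) - mu[pois] - gammaln(y[pois] + 1)
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        m = mu[nb]
        yy = y[nb]
        out[nb] = (
            gammaln(yy + r)
            - gammaln(r)
            - gammaln(yy + 1)
            + yy * np.log(phi[nb] * m / (1 + phi[nb] * m))
            - r * np.log1p(phi[nb] * m)
        )
    return out.sum(axis=1)


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB residual deviance per gene (rows); 0*log0 treated as 0."""
    y = np.atleast_2d(np.asarray(y, float))
    mu = np.maximum(np.atleast_2d(mu), 1e-300)
    if np.ndim(phi) == 1:
        phi = np.asarray(phi, float).reshape(-1, 1)
    phi = np.broadcast_to(np.asarray(phi, float), y.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    pois = phi < 1e-10
    dev = np.empty(y.shape)
    if pois.any():
        dev[pois] = term1[pois] - (y[pois] - mu[pois])
    nb = ~pois
    if nb.any():
        dev[nb] = term1[nb] - (y[nb] + 1.0 / phi[nb]) * np.log(
            (1 + phi[nb] * y[nb]) / (1 + phi[nb] * mu[nb])
        )
    return 2.0 * dev.sum(axis=1)


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    phi: np.ndarray,
    beta_init: np.ndarray | None = None,
    max_iter: int = _MAX_ITER,
    tol: float = _REL_TOL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised IRLS for NB GLMs sharing design X (natural-log scale).

    y : (G, n) counts; X : (n, p); offsets : (n,); phi : (G,).
    Returns (beta (G, p), deviance (G,), converged (G,)).
    Step-halving guards against deviance increases.
    """
    G, n = y.shape
    p = X.shape[1]
    phi = np.asarray(phi, float)

    if beta_init is None:
        # one weighted least-squares pass on log counts
        z0 = np.log(np.maximum(y, 0.5)) - offsets[None, :]
        beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T
    else:
        beta = beta_init.copy()

    eta = np.clip(beta @ X.T, _ETA_MIN, _ETA_MAX)
    mu = np.exp(eta + offsets[None, :])
    dev = nb_deviance(y, mu, phi)
    active = np.ones(G, dtype=bool)
    converged = np.zeros(G, dtype=bool)

    for _ in range(max_iter):
        idx = np.where(active)[0]
        if idx.size == 0:
            break
        mu_a = mu[idx]
        phi_a = phi[idx][:, None]
        W = mu_a / (1.0 + phi_a * mu_a)
        z = (eta[idx]) + (y[idx] - mu_a) / mu_a
        WX = W[:, :, None] * X[None, :, :]  # (g, n, p)
        A = np.matmul(X.T[None, :, :], WX)
        A += np.eye(p)[None, :, :] * 1e-10
        b = np.matmul(X.T[None, :, :], (W * z)[:, :, None])
        beta_prop = np.linalg.solve(A, b)[..., 0]

        # step-halving on genes whose deviance would increase
        step = np.ones(idx.size)
        delta = beta_prop - beta[idx]
        for _half in range(10):
            beta_try = beta[idx] + step[:, None] * delta
            eta_try = np.clip(beta_try @ X.T, _ETA_MIN, _ETA_MAX)
            mu_try = np.exp(eta_try + offsets[None, :])
            dev_try = nb_deviance(y[idx], mu_try, phi[idx])
            worse = dev_try > dev[idx] * (1 + 1e-12) + 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5

        rel_change = np.abs(dev[idx] - dev_try) / (np.abs(dev_try) + 1.0)
        beta[idx] = beta_try
        eta[idx] = eta_try
        mu[idx] = mu_try
        dev[idx] = dev_try
        done = rel_change < tol
        converged[idx[done]] = True
        active[idx[done]] = False

    return beta, dev, converged


# ---------------------------------------------------------------------------
# dispersion estimation

_PHI_GRID = np.exp(np.linspace(np.log(1e-4), np.log(16.0), 19))


def _cox_reid_apl(
    y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    phi_value: float,
    beta_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cox-Reid adjusted profile log-likelihood at one dispersion value,
    for all genes: ll(beta_hat) - 0.5 * logdet(X' W X)."""
    G = y.shape[0]
    phi = np.full(G, phi_value)
    # APL is flat near the optimum; a looser IRLS tolerance suffices here
    beta, _, _ = _irls(y, X, offsets, phi, beta_init=beta_init, tol=1e-6, max_iter=50)
    mu = np.exp(np.clip(beta @ X.T, _ETA_MIN, _ETA_MAX) + offsets[None, :])
    ll = nb_loglik(y, mu, phi)
    W = mu / (1.0 + phi_value * mu)
    WX = W[:, :, None] * X[None, :, :]
    A = np.matmul(X.T[None, :, :], WX) + np.eye(X.shape[1])[None] * 1e-10
    sign, logdet = np.linalg.slogdet(A)
    return ll - 0.5 * logdet, beta


def _interpolated_argmax(score: np.ndarray, grid_log: np.ndarray) -> np.ndarray:
    """Quadratic interpolation of the per-row maximum on a log-spaced grid.
    Rows maximised at the lower boundary return -inf (dispersion 0)."""
    G, K = score.shape
    k = np.argmax(score, axis=1)
    out = grid_log[k].astype(float)
    interior = (k > 0) & (k < K - 1)
    ki = k[interior]
    rows = np.where(interior)[0]
    y0 = score[rows, ki - 1]
    y1 = score[rows, ki]
    y2 = score[rows, ki + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    step = grid_log[1] - grid_log[0]
    out[interior] = grid_log[ki] + shift * step
    out[k == 0] = -np.inf
    return out


def estimate_dispersions(
    counts: CountMatrix,
    design: ExperimentDesign,
    offsets: pd.Series,
    prior_df: float = 10.0,
    span_frac: float = 0.25,
) -> pd.Series:
    """Gene-wise NB dispersions, shrunk toward an abundance trend.

    The Cox-Reid APL is evaluated on a fixed dispersion grid; a moving
    average over genes ordered by average log2 CPM provides the trend
    likelihood, and each gene maximises
    ``APL_g(phi) + (prior_df / df_res) * APL_trend(phi)``.
    Genes maximised at the lower grid boundary report dispersion 0.
    """
    y = counts.values.astype(float)
    X = design.cell_means_matrix().loc[counts.sample_ids].to_numpy()
    o = offsets.loc[counts.sample_ids].to_numpy(dtype=float)
    G, n = y.shape
    p = int(np.linalg.matrix_rank(X))
    df_res = n - p
    if df_res < 1:
        raise ValueError(
            "residual degrees of freedom is zero; supply a common dispersion "
            "instead of estimating gene-wise values"
        )

    cols = []
    beta_warm = None
    for phi_k in _PHI_GRID:
        apl_k, beta_warm = _cox_reid_apl(y, X, o, phi_k, beta_init=beta_warm)
        cols.append(apl_k)
    apl = np.column_stack(cols)

    # trend: moving average of APL over abundance-sorted genes
    abundance = average_log2_cpm(counts, np.exp(o) * y.sum(axis=0).mean())
    order = np.argsort(abundance, kind="stable")
    window = max(int(np.ceil(span_frac * G)), 1)
    kernel = np.ones(window) / window
    apl_sorted = apl[order]
    smooth_sorted = np.empty_like(apl_sorted)
    for j in range(apl.shape[1]):
        padded = np.pad(apl_sorted[:, j], (window // 2, window - 1 - window // 2), mode="edge")
        smooth_sorted[:, j] = np.convolve(padded, kernel, mode="valid")
    apl_smooth = np.empty_like(apl)
    apl_smooth[order] = smooth_sorted

    weight = prior_df / df_res
    score = apl + weight * apl_smooth
    log_phi = _interpolated_argmax(score, np.log(_PHI_GRID))
    phi = np.exp(log_phi)
    phi[~np.isfinite(log_phi)] = 0.0
    return pd.Series(phi, index=counts.gene_ids, name="dispersion")


# ---------------------------------------------------------------------------
# model fit and contrast tests


def fit_glm(
    counts: CountMatrix,
    design: ExperimentDesign,
    offsets: pd.Series,
    dispersions: pd.Series,
) -> GeneFit:
    """Fit the cell-means NB GLM for every gene.

    Offsets are natural-log effective library sizes; dispersions are
    gene-wise phi.  Coefficients are returned in log2.  Non-converged
    genes are flagged but their coefficients are still reported.
    """
    Xdf = design.cell_means_matrix().loc[counts.sample_ids]
    X = Xdf.to_numpy()
    o = offsets.loc[counts.sample_ids].to_numpy(dtype=float)
    phi = dispersions.loc[counts.gene_ids].to_numpy(dtype=float)
    y = counts.values.astype(float)

    beta, dev, conv = _irls(y, X, o, phi)
    lib = np.exp(o) * y.sum(axis=0).mean() if y.size else np.exp(o)
    coef2 = pd.DataFrame(
        beta / LN2, index=counts.gene_ids, columns=list(Xdf.columns)
    )
    return GeneFit(
        coefficients=coef2,
        dispersions=pd.Series(phi, index=counts.gene_ids, name="dispersion"),
        offsets=pd.Series(o, index=counts.sample_ids, name="offset"),
        deviance=pd.Series(dev, index=counts.gene_ids, name="deviance"),
        converged=pd.Series(conv, index=counts.gene_ids, name="converged"),
        design=design,
        counts=counts,
        mean_log2cpm=pd.Series(
            average_log2_cpm(counts, lib), index=counts.gene_ids, name="avg_log2cpm"
        ),
    )


def _design_and_data(fit: GeneFit):
    Xdf = fit.design.cell_means_matrix().loc[fit.counts.sample_ids]
    X = Xdf.to_numpy()
    y = fit.counts.values.astype(float)
    o = fit.offsets.to_numpy(dtype=float)
    phi = fit.dispersions.to_numpy(dtype=float)
    beta_nat = fit.coefficients[list(Xdf.columns)].to_numpy() * LN2
    return X, y, o, phi, beta_nat


def constrained_deviance(
    fit: GeneFit, constraint: np.ndarray
) -> tuple[np.ndarray, int]:
    """Residual deviance of the model constrained by ``constraint @ beta = 0``.

    ``constraint`` is an (m, p) array of weight rows over the fitted
    cells.  Returns per-gene deviances and the constraint rank (the LRT
    degrees of freedom against the full model).
    """
    X, y, o, phi, beta_nat = _design_and_data(fit)
    C = np.atleast_2d(np.asarray(constraint, float))
    rank = int(np.linalg.matrix_rank(C))
    N = null_space(C)  # p x (p - rank)
    Xc = X @ N
    # warm start: project the full-model coefficients onto the null space
    init = beta_nat @ N  # N orthonormal => least-squares projection
    _, dev, _ = _irls(y, Xc, o, phi, beta_init=init)
    return dev, rank


def test_contrasts(
    fit: GeneFit,
    contrasts: ContrastSet,
    statistic: str = "lrt",
) -> ContrastResult:
    """Test every contrast of a family for every gene.

    logFC is the contrast applied to the fitted log2 cell means.  The
    default statistic is the likelihood-ratio test (chi-squared with 1
    degree of freedom); ``statistic="qlf"`` scales the LRT statistic by a
    gene-wise quasi-likelihood dispersion estimated from the residual
    deviance and refers it to an F distribution.
    """
    if statistic not in ("lrt", "qlf"):
        raise ValueError(f"unknown statistic {statistic!r}")
    X, y, o, phi, _ = _design_and_data(fit)
    n, p = X.shape
    df_res = n - int(np.linalg.matrix_rank(X))
    dev_full = fit.deviance.to_numpy()

    W = contrasts.weights[fit.cell_labels]
    logfc = fit.coefficients.to_numpy() @ W.to_numpy().T

    stats_mat = np.empty((len(fit.gene_ids), len(contrasts)))
    pvals = np.empty_like(stats_mat)
    for j, name in enumerate(contrasts.names):
        w = W.loc[name].to_numpy()
        if not np.any(w):
            raise ValueError(f"contrast {name!r} has all-zero weights")
        dev0, _ = constrained_deviance(fit, w[None, :])
        lr = np.maximum(dev0 - dev_full, 0.0)
        if statistic == "lrt":
            stats_mat[:, j] = lr
            pvals[:, j] = stats.chi2.sf(lr, df=1)
        else:
            s2 = np.maximum(dev_full / max(df_res, 1), 1e-8)
            f = lr / s2
            stats_mat[:, j] = f
            pvals[:, j] = stats.f.sf(f, 1, df_res)

    idx = fit.gene_ids
    cols = contrasts.names
    return ContrastResult(
        family=contrasts.family,
        logfc=pd.DataFrame(logfc, index=idx, columns=cols),
        stat=pd.DataFrame(stats_mat, index=idx, columns=cols),
        pvalue=pd.DataFrame(pvals, index=idx, columns=cols),
    )


def test_contrast(fit: GeneFit, weights: pd.Series, statistic: str = "lrt") -> ContrastResult:
    """Test a single zero-sum contrast given as a Series over cell labels."""
    w = weights.reindex(fit.cell_labels).fillna(0.0)
    if not np.any(w.to_numpy()):
        raise ValueError("contrast weights are all zero")
    if abs(float(w.sum())) > 1e-9:
        raise ValueError("contrast weights must sum to zero")
    cs = ContrastSet(
        family="single",
        weights=pd.DataFrame([w.to_numpy()], index=[weights.name or "contrast"], columns=fit.cell_labels),
    )
    return test_contrasts(fit, cs, statistic=statistic)
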