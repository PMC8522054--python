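"""Vectorized negative-binomial log-linear models for RNA-seq counts.

All genes share one design matrix, so Fisher scoring is batched across
genes with einsum-built normal equations. Counts y_gi follow
NB(mu_gi, alpha_g) with log mu_gi = offset_i + x_i' beta_g, where the
offset is the log library size and alpha_g is a per-gene dispersion
(variance = mu + alpha mu^2). Dispersions are method-of-moments
estimates shrunk on the log scale toward a fitted mean-dispersion trend
alpha(m) ~ a0 + a1/m, stabilising the small-sample estimates the same
way trended-dispersion DE tools do. Group effects are tested with a
1-df likelihood-ratio chi-square between nested designs, holding the
dispersion fixed across the two fits.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

_EPS = 1e-8
_MAX_ITER = 50
_TOL = 1e-8


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (library-size fallback for sparse data)."""
    counts = np.asarray(counts, dtype=float)
    libsize = counts.sum(axis=0)
    if np.any(libsize <= 0):
        raise ValueError("all-zero column in count matrix")
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    ref = logc[np.all(np.isfinite(logc), axis=1)]
    if ref.shape[0] >= 10:
        sf = np.exp(np.median(ref - ref.mean(axis=1, keepdims=True), axis=0))
    else:
        sf = libsize / np.exp(np.mean(np.log(libsize)))
    return sf


def estimate_dispersions(
    counts: np.ndarray,
    sf: np.ndarray | None = None,
    shrink_weight: float = 0.5,
    groups: np.ndarray | list | None = None,
) -> np.ndarray:
    """Trend-shrunk method-of-moments NB dispersions, one per gene.

    With ``groups`` (one label per column, e.g. the design cells), the
    moment estimate pools within-group means/variances so that real
    group effects do not inflate the dispersion.
    """
    counts = np.asarray(counts, dtype=float)
    if sf is None:
        sf = size_factors(counts)
    norm = counts / sf
    if groups is None:
        groups = np.zeros(counts.shape[1], dtype=int)
    groups = np.asarray(groups)
    raw_num = np.zeros(counts.shape[0])
    raw_den = 0.0
    m_parts = []
    for lab in np.unique(groups):
        cols = groups == lab
        nj = int(cols.sum())
        if nj < 2:
            continue
        mj = norm[:, cols].mean(axis=1)
        vj = norm[:, cols].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            aj = (vj - mj) / np.square(mj)
        aj = np.where(np.isfinite(aj), aj, _EPS)
        raw_num += (nj - 1) * np.clip(aj, _EPS, 10.0)
        raw_den += nj - 1
        m_parts.append(mj)
    if raw_den == 0:
        raise ValueError("no group with at least two columns")
    raw = np.clip(raw_num / raw_den, _EPS, 10.0)
    m = np.mean(m_parts, axis=0)
    ok = m > 0
    if ok.sum() >= 10:
        # robust trend: alpha ~ a0 + a1/m fitted on genes with positive mean
        A = np.column_stack([np.ones(ok.sum()), 1.0 / m[ok]])
        coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
        trend = np.clip(coef[0] + coef[1] / np.clip(m, _EPS, None), _EPS, 10.0)
    else:
        trend = np.full_like(raw, np.median(raw))
    shrunk = np.exp(
        shrink_weight * np.log(trend) + (1.0 - shrink_weight) * np.log(raw)
    )
    return np.clip(shrunk, _EPS, 10.0)


def fit_nbglm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched Fisher-scoring fit.

    Parameters
    ----------
    y : (G, n) counts, X : (n, p) design, offset : (n,) log exposures,
    alpha : (G,) dispersions.

    Returns (beta (G, p), deviance (G,), converged (G,) bool).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    G, n = y.shape
    p = X.shape[1]
    alpha = np.asarray(alpha, dtype=float)

    # initialise intercept from mean rate, other coefficients at zero
    beta = np.zeros((G, p))
    mean_rate = np.clip(y.mean(axis=1) / np.exp(offset).mean(), _EPS, None)
    beta[:, 0] = np.log(mean_rate)

    converged = np.zeros(G, dtype=bool)
    ridge = 1e-8 * np.eye(p)
    for _ in range(_MAX_ITER):
        eta = offset + beta @ X.T  # (G, n)
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)  # Fisher weights for log link
        z = (eta - offset) + (y - mu) / mu  # working response
        XtWX = np.einsum("ip,gi,iq->gpq", X, W, X) + ridge
        XtWz = np.einsum("ip,gi,gi->gp", X, W, z)
        new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = new_beta
        converged = delta < _TOL
        if converged.all():
            break
    dev = nb_deviance(y, np.exp(np.clip(offset + beta @ X.T, -30, 30)), alpha)
    return beta, dev, converged


def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Summed NB deviance per gene (rows)."""
    a = alpha[:, None]
    mu = np.clip(mu, _EPS, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    term2 = (y + 1.0 / a) * np.log((1.0 + a * y) / (1.0 + a * mu))
    return 2.0 * np.sum(term1 - term2, axis=1)


def nb_lrt(
    counts: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    offset: np.ndarray | None = None,
    alpha: np.ndarray | None = None,
    coef_index: int = -1,
    groups: np.ndarray | list | None = None,
) -> dict[str, np.ndarray]:
    """Likelihood-ratio test of the coefficient dropped from X_full.

    Returns a dict with log2 fold change of the tested coefficient,
    chi-square statistic, p-value, and a tested mask (False where the
    fit failed or the design is degenerate for the gene).
    """
    counts = np.asarray(counts)
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be integers")
    counts = counts.astype(float)
    if offset is None:
        offset = np.log(np.clip(counts.sum(axis=0), 1.0, None))
    if alpha is None:
        alpha = estimate_dispersions(counts, groups=groups)
    beta_f, dev_f, conv_f = fit_nbglm(counts, X_full, offset, alpha)
    beta_r, dev_r, conv_r = fit_nbglm(counts, X_reduced, offset, alpha)
    lr = np.clip(dev_r - dev_f, 0.0, None)
    pvals = stats.chi2.sf(lr, df=1)
    log2fc = beta_f[:, coef_index] / np.log(2.0)
    tested = conv_f & conv_r & np.isfinite(pvals)
    return {
        "log2fc": log2fc,
        "stat": lr,
        "pvalue": pvals,
        "tested": tested,
        "dispersion": alpha,
    }
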