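"""Per-gene weighted linear models with empirical-Bayes moderation.

The modeling chain re-creates the standard microarray-style pipeline for
RNA-seq counts: precision weights from the mean-variance trend of log-CPM
(``voom_weights``), a single consensus intra-individual correlation pooled
across genes (``consensus_block_correlation``) so repeated samples from one
individual are modeled as a compound-symmetric block rather than treated as
independent, per-gene generalized least squares for an arbitrary contrast
(``fit_contrast``), empirical-Bayes shrinkage of the residual variances
toward a common prior (``ebayes_moderate``), and Benjamini-Hochberg FDR
(``bh_adjust``).

The individual "random effect" is thus approximated by a fixed pooled
within-block correlation — the tractable GLS surrogate for a per-gene mixed
model, adequate when the between-individual variance component is broadly
similar across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

VOOM_SPAN = 0.5
WEIGHT_CLIP = 1e6  # weights clipped to [median/clip, median*clip]


@dataclass
class GeneFits:
    """Per-gene GLS results for one contrast."""

    estimate: np.ndarray  # contrast estimate (log2 fold change)
    stdev_unscaled: np.ndarray  # se / residual sd
    s2: np.ndarray  # residual variance
    df_residual: np.ndarray


def design_matrix(
    metadata: pd.DataFrame,
    factors: list[str] = (),
    numeric: list[str] = (),
    interactions: list[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Treatment-coded design: intercept, factor dummies (first level as
    baseline), numeric covariates, and pairwise factor interactions."""
    n = len(metadata)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}
    dummies: dict[str, pd.DataFrame] = {}
    for f in factors:
        d = pd.get_dummies(metadata[f].astype(str), prefix=f, drop_first=True).astype(float)
        dummies[f] = d
        for c in d.columns:
            cols[c] = d[c].to_numpy()
    for v in numeric:
        cols[v] = metadata[v].to_numpy(dtype=float)
    for fa, fb in interactions:
        for ca in dummies[fa].columns:
            for cb in dummies[fb].columns:
                cols[f"{ca}:{cb}"] = dummies[fa][ca].to_numpy() * dummies[fb][cb].to_numpy()
    X = pd.DataFrame(cols, index=metadata.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is not full column rank")
    return X


def contrast_vector(design: pd.DataFrame, weights: dict[str, float]) -> np.ndarray:
    """Contrast c over design columns, e.g. {'species_human': 1.0}."""
    c = np.zeros(design.shape[1])
    for name, w in weights.items():
        if name not in design.columns:
            raise KeyError(f"no design column {name!r}; have {list(design.columns)}")
        c[design.columns.get_loc(name)] = w
    return c


def _log2cpm_voom(counts: np.ndarray, lib: np.ndarray) -> np.ndarray:
    return np.log2((counts + 0.5) / (lib + 1.0) * 1e6)


def voom_weights(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    span: float = VOOM_SPAN,
    lib_sizes: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-observation precision weights from the log-count mean-variance trend.

    Per-gene OLS residual standard deviations (quarter-root of the variance)
    are smoothed against mean log2 count with lowess; each observation's
    weight is the inverse fourth power of the trend evaluated at its fitted
    log2 count. Low counts are noisy on the log scale and get small weights.
    """
    G, n = counts.shape
    if G < 50:
        raise ValueError(f"mean-variance trend unreliable with {G} genes (< 50)")
    X = design.to_numpy(dtype=float)
    p = X.shape[1]
    if n <= p:
        raise ValueError("no residual degrees of freedom")
    C = counts.to_numpy(dtype=float)
    lib = C.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, dtype=float)
    Y = _log2cpm_voom(C, lib)  # genes x samples
    pinv = np.linalg.pinv(X)  # p x n
    coef = Y @ pinv.T  # genes x p
    fitted = coef @ X.T
    resid = Y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))
    sx = Y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    lo = lowess(sy, sx, frac=span, it=3, return_sorted=True)
    lx, ly = lo[:, 0], np.maximum(lo[:, 1], 1e-8)
    fitted_cpm = 2.0**fitted
    fitted_count = np.log2(fitted_cpm * (lib + 1.0)[None, :] * 1e-6)
    trend = np.interp(fitted_count, lx, ly)  # constant extension at the ends
    w = trend**-4
    med = np.median(w)
    w = np.clip(w, med / WEIGHT_CLIP, med * WEIGHT_CLIP)
    return pd.DataFrame(w, index=counts.index, columns=counts.columns)


def consensus_block_correlation(
    values: pd.DataFrame, design: pd.DataFrame, blocks: pd.Series
) -> float:
    """Pooled intra-block residual correlation.

    Per gene, OLS residuals give the ratio of the mean within-block
    cross-product to the residual variance; per-gene ratios are pooled by
    averaging Fisher-z values. Because the OLS projection both deflates
    within-block cross-products and leaks correlation into the variance,
    the pooled ratio is then mapped back to rho by inverting its exact
    finite-sample expectation under a compound-symmetric model (both the
    expected cross-product and the expected residual sum of squares are
    linear in rho for a fixed design, so the inversion is closed-form).
    Returns 0 (with a warning) when no block has two samples.
    """
    X = design.to_numpy(dtype=float)
    Y = values.to_numpy(dtype=float)
    n, p = X.shape
    blocks = blocks.reindex(values.columns)
    B = pd.get_dummies(blocks.astype(str)).to_numpy(dtype=float)  # samples x blocks
    sizes = B.sum(axis=0)
    npairs = float(np.sum(sizes * (sizes - 1) / 2))
    if npairs == 0:
        import warnings

        warnings.warn("no block with >= 2 samples; consensus correlation set to 0",
                      stacklevel=2)
        return 0.0
    pinv = np.linalg.pinv(X)
    R = Y - (Y @ pinv.T) @ X.T  # genes x samples residuals
    block_sums = R @ B  # genes x blocks
    cross = 0.5 * ((block_sums**2).sum(axis=1) - ((R**2) @ B).sum(axis=1))
    s2 = (R**2).sum(axis=1) / (n - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_g = (cross / npairs) / s2
    ratio_g = ratio_g[np.isfinite(ratio_g)]
    ratio_g = np.clip(ratio_g, -0.99, 0.99)
    t_obs = float(np.tanh(np.mean(np.arctanh(ratio_g))))

    # bias inversion: with Sigma = sigma^2 [I + rho (S - I)], S the same-block
    # indicator, E[cross] = sigma^2 (c1 + rho c2) and
    # E[RSS] = sigma^2 (n - p + rho c3), all computable from the projection
    M = np.eye(n) - X @ pinv
    S_off = (B @ B.T) - np.eye(n)
    W2 = M @ S_off @ M
    c1 = 0.5 * float(np.sum(S_off * M))
    c2 = 0.5 * float(np.sum(S_off * W2))
    c3 = float(np.trace(W2))
    denom = t_obs * c3 / (n - p) - c2 / npairs
    if abs(denom) < 1e-12:
        rho = t_obs
    else:
        rho = (c1 / npairs - t_obs) / denom
    return float(np.clip(rho, -0.999, 0.999))


def _block_corr_matrix(blocks: pd.Series, rho: float, columns: pd.Index) -> np.ndarray:
    b = blocks.reindex(columns).astype(str).to_numpy()
    same = b[:, None] == b[None, :]
    C = np.where(same, rho, 0.0)
    np.fill_diagonal(C, 1.0)
    return C


def fit_contrast(
    values: pd.DataFrame,
    design: pd.DataFrame,
    contrast: np.ndarray,
    weights: pd.DataFrame | None = None,
    rho: float = 0.0,
    blocks: pd.Series | None = None,
) -> GeneFits:
    """Per-gene GLS contrast estimate under block compound symmetry.

    The observation covariance for gene g is
    ``diag(1/sqrt(w_g)) @ C(rho) @ diag(1/sqrt(w_g))`` with C the
    compound-symmetric block correlation. With rho = 0 and unit weights this
    reduces exactly to OLS.
    """
    X = design.to_numpy(dtype=float)
    Y = values.to_numpy(dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    c = np.asarray(contrast, dtype=float)
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")

    if weights is None and rho == 0.0:
        pinv = np.linalg.pinv(X)
        coef = Y @ pinv.T
        resid = Y - coef @ X.T
        s2 = (resid**2).sum(axis=1) / df
        xtx_inv = np.linalg.inv(X.T @ X)
        su = float(np.sqrt(c @ xtx_inv @ c))
        return GeneFits(
            estimate=coef @ c,
            stdev_unscaled=np.full(G, su),
            s2=s2,
            df_residual=np.full(G, df, dtype=float),
        )

    if rho != 0.0:
        if blocks is None:
            raise ValueError("blocks required when rho != 0")
        Cmat = _block_corr_matrix(blocks, rho, values.columns)
    else:
        Cmat = np.eye(n)
    W = weights.to_numpy(dtype=float) if weights is not None else np.ones_like(Y)
    est = np.empty(G)
    su = np.empty(G)
    s2 = np.empty(G)
    dfs = np.full(G, df, dtype=float)
    for g in range(G):
        d = 1.0 / np.sqrt(W[g])
        V = Cmat * np.outer(d, d)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            est[g] = np.nan
            su[g] = np.nan
            s2[g] = np.nan
            dfs[g] = 0.0
            continue
        Xw = np.linalg.solve(L, X)
        yw = np.linalg.solve(L, Y[g])
        xtx = Xw.T @ Xw
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ (Xw.T @ yw)
        r = yw - Xw @ beta
        est[g] = c @ beta
        su[g] = np.sqrt(c @ xtx_inv @ c)
        s2[g] = (r @ r) / df
    return GeneFits(estimate=est, stdev_unscaled=su, s2=s2, df_residual=dfs)


def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0^2) on log variances.

    Follows the classic approach: the log residual variances, after removing
    the digamma/log bias of a chi-square on df degrees of freedom, have
    excess variance equal to trigamma(d0/2); inverting trigamma gives the
    prior degrees of freedom. Non-positive excess variance means the
    variances are consistent with a common value: d0 = inf (pooled variance).
    """
    ok = np.isfinite(s2) & (df > 0) & (s2 > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError("need >= 2 finite variances")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1) - np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(emean))
    return d0, s0


def ebayes_moderate(fits: GeneFits, min_genes: int = 100) -> pd.DataFrame:
    """Moderated t statistics and p-values from shrunken variances.

    Posterior variance: (d0*s0^2 + d_g*s_g^2) / (d0 + d_g); the moderated t
    replaces s_g with the posterior sd and gains d0 extra degrees of freedom.
    """
    n_ok = int(np.sum(np.isfinite(fits.s2)))
    if n_ok < min_genes:
        raise ValueError(f"need >= {min_genes} genes for hyperparameter estimation, got {n_ok}")
    d0, s0 = estimate_prior(fits.s2, fits.df_residual)
    if np.isinf(d0):
        post_s2 = np.full_like(fits.s2, s0)
        df_total = np.full_like(fits.df_residual, np.inf)
    else:
        post_s2 = (d0 * s0 + fits.df_residual * fits.s2) / (d0 + fits.df_residual)
        df_total = d0 + fits.df_residual
    t = fits.estimate / (fits.stdev_unscaled * np.sqrt(post_s2))
    with np.errstate(invalid="ignore"):
        p = np.where(
            np.isinf(df_total),
            2.0 * stats.norm.sf(np.abs(t)),
            2.0 * stats.t.sf(np.abs(t), np.where(np.isfinite(df_total), df_total, 1.0)),
        )
    p = np.where(np.isfinite(t), p, np.nan)
    return pd.DataFrame(
        {
            "logFC": fits.estimate,
            "t": t,
            "p": p,
            "s2_post": post_s2,
            "df_total": df_total,
            "d0": d0,
            "s0_sq": s0,
        }
    )


def bh_adjust(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN propagated)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="stable")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def de_contrast(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    design: pd.DataFrame,
    contrast: np.ndarray,
    block_col: str | None = None,
    use_voom: bool = True,
    use_tmm: bool = True,
) -> pd.DataFrame:
    """End-to-end differential expression for one contrast.

    Computes TMM-effective library sizes (library composition shifts would
    otherwise masquerade as coherent per-gene effects), log2 CPM on those
    libraries, voom-style weights, the pooled block correlation when
    ``block_col`` is given, the GLS contrast fit, empirical-Bayes
    moderation and BH FDR. Returns a gene-indexed table (logFC, t, p, fdr).
    """
    from .expression import log2_cpm, tmm_factors

    lib = counts.sum(axis=0)
    if use_tmm:
        lib = lib * tmm_factors(counts)
    y = log2_cpm(counts, lib_sizes=lib).values
    weights = voom_weights(counts, design, lib_sizes=lib) if use_voom else None
    rho = 0.0
    blocks = None
    if block_col is not None:
        blocks = metadata.reindex(counts.columns)[block_col]
        rho = consensus_block_correlation(y, design, blocks)
    fits = fit_contrast(y, design, contrast, weights=weights, rho=rho, blocks=blocks)
    tab = ebayes_moderate(fits)
    tab.index = counts.index
    tab["fdr"] = bh_adjust(tab["p"].to_numpy())
    return tab[["logFC", "t", "p", "fdr"]]
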