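"""Count normalization and descriptive comparisons.

The normalization chain mirrors standard bulk RNA-seq practice for
cross-species comparisons: raw counts -> log2 counts per million (CPM) ->
expression filter (mean log2 CPM > 2 in at least one cell/tissue group) ->
TMM library-composition factors -> cyclic-loess removal of residual
intensity-dependent trends -> optionally log2 RPKM using per-species
*orthologous* gene lengths (the summed lengths of a gene's surviving
orthologous metaexons), which makes expression levels comparable between
genomes with different annotated gene structures.

Descriptive tools: PCA with per-component covariate association tests,
pairwise-correlation group comparisons (e.g. day-27 cardiomyocytes vs
hearts against day-15 cardiomyocytes vs hearts), and average-linkage
clustering of the correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PRIOR_COUNT = 0.25
EXPRESSION_THRESHOLD = 2.0  # mean log2 CPM a group must exceed (strictly)
TMM_LOGRATIO_TRIM = 0.30
TMM_ABUNDANCE_TRIM = 0.05
LOESS_SPAN = 0.7
LOESS_ITERATIONS = 3


@dataclass
class NormalizedMatrix:
    """A genes x samples log2-scale expression matrix with provenance."""

    values: pd.DataFrame
    normalization: str


def log2_cpm(
    counts: pd.DataFrame,
    prior_count: float = DEFAULT_PRIOR_COUNT,
    lib_sizes: pd.Series | None = None,
) -> NormalizedMatrix:
    """log2((count + prior) / (lib_size + 2*prior) * 1e6), per observation.

    The prior keeps zero counts finite; the 2*prior library adjustment keeps
    the values a proper log-proportion (as in edgeR's ``cpm(log=TRUE)``).
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    if (lib_sizes <= 0).any():
        bad = lib_sizes.index[lib_sizes <= 0].tolist()
        raise ValueError(f"zero/negative library size for sample(s): {bad}")
    vals = np.log2(
        (counts.to_numpy(dtype=float) + prior_count)
        / (lib_sizes.to_numpy(dtype=float) + 2 * prior_count)
        * 1e6
    )
    return NormalizedMatrix(
        values=pd.DataFrame(vals, index=counts.index, columns=counts.columns),
        normalization="log2CPM",
    )


def filter_expressed(
    log2cpm: NormalizedMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    threshold: float = EXPRESSION_THRESHOLD,
    group_col: str = "group",
) -> pd.Index:
    """Genes whose mean log2 CPM strictly exceeds ``threshold`` in >= 1 group."""
    vals = log2cpm.values if isinstance(log2cpm, NormalizedMatrix) else log2cpm
    keep = pd.Series(False, index=vals.index)
    for group, sub in metadata.groupby(group_col):
        cols = sub.index.intersection(vals.columns)
        if len(cols) == 0:
            raise ValueError(f"group {group!r} has no samples in the matrix")
        keep |= vals[cols].mean(axis=1) > threshold
    return vals.index[keep]


def _quantile_factor(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.quantile(counts, p, axis=0) / lib


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    logratio_trim: float = TMM_LOGRATIO_TRIM,
    abundance_trim: float = TMM_ABUNDANCE_TRIM,
) -> pd.Series:
    """Trimmed-mean-of-M-values composition factors, one per sample.

    For each sample against the reference, per-gene log-ratios M and
    abundances A are computed on the proportion scale (genes zero in either
    sample excluded), the most extreme 30% of M on each tail and 5% of A on
    each tail are trimmed, and the remaining M are averaged with
    inverse-asymptotic-variance (delta-method binomial) weights. The factor
    is 2^(that mean); factors are rescaled to geometric mean 1 so they only
    encode relative composition. The reference defaults to the sample whose
    upper-quartile proportion is closest to the mean upper quartile.
    """
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    if ref_sample is None:
        f75 = _quantile_factor(X, lib)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)
    ref = X[:, ref_idx]
    nref = lib[ref_idx]
    factors = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        factors[j] = _tmm_pair(
            X[:, j], lib[j], ref, nref, logratio_trim, abundance_trim
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(
    obs: np.ndarray,
    nobs: float,
    ref: np.ndarray,
    nref: float,
    logratio_trim: float,
    abundance_trim: float,
) -> float:
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        return 1.0
    po = obs[mask] / nobs
    pr = ref[mask] / nref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    # asymptotic variance of M (binomial delta method)
    v = (nobs - obs[mask]) / (nobs * obs[mask]) + (nref - ref[mask]) / (nref * ref[mask])
    n = M.size
    if np.max(M) - np.min(M) < 1e-6:
        return 1.0
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abundance_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(M)
    rank_a = stats.rankdata(A)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        import warnings

        warnings.warn("no genes survive TMM trimming; factor set to 1", stacklevel=2)
        return 1.0
    f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def cyclic_loess(
    log2cpm: NormalizedMatrix | pd.DataFrame,
    span: float = LOESS_SPAN,
    iterations: int = LOESS_ITERATIONS,
    mode: str = "pairwise",
) -> NormalizedMatrix:
    """Iteratively remove intensity-dependent log-ratio trends between samples.

    In ``pairwise`` mode every sample pair (i, j) contributes: a loess curve
    of M = x_i - x_j on A = (x_i + x_j)/2 is fitted and half of the fitted
    trend is subtracted from x_i and added to x_j. In ``reference`` mode each
    sample is normalized against the row-mean pseudo-reference (faster,
    single pass per sample per iteration).
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    src = log2cpm.values if isinstance(log2cpm, NormalizedMatrix) else log2cpm
    X = src.to_numpy(dtype=float).copy()
    n_genes, n_samples = X.shape
    if n_genes < 50:
        raise ValueError(f"cyclic loess needs >= 50 genes, got {n_genes}")
    span_delta = 0.01 * (np.nanmax(X) - np.nanmin(X))

    def fitted_trend(m: np.ndarray, a: np.ndarray) -> np.ndarray:
        sm = lowess(m, a, frac=span, it=3, delta=span_delta, return_sorted=True)
        return np.interp(a, sm[:, 0], sm[:, 1])

    for _ in range(iterations):
        if mode == "pairwise":
            for i in range(n_samples):
                for j in range(i + 1, n_samples):
                    a = 0.5 * (X[:, i] + X[:, j])
                    m = X[:, i] - X[:, j]
                    fit = fitted_trend(m, a)
                    X[:, i] -= fit / 2
                    X[:, j] += fit / 2
        elif mode == "reference":
            ref = X.mean(axis=1)
            for i in range(n_samples):
                a = 0.5 * (X[:, i] + ref)
                m = X[:, i] - ref
                X[:, i] -= fitted_trend(m, a)
        else:
            raise ValueError(f"mode must be 'pairwise' or 'reference', got {mode!r}")
    tag = (log2cpm.normalization if isinstance(log2cpm, NormalizedMatrix) else "log2") + "+loess"
    return NormalizedMatrix(
        values=pd.DataFrame(X, index=src.index, columns=src.columns),
        normalization=tag,
    )


def log2_rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    tmm: pd.Series | None = None,
    prior_count: float = DEFAULT_PRIOR_COUNT,
) -> NormalizedMatrix:
    """log2 RPKM on TMM-effective library sizes.

    value = log2CPM(counts, lib_size * factor) - log2(gene_length / 1000).
    ``gene_lengths`` must be the species-appropriate orthologous lengths.
    """
    missing = counts.index.difference(gene_lengths.index)
    if len(missing) > 0:
        raise KeyError(f"genes missing from length table: {missing.tolist()[:10]}")
    lib = counts.sum(axis=0)
    if tmm is not None:
        lib = lib * tmm.reindex(counts.columns)
    cpm = log2_cpm(counts, prior_count=prior_count, lib_sizes=lib)
    lengths = gene_lengths.reindex(counts.index).to_numpy(dtype=float)
    vals = cpm.values.to_numpy() - np.log2(lengths / 1000.0)[:, None]
    return NormalizedMatrix(
        values=pd.DataFrame(vals, index=counts.index, columns=counts.columns),
        normalization="log2RPKM" + ("(TMM)" if tmm is not None else ""),
    )


def pca_with_association(
    normalized: NormalizedMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: list[str],
    n_components: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Sample PCA plus per-(PC, covariate) association tests.

    Genes are centered; components come from the SVD of the samples x genes
    matrix. For each component and covariate, a one-way linear model F-test
    (categorical covariate) or simple regression (numeric) gives the
    association p-value. Returns (scores, variance_fractions, pvalues);
    a constant covariate yields NaN.
    """
    vals = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    X = vals.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    n_samples = X.shape[0]
    if n_samples < 3:
        raise ValueError("PCA needs >= 3 samples")
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    k = n_components or min(n_samples - 1, len(S))
    scores = pd.DataFrame(
        (U * S)[:, :k], index=vals.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    var_frac = pd.Series(S**2 / np.sum(S**2), index=[f"PC{i+1}" for i in range(len(S))])
    pvals = pd.DataFrame(index=scores.columns, columns=covariates, dtype=float)
    meta = metadata.reindex(vals.columns)
    for cov in covariates:
        col = meta[cov]
        for pc in scores.columns:
            pvals.loc[pc, cov] = _association_pvalue(scores[pc].to_numpy(), col)
    return scores, var_frac, pvals


def _association_pvalue(score: np.ndarray, covariate: pd.Series) -> float:
    if covariate.nunique() < 2:
        return float("nan")
    if pd.api.types.is_numeric_dtype(covariate):
        res = stats.linregress(covariate.to_numpy(dtype=float), score)
        return float(res.pvalue)
    groups = [score[(covariate == g).to_numpy()] for g in covariate.unique()]
    return float(stats.f_oneway(*groups).pvalue)


def correlation_group_test(
    normalized: NormalizedMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    tissue_group: str,
    cm_groups: tuple[str, str],
    group_col: str = "group",
) -> dict:
    """Do samples of one group correlate more strongly with a tissue than another's?

    Every tissue (e.g. heart) sample's Pearson correlation with every sample
    of each candidate group is averaged per tissue sample, and the two
    per-tissue-sample mean-correlation vectors are compared with a paired
    t-test (pairing unit: the tissue sample).
    """
    vals = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    meta = metadata.reindex(vals.columns)

    def samples_of(group: str) -> list[str]:
        s = meta.index[meta[group_col] == group].tolist()
        if len(s) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 samples")
        return s

    tissue = samples_of(tissue_group)
    corr = vals.corr(method="pearson")
    means = {}
    for g in cm_groups:
        cols = samples_of(g)
        means[g] = corr.loc[tissue, cols].mean(axis=1)
    t, p = stats.ttest_rel(means[cm_groups[0]], means[cm_groups[1]])
    return {
        "mean_correlations": pd.DataFrame(means),
        "t_statistic": float(t),
        "p_value": float(p),
        "mean_difference": float(means[cm_groups[0]].mean() - means[cm_groups[1]].mean()),
    }


def correlation_clusters(
    normalized: NormalizedMatrix | pd.DataFrame, n_clusters: int
) -> pd.Series:
    """Average-linkage agglomerative clustering of samples on 1 - Pearson r."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    vals = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    corr = vals.corr(method="pearson").to_numpy()
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    Z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=vals.columns, name="cluster")
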