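"""Count normalization, feature selection, read thinning, outlier flagging.

Matrices are pandas DataFrames with genes in rows and samples in columns.
Normalization follows the median-of-ratios ("DESeq") size-factor method of
Anders & Huber; expression is reported as log2(count / size_factor + 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NormalizationError, NumericalError, StructuralError


def deseq_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    For each gene with a strictly positive geometric mean across samples,
    form the ratio of each sample's count to that geometric mean; a sample's
    size factor is the median of its ratios.  Genes with any zero count are
    excluded from the reference (their log geometric mean is -inf).
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise StructuralError("count matrix contains negative entries")
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene with all-positive counts: cannot form a geometric-mean reference")
    logs = np.log(values[positive])
    log_geomean = logs.mean(axis=1)
    ratios = np.exp(logs - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_log2(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), genes x samples, finite everywhere."""
    sf = np.asarray(size_factors, dtype=float)
    if sf.shape != (counts.shape[1],):
        raise StructuralError(
            f"size_factors length {sf.shape} does not match {counts.shape[1]} samples")
    if (sf <= 0).any():
        raise StructuralError("size factors must be positive")
    expr = np.log2(counts.to_numpy(dtype=float) / sf[None, :] + 1.0)
    return pd.DataFrame(expr, index=counts.index, columns=counts.columns)


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Convenience wrapper: size factors + log2 normalization in one call."""
    sf = deseq_size_factors(counts)
    return normalize_log2(counts, sf), sf


def variance_filter(matrix: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """Keep the ceil(fraction * n_genes) highest-variance genes.

    Ties at the retention boundary are broken by input order (earlier rows
    win); the surviving genes keep their original relative order.
    """
    if not (0.0 < fraction <= 1.0):
        raise ConfigurationError(f"invalid fraction: {fraction!r} not in (0, 1]")
    n_genes = matrix.shape[0]
    if n_genes == 0:
        raise StructuralError("empty matrix")
    n_keep = int(np.ceil(fraction * n_genes))
    variances = matrix.to_numpy(dtype=float).var(axis=1, ddof=1) if matrix.shape[1] > 1 \
        else np.zeros(n_genes)
    # stable sort on (-variance, input order): ties favour earlier genes
    order = np.lexsort((np.arange(n_genes), -variances))
    keep = np.sort(order[:n_keep])
    return matrix.iloc[keep]


def subset_panel(matrix: pd.DataFrame,
                 panel: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Restrict to a gene panel, in panel order; report missing panel genes."""
    if len(panel) == 0:
        raise ConfigurationError("invalid panel: empty gene list")
    present = [g for g in panel if g in matrix.index]
    missing = [g for g in panel if g not in matrix.index]
    if not present:
        raise StructuralError("panel has empty intersection with the gene set")
    return matrix.loc[present], missing


def thin_counts(counts: pd.DataFrame, target_total_per_sample: int,
                seed: int) -> pd.DataFrame:
    """Binomially downsample each sample to roughly a target total count.

    For a sample with total T > target, each gene count is replaced by a
    Binomial(count, target/T) draw — the count-level equivalent (in
    expectation) of subsampling the underlying reads.  Samples already at or
    below the target are left untouched.  Zeros stay zero and no count ever
    increases.
    """
    if target_total_per_sample < 0:
        raise ConfigurationError(
            f"invalid target_total_per_sample: {target_total_per_sample} < 0")
    rng = np.random.default_rng(seed)
    values = counts.to_numpy(dtype=np.int64).copy()
    totals = values.sum(axis=0)
    for j in range(values.shape[1]):
        if totals[j] > target_total_per_sample:
            p = target_total_per_sample / totals[j]
            values[:, j] = rng.binomial(values[:, j], p)
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def flag_outliers_pca(matrix: pd.DataFrame, n_components: int = 5,
                      score_quantile: float = 0.99,
                      residual_quantile: float = 0.99) -> pd.Series:
    """Flag outlying samples by PCA score distance or reconstruction residual.

    Samples (columns) are projected onto the first ``n_components`` principal
    components of the gene-by-sample expression matrix.  A sample is flagged
    if its Hotelling-type score distance (sum of squared standardized scores)
    or its residual sum of squares exceeds the respective empirical quantile
    over samples — an automatic surrogate for visual inspection of PCA scores
    and residuals.
    """
    from sklearn.decomposition import PCA

    n_genes, n_samples = matrix.shape
    if n_components >= min(n_genes, n_samples):
        raise ConfigurationError(
            f"invalid n_components: {n_components} >= min(genes, samples)")
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    if np.allclose(X.var(axis=0), 0.0):
        raise NumericalError("degenerate matrix: all genes are constant across samples")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    eigvals = pca.explained_variance_
    eigvals = np.where(eigvals > 0, eigvals, np.inf)  # flat directions carry no distance
    score_dist = ((scores ** 2) / eigvals[None, :]).sum(axis=1)
    residual = ((X - pca.inverse_transform(scores)) ** 2).sum(axis=1)
    flags = (score_dist > np.quantile(score_dist, score_quantile)) | \
            (residual > np.quantile(residual, residual_quantile))
    return pd.Series(flags, index=matrix.columns, name="outlier")
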