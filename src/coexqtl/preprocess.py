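"""Input filtering, rank-based normalization, and covariate construction.

The expression filters mirror the study's two retention rules: genes with
mean FPKM >= 1 enter module detection, genes with median FPKM > 0 (strict)
enter the eQTL scan. Expression is normalized per gene with the rank-based
inverse normal transform (R's ``qqnorm`` convention). Nuisance covariates
are K latent expression factors (principal components, the standard
surrogate for PEER-style hidden factors) plus the first genotype principal
components.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from coexqtl.containers import CovariateSet, GenotypeMatrix, warn


def filter_snps(
    geno: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.2
) -> GenotypeMatrix:
    """Keep SNPs with MAF > ``maf_min`` and missing fraction < ``miss_max``."""
    keep = (geno.maf() > maf_min) & (geno.missing_fraction() < miss_max)
    return geno.subset_snps(np.where(keep)[0])


def filter_genes_for_modules(
    expr: pd.DataFrame, min_mean_fpkm: float = 1.0
) -> pd.DataFrame:
    """Drop low-expressed genes (mean FPKM < threshold, strict) before
    module detection; gene order is preserved."""
    if expr.empty:
        raise ValueError("empty expression matrix")
    out = expr.loc[expr.mean(axis=1) >= min_mean_fpkm]
    if out.empty:
        warn("no genes pass the mean-FPKM filter")
    return out


def filter_genes_for_eqtl(
    expr: pd.DataFrame, min_median_fpkm: float = 0.0
) -> pd.DataFrame:
    """Keep expressed genes: per-gene median FPKM strictly above threshold."""
    if expr.empty:
        raise ValueError("empty expression matrix")
    out = expr.loc[expr.median(axis=1) > min_median_fpkm]
    if out.empty:
        warn("no genes pass the median-FPKM filter")
    return out


def rank_normalize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform of one sample vector.

    Uses the normal-quantile plotting positions of R's ``qqnorm``:
    Phi^-1((r_i - a) / (n + 1 - 2a)) with a = 3/8 for n <= 10 and a = 1/2
    otherwise; ties receive average ranks. A constant vector is degenerate
    and maps to all zeros (with a warning).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(x) == 0:
        warn("constant input to rank_normalize; returning zeros")
        return np.zeros(n)
    a = 0.375 if n <= 10 else 0.5
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - a) / (n + 1 - 2 * a))


def rank_normalize_matrix(expr: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Row-wise inverse normal transform; returns (matrix, degenerate ids)."""
    vals = expr.to_numpy(dtype=float)
    n = vals.shape[1]
    a = 0.375 if n <= 10 else 0.5
    constant = np.ptp(vals, axis=1) == 0
    ranks = stats.rankdata(vals, method="average", axis=1)
    out = stats.norm.ppf((ranks - a) / (n + 1 - 2 * a))
    out[constant] = 0.0
    degenerate = expr.index[constant].tolist()
    if degenerate:
        warn(f"{len(degenerate)} constant genes set to zero in rank_normalize")
    return pd.DataFrame(out, index=expr.index, columns=expr.columns), degenerate


def _top_pcs(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k left singular vectors (scores) of a column-centered matrix."""
    centered = mat - mat.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / max(1, mat.shape[0] - 1)
    frac = var / var.sum() if var.sum() > 0 else var
    scores = u[:, :k] * s[:k]
    scores = scores - scores.mean(axis=0, keepdims=True)
    return scores, frac[:k]


def latent_factors(expr_normalized: pd.DataFrame, k: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Top-K principal components of the samples x genes normalized matrix.

    Returns ``(factors, variance_fraction)`` with factors of shape
    (samples, K), columns mean-centered. These stand in for PEER-style
    hidden confounders: the scan only needs nuisance variance removed,
    which principal components provide.
    """
    n_samples = expr_normalized.shape[1]
    if k >= n_samples:
        raise ValueError(f"k={k} must be < number of samples ({n_samples})")
    if k == 0:
        return np.empty((n_samples, 0)), np.empty(0)
    mat = expr_normalized.to_numpy(dtype=float).T  # samples x genes
    return _top_pcs(mat, k)


def genotype_pcs(geno: GenotypeMatrix, n_pcs: int = 5) -> np.ndarray:
    """Principal components of the mean-imputed, centered dosage matrix."""
    if n_pcs >= geno.n_individuals:
        raise ValueError("n_pcs must be < number of individuals")
    if n_pcs == 0:
        return np.empty((geno.n_individuals, 0))
    scores, _ = _top_pcs(geno.dosage_imputed(), n_pcs)
    return scores


def drop_genetic_factors(
    factors: np.ndarray,
    geno: GenotypeMatrix,
    alpha: float = 0.05,
) -> tuple[np.ndarray, list]:
    """Remove latent factors that are themselves under strong genetic control.

    A factor with a Bonferroni-significant single-SNP association (alpha
    over factors x SNPs tests) likely captures a real trans-regulatory
    axis; regressing it out would erase the very signal the distant-eQTL
    scan is after, so such factors are excluded from the covariate set.
    Returns ``(kept_factors, dropped_indices)``.
    """
    k = factors.shape[1]
    if k == 0 or geno.n_snps == 0:
        return factors, []
    d = geno.dosage_imputed()
    d = d - d.mean(axis=0, keepdims=True)
    sd = d.std(axis=0)
    poly = sd > 0
    d = d[:, poly] / sd[poly]
    f = factors - factors.mean(axis=0, keepdims=True)
    fn = np.linalg.norm(f, axis=0)
    fn[fn == 0] = 1.0
    n = factors.shape[0]
    corr = (f / fn).T @ (d / np.sqrt(n))  # factors x snps correlations
    r2max = np.max(corr**2, axis=1)
    r2max = np.clip(r2max, 0, 1 - 1e-12)
    t = np.sqrt(r2max) * np.sqrt((n - 2) / (1 - r2max))
    p = 2 * stats.t.sf(t, df=n - 2)
    cutoff = alpha / (k * d.shape[1])
    dropped = np.where(p < cutoff)[0].tolist()
    kept = factors[:, [i for i in range(k) if i not in dropped]]
    return kept, dropped


def build_covariates(
    expr_normalized: pd.DataFrame,
    geno: GenotypeMatrix,
    k_factors: int = 20,
    n_geno_pcs: int = 5,
    screen_genetic: bool = True,
) -> CovariateSet:
    """Latent expression factors + genotype PCs, optionally screening out
    genetically controlled factors (see :func:`drop_genetic_factors`)."""
    factors, var_frac = latent_factors(expr_normalized, k_factors)
    dropped: list = []
    if screen_genetic and factors.size:
        factors, dropped = drop_genetic_factors(factors, geno)
    pcs = genotype_pcs(geno, n_geno_pcs)
    return CovariateSet(
        latent_factors=factors,
        genotype_pcs=pcs,
        factor_variance=var_frac,
        dropped_genetic_factors=dropped,
    )
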