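"""Weighted co-expression network modules and trait association.

Implements the WGCNA core: unsigned soft-thresholded adjacency
a_ij = |cor(x_i, x_j)|^beta, the topological overlap matrix (TOM),
average-linkage clustering of 1 - TOM with a static height cut, module
eigengenes, eigengene-similarity module merging, and the Student
asymptotic p-value for Pearson correlations used in module- and
gene-trait association.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from coexqtl.containers import ModulePartition, TraitAssociation, warn


def soft_adjacency(expr: pd.DataFrame | np.ndarray, beta: float = 5.0) -> np.ndarray:
    """Unsigned soft-thresholded adjacency |cor|^beta with unit diagonal.

    Rows are genes, columns samples (>= 3). Constant genes contribute zero
    correlation to every other gene.
    """
    x = np.asarray(expr, dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = x.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(x)
    cor[constant, :] = 0.0
    cor[:, constant] = 0.0
    cor = np.nan_to_num(cor)
    adj = np.abs(np.clip(cor, -1.0, 1.0)) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    connectivity k_i = sum_{u != i} a_iu; diagonal 1. The diagonal of the
    input is ignored (treated as zero), matching the convention that a
    node is not its own neighbour.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray,
    gene_ids: np.ndarray,
    min_module_size: int = 30,
    cut_height_frac: float = 0.99,
    soft_power: float = 5.0,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    The dendrogram is cut at ``cut_height_frac`` x (maximum merge height);
    clusters smaller than ``min_module_size`` become unassigned (label 0).
    Labels are ordered by size, largest first.
    """
    gene_ids = np.asarray(gene_ids)
    n = len(gene_ids)
    if tom.shape != (n, n):
        raise ValueError("TOM shape does not match gene_ids")
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    z = linkage(squareform(diss, checks=False), method="average")
    cut = cut_height_frac * z[:, 2].max()
    raw = fcluster(z, t=cut, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size].index
    if len(big) == 0:
        warn("no cluster reaches min_module_size; all genes unassigned")
    order = sizes.loc[big].sort_values(ascending=False).index
    relabel = {old: i + 1 for i, old in enumerate(order)}
    labels = np.array([relabel.get(c, 0) for c in raw])
    if labels.max() == 1 and (labels == 1).all():
        warn("all genes fell into a single module")
    return ModulePartition(
        gene_ids=gene_ids, labels=labels, soft_power=soft_power
    )


def module_eigengene(expr_block: pd.DataFrame | np.ndarray) -> np.ndarray:
    """First principal component of a standardized genes x samples block.

    The eigengene is scaled to unit variance and sign-oriented so that its
    correlation with the module's mean expression profile is positive.
    A (numerically) singular block falls back to the mean profile.
    """
    x = np.asarray(expr_block, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("module needs at least 2 genes")
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    mean_profile = z.mean(axis=0)
    try:
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        if s[0] <= 0:
            raise np.linalg.LinAlgError
        eig = vt[0]
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate fallback
        warn("singular module block; using mean profile as eigengene")
        eig = mean_profile.copy()
    if eig.std() == 0:
        warn("constant eigengene; returning zeros")
        return np.zeros_like(eig)
    eig = (eig - eig.mean()) / eig.std()
    if np.corrcoef(eig, mean_profile)[0, 1] < 0:
        eig = -eig
    return eig


def compute_eigengenes(
    expr: pd.DataFrame, partition: ModulePartition
) -> pd.DataFrame:
    """Eigengene (modules x samples) for every non-outlier module."""
    rows = {}
    for label in partition.modules():
        block = expr.loc[partition.genes_in(label)]
        rows[label] = module_eigengene(block)
    eig = pd.DataFrame(rows, index=expr.columns).T
    eig.index.name = "module"
    return eig


def merge_modules(
    expr: pd.DataFrame,
    partition: ModulePartition,
    threshold: float = 0.3,
) -> ModulePartition:
    """Iteratively merge modules with eigengene dissimilarity < threshold.

    Dissimilarity is 1 - cor(eigengene_a, eigengene_b). After each merge
    eigengenes are recomputed; merging repeats until no pair is closer
    than the threshold. Final labels are re-ordered by module size.
    """
    labels = partition.labels.copy()
    while True:
        part = ModulePartition(partition.gene_ids, labels, soft_power=partition.soft_power)
        mods = part.modules()
        if len(mods) < 2:
            break
        eig = compute_eigengenes(expr, part)
        cor = np.corrcoef(eig.to_numpy())
        diss = 1.0 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= threshold:
            break
        keep, absorb = sorted((mods[i], mods[j]))
        labels[labels == absorb] = keep

    # relabel by size descending
    sizes = pd.Series(labels[labels > 0]).value_counts()
    relabel = {old: rank + 1 for rank, old in enumerate(sizes.index)}
    labels = np.array([relabel.get(l, 0) for l in labels])
    out = ModulePartition(
        gene_ids=partition.gene_ids,
        labels=labels,
        soft_power=partition.soft_power,
        merge_threshold=threshold,
    )
    out.eigengenes = compute_eigengenes(expr, out)
    return out


def cor_pvalue_student(x: np.ndarray, y: np.ndarray) -> TraitAssociation:
    """Pearson r with the Student asymptotic two-sided p-value.

    t = r sqrt(n-2) / sqrt(1 - r^2) against a t distribution with n-2
    degrees of freedom (the WGCNA ``corPvalueStudent`` convention).
    Constant input yields a degenerate association with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        warn("constant input to cor_pvalue_student")
        return TraitAssociation(r=0.0, p=1.0, n=n, degenerate=True)
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        warn("perfectly collinear input; p reported as smallest representable")
        return TraitAssociation(r=r, p=np.nextafter(0, 1), n=n, degenerate=True)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return TraitAssociation(r=r, p=max(p, np.nextafter(0, 1)), n=n)


def module_trait_table(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """All module x trait correlations with Student p-values."""
    rows = []
    for label, eig in eigengenes.iterrows():
        for trait in traits.columns:
            assoc = cor_pvalue_student(eig.to_numpy(), traits[trait].to_numpy())
            rows.append(
                {"module": label, "trait": trait, "r": assoc.r, "p": assoc.p, "n": assoc.n}
            )
    return pd.DataFrame(rows)


def select_trait_modules(
    eigengenes: pd.DataFrame,
    trait: np.ndarray | pd.Series,
    p_max: float = 0.01,
) -> list[int]:
    """Module labels whose eigengene-trait association has p <= p_max."""
    trait = np.asarray(trait, dtype=float)
    selected = []
    for label, eig in eigengenes.iterrows():
        if cor_pvalue_student(eig.to_numpy(), trait).p <= p_max:
            selected.append(label)
    return selected


def gene_trait_significance(
    expr: pd.DataFrame,
    trait: np.ndarray | pd.Series,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Per-gene trait correlation; keeps genes with p < p_max (strict)."""
    trait = np.asarray(trait, dtype=float)
    rows = []
    for gene, values in expr.iterrows():
        assoc = cor_pvalue_student(values.to_numpy(), trait)
        if assoc.p < p_max:
            rows.append({"gene_id": gene, "r": assoc.r, "p": assoc.p})
    return pd.DataFrame(rows, columns=["gene_id", "r", "p"])
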