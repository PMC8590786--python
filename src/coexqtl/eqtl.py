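"""All-pairs SNP x gene association scan and eQTL post-processing.

The scan fits, per pair, the linear model
expression ~ intercept + covariates + dosage and tests the dosage slope
(t, df = n - 2 - #covariates). Expression and dosage are residualized on
the covariates once (Frisch-Waugh), so each pair reduces to a simple
regression of residuals; results are algebraically identical to the full
per-pair OLS and evaluated in SNP blocks so the full n_snps x n_genes
result never materializes.

Significant pairs are collapsed to leading SNPs (greedy best-p clumping
within a 20-kb window), classified local/distant against the gene interval
+- 20 kb, and distant eQTLs are screened for 1-Mb hotspot windows whose
counts exceed a permutation null (uniform reassignment of all distant
eQTLs across windows, bin-level exceedance at P <= 0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from coexqtl.containers import CovariateSet, GenotypeMatrix, warn


def bonferroni_threshold(n_snps: int, n_genes: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (n_snps x n_genes)."""
    if n_snps <= 0 or n_genes <= 0:
        raise ValueError("counts must be > 0")
    return alpha / (float(n_snps) * float(n_genes))


def _residualize(mat: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``mat`` on [intercept, covariates]."""
    n = mat.shape[0]
    design = np.column_stack([np.ones(n), covariates]) if covariates.size else np.ones((n, 1))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols = [design[:, :1]]
        for j in range(1, design.shape[1]):
            trial = np.column_stack(cols + [design[:, j : j + 1]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                cols.append(design[:, j : j + 1])
            else:
                bad.append(j - 1)  # covariate index (0-based, excl. intercept)
        raise ValueError(f"rank-deficient covariates; offending columns {bad}")
    q, _ = np.linalg.qr(design)
    return mat - q @ (q.T @ mat)


@dataclass
class ScanSummary:
    n_pairs_tested: int
    n_monomorphic_skipped: int
    n_degenerate_genes: int
    df: int


def scan(
    geno: GenotypeMatrix,
    expr_norm: pd.DataFrame,
    covariates: CovariateSet | np.ndarray | None,
    p_keep: float = 1.0,
    block_size: int = 2000,
) -> tuple[pd.DataFrame, ScanSummary]:
    """Linear-model association scan over all SNP x gene pairs.

    ``expr_norm`` is genes x samples (already rank-normalized); dosages are
    mean-imputed. Only pairs with p <= ``p_keep`` are returned. Monomorphic
    SNPs and zero-residual-variance genes are skipped and counted.
    """
    samples = expr_norm.columns.to_numpy()
    if not np.array_equal(samples, geno.sample_ids):
        raise ValueError("sample ids of expression and genotypes must align")
    if covariates is None:
        cov = np.empty((len(samples), 0))
    elif isinstance(covariates, CovariateSet):
        cov = covariates.matrix()
    else:
        cov = np.asarray(covariates, dtype=float)
    n = len(samples)
    n_cov = cov.shape[1]
    df = n - 2 - n_cov
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")

    y = _residualize(expr_norm.to_numpy(dtype=float).T, cov)  # samples x genes
    y_norm = np.linalg.norm(y, axis=0)
    degenerate_genes = y_norm <= 1e-12
    if degenerate_genes.any():
        warn(f"{int(degenerate_genes.sum())} genes have zero residual variance; skipped")
    y_unit = np.where(y_norm > 1e-12, y_norm, 1.0)
    yu = y / y_unit

    dosage = geno.dosage_imputed()
    mono = dosage.std(axis=0) == 0
    gene_ids = expr_norm.index.to_numpy()

    frames = []
    tested = 0
    for lo in range(0, geno.n_snps, block_size):
        hi = min(lo + block_size, geno.n_snps)
        block_keep = ~mono[lo:hi]
        if not block_keep.any():
            continue
        idx = np.arange(lo, hi)[block_keep]
        x = _residualize(dosage[:, idx], cov)
        x_norm = np.linalg.norm(x, axis=0)
        ok = x_norm > 1e-12
        idx, x, x_norm = idx[ok], x[:, ok], x_norm[ok]
        if idx.size == 0:
            continue
        xu = x / x_norm
        r = xu.T @ yu  # snps x genes correlation of residuals
        r[:, degenerate_genes] = 0.0
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=df)
        p[:, degenerate_genes] = 1.0
        tested += idx.size * (len(gene_ids) - int(degenerate_genes.sum()))
        si, gi = np.where(p <= p_keep)
        if si.size:
            beta = r[si, gi] * (y_norm[gi] / x_norm[si])
            frames.append(
                pd.DataFrame(
                    {
                        "snp_id": geno.snp_ids[idx][si],
                        "snp_chrom": geno.snp_chrom[idx][si],
                        "snp_pos": geno.snp_pos[idx][si],
                        "gene_id": gene_ids[gi],
                        "beta": beta,
                        "t_stat": t[si, gi],
                        "p": p[si, gi],
                    }
                )
            )
    cols = ["snp_id", "snp_chrom", "snp_pos", "gene_id", "beta", "t_stat", "p"]
    out = (
        pd.concat(frames, ignore_index=True)[cols]
        if frames
        else pd.DataFrame(columns=cols)
    )
    summary = ScanSummary(
        n_pairs_tested=tested,
        n_monomorphic_skipped=int(mono.sum()),
        n_degenerate_genes=int(degenerate_genes.sum()),
        df=df,
    )
    return out, summary


def collapse_leading_snps(assocs: pd.DataFrame, window: int = 20_000) -> pd.DataFrame:
    """Greedy best-p clumping of one gene's significant SNPs.

    Per chromosome, repeatedly take the remaining SNP with the smallest p
    (ties broken by the smaller coordinate), emit it as the leading SNP,
    and discard every remaining SNP within +-``window`` bp of it.
    """
    if assocs.empty:
        return assocs.copy()
    if assocs["gene_id"].nunique() > 1:
        raise ValueError("collapse_leading_snps expects associations of one gene")
    leaders = []
    for _, chrom_df in assocs.groupby("snp_chrom", sort=False):
        remaining = chrom_df.sort_values(["p", "snp_pos"], kind="mergesort")
        while not remaining.empty:
            lead = remaining.iloc[0]
            leaders.append(lead)
            remaining = remaining[
                (remaining["snp_pos"] - lead["snp_pos"]).abs() > window
            ]
    return pd.DataFrame(leaders).reset_index(drop=True)


def collapse_all_genes(assocs: pd.DataFrame, window: int = 20_000) -> pd.DataFrame:
    """Leading-SNP collapse applied per gene across a full scan result."""
    if assocs.empty:
        return assocs.copy()
    parts = [
        collapse_leading_snps(g, window=window)
        for _, g in assocs.groupby("gene_id", sort=False)
    ]
    return pd.concat(parts, ignore_index=True)


def classify_local_distant(
    records: pd.DataFrame, gene_models: pd.DataFrame, local_window: int = 20_000
) -> pd.DataFrame:
    """Add class (local/distant) and signed distance to the gene interval.

    A record is local when its SNP lies within [start - window, end +
    window] of its associated gene (boundaries inclusive, strand-agnostic),
    distant otherwise. ``distance_bp`` is 0 inside the gene, negative
    upstream of start, positive downstream of end; cross-chromosome
    records get NA distance.
    """
    gm = gene_models.set_index("gene_id")
    missing = set(records["gene_id"]) - set(gm.index)
    if missing:
        raise KeyError(f"unknown gene ids: {sorted(missing)[:5]}")
    out = records.copy()
    gchrom = gm.loc[out["gene_id"], "chrom"].to_numpy()
    gstart = gm.loc[out["gene_id"], "start"].to_numpy()
    gend = gm.loc[out["gene_id"], "end"].to_numpy()
    pos = out["snp_pos"].to_numpy()
    same = out["snp_chrom"].to_numpy() == gchrom
    dist = np.where(pos < gstart, pos - gstart, np.where(pos > gend, pos - gend, 0))
    local = same & (np.abs(dist) <= local_window)
    out["class"] = np.where(local, "local", "distant")
    out["distance_bp"] = pd.array(
        np.where(same, dist, 0), dtype="Int64"
    )
    out.loc[~same, "distance_bp"] = pd.NA
    return out


def derive_local_window(gene_models: pd.DataFrame, coverage: float = 0.90) -> int:
    """Suggest a local window: the coverage-quantile of adjacent intergenic
    gaps, rounded up to the nearest kb. Falls back to 20 kb if there are no
    adjacent pairs."""
    gaps = []
    for _, chrom_df in gene_models.groupby("chrom"):
        s = chrom_df.sort_values("start")
        g = (s["start"].to_numpy()[1:] - s["end"].to_numpy()[:-1] - 1).clip(min=0)
        gaps.append(g)
    gaps = np.concatenate(gaps) if gaps else np.empty(0)
    if gaps.size == 0:
        warn("no adjacent gene pairs; returning default 20 kb window")
        return 20_000
    q = float(np.quantile(gaps, coverage))
    return int(math.ceil(q / 1000.0) * 1000)


@dataclass
class HotspotSet:
    """1-Mb window counts of distant eQTLs with the permutation cutoff."""

    windows: pd.DataFrame  # chrom, start, end, count, hotspot
    cutoff: int
    n_records: int
    n_perm: int
    alpha: float

    @property
    def hotspots(self) -> pd.DataFrame:
        return self.windows[self.windows["hotspot"]]


def _make_windows(chrom_lengths: dict, window: int) -> pd.DataFrame:
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(1, int(length) + 1, window):
            rows.append(
                {"chrom": chrom, "start": start, "end": min(start + window - 1, int(length))}
            )
    return pd.DataFrame(rows)


def hotspot_detection(
    distant_records: pd.DataFrame,
    chrom_lengths: dict,
    window: int = 1_000_000,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> HotspotSet:
    """Permutation test for distant-eQTL hotspot windows.

    Observed counts are the number of distant eQTLs per non-overlapping
    1-Mb bin. The null pools bin counts from ``n_perm`` uniform random
    reassignments of all records across bins; the cutoff is the smallest
    count c whose pooled null exceedance fraction is <= ``alpha``, and
    hotspots are observed bins with count >= c.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bins = _make_windows(chrom_lengths, window)
    nb = len(bins)
    if distant_records.empty:
        bins["count"] = 0
        bins["hotspot"] = False
        return HotspotSet(bins, cutoff=0, n_records=0, n_perm=n_perm, alpha=alpha)

    key = bins["chrom"].astype(str) + ":" + ((bins["start"] - 1) // window).astype(str)
    index = {k: i for i, k in enumerate(key)}
    rec_bin = (
        distant_records["snp_chrom"].astype(str)
        + ":"
        + ((distant_records["snp_pos"].to_numpy() - 1) // window).astype(str)
    )
    unknown = set(rec_bin) - set(index)
    if unknown:
        raise ValueError(f"records outside chrom_lengths: {sorted(unknown)[:3]}")
    counts = np.bincount([index[k] for k in rec_bin], minlength=nb)

    n_rec = len(distant_records)
    null = rng.multinomial(n_rec, np.full(nb, 1.0 / nb), size=n_perm)
    null_counts = null.ravel()
    # pooled bin-level exceedance: smallest c with tail fraction <= alpha
    max_c = int(null_counts.max()) + 1
    tail = np.zeros(max_c + 2)
    hist = np.bincount(null_counts, minlength=max_c + 2)
    tail = hist[::-1].cumsum()[::-1] / null_counts.size
    cutoff = int(np.argmax(tail <= alpha))
    if tail[cutoff] > alpha:  # never reached: beyond null max
        cutoff = max_c + 1

    bins = bins.copy()
    bins["count"] = counts
    bins["hotspot"] = counts >= cutoff
    return HotspotSet(bins, cutoff=cutoff, n_records=n_rec, n_perm=n_perm, alpha=alpha)
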