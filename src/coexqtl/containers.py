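"""Shared in-memory containers for the pipeline stages.

Expression matrices, gene models, trait tables and association tables are
plain :class:`pandas.DataFrame` objects (genes x samples with gene ids as
index for expression; one row per gene for gene models). The classes here
hold the objects that need more structure than a frame: genotypes with a
missing-data sentinel, covariate blocks, module partitions, and the
recorded ground truth of a simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: In-memory sentinel for a missing genotype call (``./.`` in VCF).
MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive dosage matrix with SNP coordinates.

    ``dosage`` is an int8 array with values in {0, 1, 2} and :data:`MISSING`
    (-1) for no-calls. Positions are 1-based bp and sorted within each
    chromosome.
    """

    dosage: np.ndarray
    snp_ids: np.ndarray
    snp_chrom: np.ndarray
    snp_pos: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.snp_ids = np.asarray(self.snp_ids)
        self.snp_chrom = np.asarray(self.snp_chrom)
        self.snp_pos = np.asarray(self.snp_pos, dtype=np.int64)
        self.sample_ids = np.asarray(self.sample_ids)
        n, m = self.dosage.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError("dosage shape does not match id vectors")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        freq = d.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def dosage_imputed(self) -> np.ndarray:
        """Float dosage matrix with per-SNP mean imputation of no-calls."""
        d = self.dosage.astype(np.float64)
        miss = self.missing_mask
        if miss.any():
            d[miss] = np.nan
            col_mean = np.nanmean(d, axis=0)
            # monomorphic all-missing column: fall back to 0
            col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
            idx = np.where(miss)
            d[idx] = col_mean[idx[1]]
        return d

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage[:, keep],
            snp_ids=self.snp_ids[keep],
            snp_chrom=self.snp_chrom[keep],
            snp_pos=self.snp_pos[keep],
            sample_ids=self.sample_ids,
        )


@dataclass
class CovariateSet:
    """Nuisance covariates for the association scan.

    ``latent_factors``: samples x K principal components of the normalized
    expression matrix (surrogate for PEER-style hidden factors).
    ``genotype_pcs``: samples x P principal components of the dosage matrix.
    Columns of both blocks are mean-centered.
    """

    latent_factors: np.ndarray
    genotype_pcs: np.ndarray
    factor_variance: np.ndarray | None = None
    dropped_genetic_factors: list[int] = field(default_factory=list)

    def matrix(self) -> np.ndarray:
        blocks = [b for b in (self.latent_factors, self.genotype_pcs) if b.size]
        if not blocks:
            n = max(self.latent_factors.shape[0], self.genotype_pcs.shape[0])
            return np.empty((n, 0))
        return np.column_stack(blocks)

    @property
    def n_covariates(self) -> int:
        return self.latent_factors.shape[1] + self.genotype_pcs.shape[1]


@dataclass
class ModulePartition:
    """Gene -> module assignment with module eigengenes.

    Label 0 marks unassigned/outlier genes. ``eigengenes`` is a modules x
    samples frame (index = module labels) with unit-variance rows.
    """

    gene_ids: np.ndarray
    labels: np.ndarray
    eigengenes: pd.DataFrame | None = None
    soft_power: float = 5.0
    merge_threshold: float = 0.3

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.gene_ids) != len(self.labels):
            raise ValueError("gene_ids and labels must align")

    @property
    def module_of_gene(self) -> dict:
        return dict(zip(self.gene_ids.tolist(), self.labels.tolist()))

    def modules(self) -> list[int]:
        """Sorted non-outlier module labels."""
        return sorted(set(self.labels.tolist()) - {0})

    def genes_in(self, label: int) -> np.ndarray:
        return self.gene_ids[self.labels == label]


@dataclass
class TraitAssociation:
    """Pearson correlation with its Student asymptotic p-value."""

    r: float
    p: float
    n: int
    degenerate: bool = False


@dataclass
class SimTruth:
    """Recorded ground truth of a simulated dataset.

    ``cis_eqtl_pairs`` holds ``(snp_id, gene_id, effect_sd)`` triples; the
    regulator gene appears there too, since its local SNP drives its own
    expression. ``regulated_genes`` all share the regulator's module.
    """

    module_of_gene: dict
    cis_eqtl_pairs: list
    regulator_gene: str
    regulator_snp: str
    regulated_genes: list
    trait_loadings: dict
    structural_genes: list = field(default_factory=list)
    tf_genes: list = field(default_factory=list)
    module_factors: pd.DataFrame | None = None
    motif_offsets: dict = field(default_factory=dict)


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
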