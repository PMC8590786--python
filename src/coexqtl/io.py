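"""Readers and writers for the pipeline's on-disk formats.

Standard formats go through established libraries where one exists: VCF is
parsed with :mod:`cyvcf2`, FASTA with Biopython, tab tables with pandas.
VCF writing emits plain VCF 4.2 text (biallelic SNPs, GT only) directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from coexqtl.containers import MISSING, GenotypeMatrix, SimTruth

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal VCF 4.2 with GT calls for biallelic SNPs."""
    path = Path(path)
    chroms = pd.unique(geno.snp_chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.sample_ids))
            + "\n"
        )
        for j in range(geno.n_snps):
            calls = "\t".join(_GT[int(d)] for d in geno.dosage[:, j])
            fh.write(
                f"{geno.snp_chrom[j]}\t{geno.snp_pos[j]}\t{geno.snp_ids[j]}"
                f"\tA\tG\t.\tPASS\t.\tGT\t{calls}\n"
            )
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Parse a biallelic-SNP VCF into additive dosages."""
    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    ids, chroms, poss, cols = [], [], [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        ids.append(v.ID or f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        cols.append(remap[v.gt_types])
    vcf.close()
    dosage = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        dosage=dosage,
        snp_ids=np.array(ids),
        snp_chrom=np.array(chroms),
        snp_pos=np.array(poss, dtype=np.int64),
        sample_ids=samples,
    )


def write_expression(expr: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
    return path


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gene_models(annotation: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    annotation[["chrom", "start", "end", "strand", "gene_id"]].to_csv(
        path, sep="\t", index=False
    )
    return path


def read_gene_models(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[["gene_id", "chrom", "start", "end", "strand"]]


def write_traits(traits: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    traits.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6g")
    return path


def read_traits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_fasta(sequences: dict, path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=str(name), description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_fasta(path: str | Path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_truth(truth: SimTruth, path: str | Path) -> Path:
    """Flat key-value text file; list/dict values are JSON-encoded."""
    path = Path(path)
    payload = {
        "module_of_gene": truth.module_of_gene,
        "cis_eqtl_pairs": truth.cis_eqtl_pairs,
        "regulator_gene": truth.regulator_gene,
        "regulator_snp": truth.regulator_snp,
        "regulated_genes": truth.regulated_genes,
        "trait_loadings": truth.trait_loadings,
        "structural_genes": truth.structural_genes,
        "tf_genes": truth.tf_genes,
        "motif_offsets": truth.motif_offsets,
    }
    with open(path, "w") as fh:
        for key, value in payload.items():
            fh.write(f"{key}\t{json.dumps(value)}\n")
    return path


def read_truth(path: str | Path) -> SimTruth:
    raw = {}
    with open(path) as fh:
        for line in fh:
            key, value = line.rstrip("\n").split("\t", 1)
            raw[key] = json.loads(value)
    raw["cis_eqtl_pairs"] = [tuple(p) for p in raw["cis_eqtl_pairs"]]
    raw["trait_loadings"] = {int(k): v for k, v in raw["trait_loadings"].items()}
    return SimTruth(module_factors=None, **raw)
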