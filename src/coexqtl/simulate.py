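"""Synthetic diversity-panel generator with planted, recorded ground truth.

The generator emulates the data a systems-genetics scan consumes: a
structured genotype panel (two subpopulations, Balding-Nichols allele
frequency divergence), dense gene models, a factor-model expression matrix
with planted co-expression modules, cis effects, one trans master regulator
whose local SNP drives a whole module, a module-driven quantitative trait,
and protein sequences in which only the regulator carries the conserved
LP-/WQ-box activation motifs. Everything planted is returned in a
:class:`~coexqtl.containers.SimTruth` so recovery can be scored exactly.

Expression is generated on a Gaussian latent scale and mapped through an
exponential to non-negative FPKM-like values; the downstream analysis
rank-normalizes, so only the ordering matters.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from coexqtl.config import SimConfig
from coexqtl.containers import MISSING, GenotypeMatrix, SimTruth

# stage offsets so each simulate_* call has its own reproducible stream
(
    _GENO_STREAM,
    _ANNOT_STREAM,
    _EXPR_STREAM,
    _TRAIT_STREAM,
    _PROT_STREAM,
    _DEV_STREAM,
    _BASE_STREAM,
) = range(7)

LP_BOX = "F[ML]QLPQLESP[KS]"
WQ_BOX = "DQ[VL]TDWRALD[KR][LF][VL]AS[QH]L[SN]Q[DE]D"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def subpopulation_labels(cfg: SimConfig) -> np.ndarray:
    """Deterministic assignment of individuals to subpopulations."""
    return np.arange(cfg.n_individuals) % cfg.n_subpops


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a structured biallelic SNP panel.

    Ancestral minor-allele frequencies are uniform over ``maf_range``;
    subpopulation frequencies diverge Balding-Nichols style with
    between-population variance set by ``fst_divergence``. Dosages are
    Binomial(2, p); no-calls are planted at ``missing_rate``. SNPs whose
    realized (post-sampling) MAF escapes ``maf_range`` are redrawn, so the
    emitted panel honours the filter the analysis assumes. Coordinates are
    uniform over chromosomes and sorted within each.
    """
    cfg.validate()
    rng = _rng(cfg, _GENO_STREAM)
    n, m = cfg.n_individuals, cfg.n_snps
    lo, hi = cfg.maf_range
    pop = subpopulation_labels(cfg)
    fst = cfg.fst_divergence

    dosage = np.full((n, m), MISSING, dtype=np.int8)
    pending = np.arange(m)
    for _ in range(200):
        if pending.size == 0:
            break
        k = pending.size
        p_anc = rng.uniform(lo, hi, size=k)
        if fst > 0:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            p_sub = rng.beta(a[None, :], b[None, :], size=(cfg.n_subpops, k))
        else:
            p_sub = np.broadcast_to(p_anc, (cfg.n_subpops, k)).copy()
        p_sub = np.clip(p_sub, 1e-6, 1 - 1e-6)
        d = rng.binomial(2, p_sub[pop, :]).astype(np.int8)
        if cfg.missing_rate > 0:
            d[rng.random((n, k)) < cfg.missing_rate] = MISSING
        masked = np.ma.masked_equal(d, MISSING)
        freq = masked.mean(axis=0).filled(np.nan) / 2.0
        maf = np.minimum(freq, 1 - freq)
        ok = np.isfinite(maf) & (maf >= lo) & (maf <= hi)
        dosage[:, pending[ok]] = d[:, ok]
        pending = pending[~ok]
    if pending.size:
        raise RuntimeError(
            f"could not realize MAF within {cfg.maf_range} for "
            f"{pending.size} SNPs after 200 rounds"
        )

    chrom = rng.integers(1, cfg.n_chromosomes + 1, size=m)
    pos = rng.integers(1, cfg.chrom_length_bp + 1, size=m)
    order = np.lexsort((pos, chrom))
    snp_ids = np.array(
        [f"snp_{chrom[i]}_{pos[i]}_{i}" for i in order]
    )
    return GenotypeMatrix(
        dosage=dosage[:, order],
        snp_ids=snp_ids,
        snp_chrom=np.array([f"chr{c}" for c in chrom[order]]),
        snp_pos=pos[order],
        sample_ids=np.array([f"ind{i:03d}" for i in range(n)]),
    )


def simulate_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Place non-overlapping gene models so ~90% of adjacent gaps are < 20 kb.

    Gaps are a mixture of short (exponential, mean 5 kb, capped just under
    20 kb; 90% of pairs) and long (uniform 25-80 kb) spacers, matching the
    empirical intergenic-distance profile the 20-kb local window is based
    on. Coordinates are 1-based inclusive.
    """
    cfg.validate()
    rng = _rng(cfg, _ANNOT_STREAM)
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1

    rows = []
    gid = 0
    for c in range(1, cfg.n_chromosomes + 1):
        ng = per_chrom[c - 1]
        lengths = rng.integers(1000, 5001, size=ng)
        short = np.minimum(rng.exponential(5000.0, size=ng), 19_000).astype(np.int64)
        long_ = rng.integers(25_000, 80_001, size=ng)
        gaps = np.where(rng.random(ng) < 0.9, short, long_)
        gaps = np.maximum(gaps, 100)
        start = 10_000
        for i in range(ng):
            end = start + int(lengths[i]) - 1
            if end > cfg.chrom_length_bp:
                raise ValueError(
                    "gene models exceed chrom_length_bp; increase chromosome "
                    "length or reduce n_genes"
                )
            rows.append(
                {
                    "gene_id": f"gene_{gid:05d}",
                    "chrom": f"chr{c}",
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
            gid += 1
            start = end + 1 + int(gaps[i])
    return pd.DataFrame(rows)


def _gene_baselines(cfg: SimConfig) -> np.ndarray:
    """Per-gene log-abundance baselines, shared by every expression panel of
    one dataset so between-panel gene means are consistent."""
    return _rng(cfg, _BASE_STREAM).normal(1.5, 1.0, size=cfg.n_genes)


def _standardized_dosage(geno: GenotypeMatrix, snp_idx: int) -> np.ndarray:
    d = geno.dosage_imputed()[:, snp_idx]
    sd = d.std()
    return (d - d.mean()) / (sd if sd > 0 else 1.0)


def _snps_near(
    geno: GenotypeMatrix, chrom: str, start: int, end: int, window: int
) -> np.ndarray:
    sel = (
        (geno.snp_chrom == chrom)
        & (geno.snp_pos >= start - window)
        & (geno.snp_pos <= end + window)
    )
    return np.where(sel)[0]


def simulate_expression(
    geno: GenotypeMatrix, annotation: pd.DataFrame, cfg: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Factor-model expression with planted cis, trans and module structure.

    Gene *g* in module *m*: latent value = loading_g x factor_m
    (+ cis dosage effect if planted) (+ trans effect of the regulator SNP's
    dosage if regulated) + Gaussian noise. The regulator itself is a member
    of the trait module whose expression is additionally driven by a SNP in
    its own gene body, so that locus is simultaneously a local eQTL for the
    regulator and the distant eQTL source for its targets. Latent values
    are mapped to FPKM-like non-negative values by exponentiation.
    """
    cfg.validate()
    if sum(cfg.module_sizes) > cfg.n_genes:
        raise ValueError("module_sizes must sum to <= n_genes")
    rng = _rng(cfg, _EXPR_STREAM)
    n = cfg.n_individuals
    genes = annotation["gene_id"].to_numpy()
    if len(genes) != cfg.n_genes:
        raise ValueError("annotation was built from a different config")

    # module membership: contiguous gene blocks would correlate position with
    # module, so membership is a random draw
    perm = rng.permutation(cfg.n_genes)
    labels = np.zeros(cfg.n_genes, dtype=int)
    off = 0
    for mi, size in enumerate(cfg.module_sizes, start=1):
        labels[perm[off : off + size]] = mi
        off += size

    factors = rng.standard_normal((n, cfg.n_modules))
    loadings = rng.uniform(*cfg.module_loading_range, size=cfg.n_genes)

    latent = cfg.noise_sd * rng.standard_normal((cfg.n_genes, n))
    for mi in range(1, cfg.n_modules + 1):
        idx = np.where(labels == mi)[0]
        latent[idx] += loadings[idx, None] * factors[:, mi - 1][None, :]

    # regulator: a trait-module gene with a SNP inside (or within 20 kb of)
    # its body; its local SNP drives it and, in trans, the whole module
    module1 = np.where(labels == 1)[0]
    regulator_idx = regulator_snp_idx = None
    order = rng.permutation(module1)
    for gi in order:
        row = annotation.iloc[gi]
        inside = _snps_near(geno, row["chrom"], row["start"], row["end"], 0)
        nearby = inside if inside.size else _snps_near(
            geno, row["chrom"], row["start"], row["end"], 20_000
        )
        if nearby.size:
            regulator_idx = int(gi)
            regulator_snp_idx = int(rng.choice(nearby))
            break
    if regulator_idx is None:
        raise RuntimeError("no trait-module gene has a SNP within 20 kb")

    reg_dos = _standardized_dosage(geno, regulator_snp_idx)
    regulated = np.array([g for g in module1 if g != regulator_idx])
    latent[regulated] += cfg.trans_effect_sd * reg_dos[None, :]
    latent[regulator_idx] += cfg.cis_effect_sd * reg_dos

    cis_pairs = [
        (str(geno.snp_ids[regulator_snp_idx]), str(genes[regulator_idx]), cfg.cis_effect_sd)
    ]

    # additional cis genes, each with a SNP within 20 kb of the gene; the
    # regulated (trans-driven) genes are excluded so every planted cis
    # signal is unconfounded by the trans effect
    regulated_set = set(regulated.tolist())
    eligible = [
        g
        for g in range(cfg.n_genes)
        if g != regulator_idx and g not in regulated_set
    ]
    rng.shuffle(eligible)
    for gi in eligible:
        if len(cis_pairs) >= cfg.n_cis_genes + 1:
            break
        row = annotation.iloc[gi]
        nearby = _snps_near(geno, row["chrom"], row["start"], row["end"], 20_000)
        nearby = nearby[nearby != regulator_snp_idx]
        if not nearby.size:
            continue
        si = int(rng.choice(nearby))
        latent[gi] += cfg.cis_effect_sd * _standardized_dosage(geno, si)
        cis_pairs.append((str(geno.snp_ids[si]), str(genes[gi]), cfg.cis_effect_sd))

    # FPKM-like scale; per-gene baseline varies so the low-expression filter
    # has something to remove
    baseline = _gene_baselines(cfg)
    fpkm = np.exp(0.4 * latent + baseline[:, None])

    # a small fraction of background genes are silent in most samples
    background = np.where(labels == 0)[0]
    planted_cis = {p[1] for p in cis_pairs}
    background = np.array(
        [g for g in background if genes[g] not in planted_cis], dtype=int
    )
    n_drop = int(round(cfg.dropout_gene_frac * cfg.n_genes))
    if n_drop and background.size:
        drop_genes = rng.choice(background, size=min(n_drop, background.size), replace=False)
        for gi in drop_genes:
            silent = rng.random(n) < 0.7
            fpkm[gi, silent] = 0.0

    expr = pd.DataFrame(fpkm, index=genes, columns=geno.sample_ids)

    # role lists for the targeted network: "structural" genes are regulated
    # trait-module members; "TFs" are the regulator plus background genes
    struct_pool = [str(genes[g]) for g in regulated]
    n_struct = min(cfg.n_structural_genes, len(struct_pool))
    structural = sorted(rng.choice(struct_pool, size=n_struct, replace=False).tolist())
    tf_pool = [
        str(genes[g])
        for g in range(cfg.n_genes)
        if labels[g] == 0 and str(genes[g]) not in planted_cis
    ]
    n_tf = min(cfg.n_tf_genes - 1, len(tf_pool))
    tfs = [str(genes[regulator_idx])] + sorted(
        rng.choice(tf_pool, size=n_tf, replace=False).tolist()
    )

    truth = SimTruth(
        module_of_gene=dict(zip(genes.tolist(), labels.tolist())),
        cis_eqtl_pairs=cis_pairs,
        regulator_gene=str(genes[regulator_idx]),
        regulator_snp=str(geno.snp_ids[regulator_snp_idx]),
        regulated_genes=[str(genes[g]) for g in regulated],
        trait_loadings={1: 1.0, **{m: 0.0 for m in range(2, cfg.n_modules + 1)}},
        structural_genes=structural,
        tf_genes=tfs,
        module_factors=pd.DataFrame(
            factors,
            index=geno.sample_ids,
            columns=[f"M{m}" for m in range(1, cfg.n_modules + 1)],
        ),
    )
    return expr, truth


def _rescale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = x.max() - x.min()
    if span == 0:
        return np.full_like(x, (lo + hi) / 2.0)
    return lo + (x - x.min()) * (hi - lo) / span


def simulate_trait(
    expression: pd.DataFrame, truth: SimTruth, cfg: SimConfig
) -> pd.DataFrame:
    """Three positively correlated traits driven by the trait module's factor.

    Stone-cell content is rescaled to span [3.2, 22.6] g/100 g (the observed
    panel range, ~7-fold); lignin and cellulose are affine maps of the same
    latent factor with independent noise, so all pairwise trait correlations
    are positive (and exactly 1 when ``trait_noise_sd`` is 0).
    """
    rng = _rng(cfg, _TRAIT_STREAM)
    f = truth.module_factors["M1"].to_numpy()
    n = len(f)
    ranges = {"stone_cell": (3.2, 22.6), "lignin": (8.0, 28.0), "cellulose": (10.0, 35.0)}
    cols = {}
    for name, (lo, hi) in ranges.items():
        noisy = f + cfg.trait_noise_sd * rng.standard_normal(n)
        cols[name] = _rescale(noisy, lo, hi)
    return pd.DataFrame(cols, index=truth.module_factors.index)


def simulate_development_panel(
    annotation: pd.DataFrame, truth: SimTruth, cfg: SimConfig
) -> pd.DataFrame:
    """Small developmental expression panel (stages x cultivars).

    Trait-module genes (and the regulator) follow a shared developmental
    trajectory with amplitude ``dev_amplitude`` and small noise, emulating
    the strong developmental co-regulation of secondary-cell-wall genes
    that motivates merging a developmental series into the network panel.
    Other genes get low-amplitude gene-specific trajectories.
    """
    rng = _rng(cfg, _DEV_STREAM)
    n_samp = cfg.dev_n_stages * cfg.dev_n_cultivars
    genes = annotation["gene_id"].to_numpy()
    labels = np.array([truth.module_of_gene[g] for g in genes])
    loadings = np.ones(len(genes))

    t = np.tile(np.linspace(-1.0, 1.0, cfg.dev_n_stages), cfg.dev_n_cultivars)
    t = t / t.std()  # unit-SD trajectory so amplitudes are in factor-SD units
    latent = cfg.dev_noise_sd * rng.standard_normal((len(genes), n_samp))

    module_traj = {
        m: (cfg.dev_amplitude if m == 1 else 1.0)
        * np.sign(rng.standard_normal())
        * t
        for m in range(1, cfg.n_modules + 1)
    }
    # trait module rises with development (secondary wall deposition)
    module_traj[1] = cfg.dev_amplitude * t
    for m, traj in module_traj.items():
        idx = np.where(labels == m)[0]
        latent[idx] += loadings[idx, None] * traj[None, :]
    bg = np.where(labels == 0)[0]
    phase = rng.uniform(0, 2 * np.pi, size=bg.size)
    freq = rng.uniform(0.5, 2.0, size=bg.size)
    latent[bg] += 1.0 * np.sin(freq[:, None] * t[None, :] * np.pi + phase[:, None])

    baseline = _gene_baselines(cfg)
    fpkm = np.exp(0.4 * latent + baseline[:, None])
    samples = [
        f"dev_c{c + 1}_s{s + 1}"
        for c in range(cfg.dev_n_cultivars)
        for s in range(cfg.dev_n_stages)
    ]
    return pd.DataFrame(fpkm, index=genes, columns=samples)


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """One concrete amino-acid instance of a bracket pattern."""
    out = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "[":
            j = pattern.index("]", i)
            out.append(rng.choice(list(pattern[i + 1 : j])))
            i = j + 1
        else:
            out.append(pattern[i])
            i += 1
    return "".join(out)


def simulate_proteins(
    gene_ids: list,
    regulator_gene: str | None,
    cfg: SimConfig,
    length: int = 300,
) -> tuple[dict, dict]:
    """Random protein sequences; only the regulator carries the SCW motifs.

    Returns ``(sequences, motif_offsets)`` where motif_offsets maps the
    regulator id to ``{"LP": offset, "WQ": offset}`` (1-based). Non-regulator
    sequences are rejection-sampled until they contain no LP-/WQ-box match.
    """
    rng = _rng(cfg, _PROT_STREAM)
    lp_re, wq_re = re.compile(LP_BOX), re.compile(WQ_BOX)
    seqs: dict = {}
    offsets: dict = {}
    for gid in gene_ids:
        for _ in range(100):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
            if not lp_re.search(seq) and not wq_re.search(seq):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a motif-free background sequence")
        if gid == regulator_gene:
            lp = _instantiate(LP_BOX, rng)
            wq = _instantiate(WQ_BOX, rng)
            lp_off = int(rng.integers(20, length // 2 - len(lp)))
            wq_off = int(rng.integers(length // 2, length - len(wq)))
            seq = (
                seq[:lp_off]
                + lp
                + seq[lp_off + len(lp) : wq_off]
                + wq
                + seq[wq_off + len(wq) :]
            )
            offsets[gid] = {"LP": lp_off + 1, "WQ": wq_off + 1}
        seqs[gid] = seq
    return seqs, offsets


def simulate_all(cfg: SimConfig) -> dict:
    """Run every generator stage; returns a dict of all artifacts."""
    geno = simulate_genotypes(cfg)
    annotation = simulate_annotation(cfg)
    expr, truth = simulate_expression(geno, annotation, cfg)
    traits = simulate_trait(expr, truth, cfg)
    dev = simulate_development_panel(annotation, truth, cfg)
    proteins, offsets = simulate_proteins(truth.tf_genes, truth.regulator_gene, cfg)
    truth.motif_offsets = offsets
    return {
        "genotypes": geno,
        "annotation": annotation,
        "expression": expr,
        "truth": truth,
        "traits": traits,
        "dev_expression": dev,
        "proteins": proteins,
    }
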