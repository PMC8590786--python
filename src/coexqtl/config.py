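"""Configuration objects for the simulator and the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


@dataclass
class SimConfig:
    """Parameters of the synthetic diversity panel.

    Defaults emulate the motivating study design: ~200 individuals in two
    diverged subpopulations, biallelic SNPs with MAF > 5% and < 20%
    missingness, dense gene models (adjacent intergenic gaps mostly < 20 kb),
    expression with a handful of co-expression modules, planted cis effects,
    one trans master regulator driving the trait module, and a trait whose
    range emulates stone-cell content (3.2-22.6 g/100 g).
    """

    n_individuals: int = 206
    n_subpops: int = 2
    fst_divergence: float = 0.15
    n_chromosomes: int = 3
    chrom_length_bp: int = 10_000_000
    n_genes: int = 1000
    n_snps: int = 5000
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.05
    n_modules: int = 3
    module_sizes: tuple = (150, 100, 80)
    module_loading_range: tuple = (0.8, 1.25)
    n_cis_genes: int = 30
    cis_effect_sd: float = 1.0
    trans_effect_sd: float = 1.0
    noise_sd: float = 1.0
    trait_noise_sd: float = 0.3
    n_regulators: int = 1
    n_structural_genes: int = 45
    n_tf_genes: int = 30
    # developmental mini-panel merged in for the targeted network
    dev_n_stages: int = 7
    dev_n_cultivars: int = 3
    dev_amplitude: float = 2.5
    dev_noise_sd: float = 0.3
    # fraction of background genes silenced in most samples (exercises the
    # expressed-gene filters)
    dropout_gene_frac: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_individuals": self.n_individuals,
            "n_subpops": self.n_subpops,
            "n_chromosomes": self.n_chromosomes,
            "n_genes": self.n_genes,
            "n_snps": self.n_snps,
            "n_modules": self.n_modules,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.n_snps < 10 or self.n_individuals < 10:
            raise ValueError(
                "need n_snps >= 10 and n_individuals >= 10 for downstream "
                "covariance estimation"
            )
        if not (0 <= self.missing_rate < 0.2):
            raise ValueError("missing_rate must be in [0, 0.2)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes must sum to <= n_genes")
        if not (0 <= self.fst_divergence < 1):
            raise ValueError("fst_divergence must be in [0, 1)")


@dataclass
class RunConfig:
    """Flat configuration of the full pipeline.

    Analysis defaults are the study's published settings: soft powers 5
    (module detection) and 9 (targeted network), eigengene merge threshold
    0.3, MAF > 0.05, missingness < 0.2, 20 latent expression factors plus
    5 genotype PCs, Bonferroni alpha 0.05, 20-kb local/clump window, 1-Mb
    hotspot windows, 1000 permutations, module/gene trait p cut-offs
    0.01 / 0.05, TOM edge threshold 0.01.
    """

    outdir: str = "run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple = ("simulate", "preprocess", "modules", "eqtl", "network", "regulators")
    maf_min: float = 0.05
    miss_max: float = 0.2
    k_factors: int = 20
    n_geno_pcs: int = 5
    drop_genetic_factors: bool = True
    beta_modules: float = 5.0
    min_module_size: int = 30
    cut_height_frac: float = 0.99
    merge_diss: float = 0.3
    module_p: float = 0.01
    gene_p: float = 0.05
    alpha: float = 0.05
    local_window: int = 20_000
    hotspot_window: int = 1_000_000
    n_perm: int = 1000
    hotspot_p: float = 0.01
    beta_network: float = 9.0
    tom_min: float = 0.01
    region_halfwidth: int = 20_000
    candidates_tf_only: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            sim_known = {f.name for f in fields(SimConfig)}
            sim_unknown = set(sim_raw) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
            for key in ("maf_range", "module_sizes", "module_loading_range"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            cfg.sim = SimConfig(**sim_raw)
        if "stages" in raw:
            cfg.stages = tuple(raw["stages"])
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d
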