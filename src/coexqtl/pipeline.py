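"""End-to-end orchestration: simulate -> preprocess -> modules -> eqtl ->
network -> regulators, with a run manifest and deterministic seeding.

Every stage writes its outputs under the run directory with fixed file
names and appends a manifest entry (parameters, seed, input checksums, row
counts). Re-running with the same config and seed reproduces all outputs
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from coexqtl import coexpression, eqtl, io, network, preprocess, simulate
from coexqtl.config import RunConfig

log = logging.getLogger("coexqtl")

STAGE_ORDER = ("simulate", "preprocess", "modules", "eqtl", "network", "regulators")
_DEPS = {
    "preprocess": ("simulate",),
    "modules": ("preprocess",),
    "eqtl": ("preprocess",),
    "network": ("preprocess",),
    "regulators": ("eqtl", "network"),
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns in-memory artifacts.

    Raises :class:`PipelineError` naming the failing stage, including when
    a requested stage's dependency is not enabled.
    """
    stages = [s for s in STAGE_ORDER if s in config.stages]
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for s in stages:
        for dep in _DEPS.get(s, ()):
            if dep not in stages:
                raise PipelineError(s, f"requires stage '{dep}' to be enabled")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    art: dict = {}

    sim_cfg = dataclasses.replace(config.sim, seed=config.seed)

    def record(stage: str, files: dict, counts: dict) -> None:
        manifest["stages"][stage] = {
            "seed": config.seed,
            "files": {name: _sha256(Path(p)) for name, p in files.items()},
            "counts": counts,
        }

    if "simulate" in stages:
        log.info("simulate: n=%d, %d SNPs, %d genes", sim_cfg.n_individuals,
                 sim_cfg.n_snps, sim_cfg.n_genes)
        sim = simulate.simulate_all(sim_cfg)
        art.update(sim)
        files = {
            "genotypes": io.write_vcf(sim["genotypes"], outdir / "genotypes.vcf"),
            "gene_models": io.write_gene_models(sim["annotation"], outdir / "gene_models.tsv"),
            "expression": io.write_expression(sim["expression"], outdir / "expression.tsv"),
            "traits": io.write_traits(sim["traits"], outdir / "traits.tsv"),
            "dev_expression": io.write_expression(
                sim["dev_expression"], outdir / "dev_expression.tsv"
            ),
            "proteins": io.write_fasta(sim["proteins"], outdir / "proteins.fasta"),
            "truth": io.write_truth(sim["truth"], outdir / "truth.tsv"),
        }
        record("simulate", files, {
            "individuals": sim["genotypes"].n_individuals,
            "snps": sim["genotypes"].n_snps,
            "genes": len(sim["expression"]),
        })

    if "preprocess" in stages:
        geno_all = art["genotypes"]
        geno = preprocess.filter_snps(geno_all, config.maf_min, config.miss_max)
        log.info("preprocess: %d/%d SNPs pass MAF/missingness",
                 geno.n_snps, geno_all.n_snps)
        expr_eqtl = preprocess.filter_genes_for_eqtl(art["expression"])
        log.info("preprocess: %d/%d genes expressed (median FPKM > 0)",
                 len(expr_eqtl), len(art["expression"]))
        expr_norm, degenerate = preprocess.rank_normalize_matrix(expr_eqtl)
        covariates = preprocess.build_covariates(
            expr_norm,
            geno,
            k_factors=config.k_factors,
            n_geno_pcs=config.n_geno_pcs,
            screen_genetic=config.drop_genetic_factors,
        )
        log.info(
            "preprocess: %d latent factors kept (%d dropped as genetic), %d genotype PCs",
            covariates.latent_factors.shape[1],
            len(covariates.dropped_genetic_factors),
            covariates.genotype_pcs.shape[1],
        )
        art.update(
            geno_filtered=geno,
            expr_eqtl=expr_eqtl,
            expr_norm=expr_norm,
            covariates=covariates,
        )
        norm_path = io.write_expression(expr_norm, outdir / "expression_norm.tsv")
        record("preprocess", {"expression_norm": norm_path}, {
            "snps_kept": geno.n_snps,
            "genes_expressed": len(expr_eqtl),
            "degenerate_genes": len(degenerate),
            "latent_factors": covariates.latent_factors.shape[1],
            "dropped_genetic_factors": len(covariates.dropped_genetic_factors),
        })

    if "modules" in stages:
        expr_mod = preprocess.filter_genes_for_modules(art["expression"])
        log.info("modules: %d/%d genes pass mean-FPKM filter",
                 len(expr_mod), len(art["expression"]))
        expr_mod_norm, _ = preprocess.rank_normalize_matrix(expr_mod)
        adj = coexpression.soft_adjacency(expr_mod_norm, beta=config.beta_modules)
        tom = coexpression.tom_similarity(adj)
        partition = coexpression.detect_modules(
            tom,
            expr_mod_norm.index.to_numpy(),
            min_module_size=config.min_module_size,
            cut_height_frac=config.cut_height_frac,
            soft_power=config.beta_modules,
        )
        partition = coexpression.merge_modules(
            expr_mod_norm, partition, threshold=config.merge_diss
        )
        traits = art["traits"].loc[expr_mod_norm.columns]
        mt = coexpression.module_trait_table(partition.eigengenes, traits)
        selected = coexpression.select_trait_modules(
            partition.eigengenes, traits["stone_cell"], p_max=config.module_p
        )
        log.info("modules: %d modules, trait-associated: %s",
                 len(partition.modules()), selected)
        art.update(partition=partition, module_trait=mt, trait_modules=selected)
        assign = pd.DataFrame(
            {"gene_id": partition.gene_ids, "module": partition.labels}
        )
        files = {
            "modules": outdir / "modules.tsv",
            "eigengenes": outdir / "eigengenes.tsv",
            "module_trait": outdir / "module_trait.tsv",
        }
        assign.to_csv(files["modules"], sep="\t", index=False)
        partition.eigengenes.to_csv(files["eigengenes"], sep="\t", float_format="%.6g")
        mt.to_csv(files["module_trait"], sep="\t", index=False, float_format="%.6g")
        record("modules", files, {
            "genes_clustered": int((partition.labels > 0).sum()),
            "modules": len(partition.modules()),
            "trait_modules": len(selected),
        })

    if "eqtl" in stages:
        geno = art["geno_filtered"]
        expr_norm = art["expr_norm"]
        threshold = eqtl.bonferroni_threshold(geno.n_snps, len(expr_norm), config.alpha)
        assocs, summary = eqtl.scan(geno, expr_norm, art["covariates"], p_keep=threshold)
        log.info("eqtl: %d significant pairs at p <= %.3g (df=%d)",
                 len(assocs), threshold, summary.df)
        records = eqtl.collapse_all_genes(assocs, window=config.local_window)
        records = eqtl.classify_local_distant(
            records, art["annotation"], local_window=config.local_window
        )
        chrom_lengths = {
            f"chr{c}": sim_cfg.chrom_length_bp
            for c in range(1, sim_cfg.n_chromosomes + 1)
        }
        hotspots = eqtl.hotspot_detection(
            records[records["class"] == "distant"],
            chrom_lengths,
            window=config.hotspot_window,
            n_perm=config.n_perm,
            alpha=config.hotspot_p,
            seed=np.random.default_rng([config.seed, 101]),
        )
        log.info("eqtl: %d eQTLs (%d local, %d distant), hotspot cutoff %d, %d hotspots",
                 len(records), int((records["class"] == "local").sum()),
                 int((records["class"] == "distant").sum()),
                 hotspots.cutoff, len(hotspots.hotspots))
        art.update(assocs=assocs, eqtl_records=records, hotspots=hotspots,
                   bonferroni_p=threshold)
        files = {
            "associations": outdir / "associations.tsv",
            "eqtls": outdir / "eqtls.tsv",
            "hotspots": outdir / "hotspots.bed",
        }
        assocs.to_csv(files["associations"], sep="\t", index=False, float_format="%.6g")
        records.to_csv(files["eqtls"], sep="\t", index=False, float_format="%.6g")
        bed = hotspots.windows.copy()
        bed["start0"] = bed["start"] - 1
        bed[["chrom", "start0", "end", "count", "hotspot"]].to_csv(
            files["hotspots"], sep="\t", index=False, header=False
        )
        record("eqtl", files, {
            "significant_pairs": len(assocs),
            "eqtls": len(records),
            "local": int((records["class"] == "local").sum()),
            "distant": int((records["class"] == "distant").sum()),
            "hotspot_cutoff": hotspots.cutoff,
            "hotspots": int(len(hotspots.hotspots)),
        })

    if "network" in stages:
        truth = art["truth"]
        merged = network.merge_expression_panels(
            art["expression"], art["dev_expression"], prefixes=("panel", "dev")
        )
        graph = network.build_targeted_network(
            merged,
            truth.structural_genes,
            truth.tf_genes,
            beta=config.beta_network,
            weight_min=config.tom_min,
        )
        hubs, hub_cutoff = network.hub_detection(
            graph,
            n_perm=config.n_perm,
            seed=np.random.default_rng([config.seed, 202]),
        )
        log.info("network: %d nodes, %d edges, hub cutoff %d, %d hubs",
                 graph.graph.number_of_nodes(), graph.graph.number_of_edges(),
                 hub_cutoff, len(hubs))
        art.update(graph=graph, hubs=hubs, hub_cutoff=hub_cutoff, merged_expr=merged)
        files = {"edges": outdir / "network_edges.tsv", "graphml": outdir / "network.graphml"}
        graph.edge_table().to_csv(files["edges"], sep="\t", index=False, float_format="%.6g")
        nx_write(graph, files["graphml"])
        record("network", files, {
            "nodes": graph.graph.number_of_nodes(),
            "edges": graph.graph.number_of_edges(),
            "hub_cutoff": hub_cutoff,
            "hubs": len(hubs),
        })

    if "regulators" in stages:
        truth = art["truth"]
        graph = art["graph"]
        records = art["eqtl_records"]
        structural = set(truth.structural_genes)
        struct_records = records[records["gene_id"].isin(structural)]
        candidates = network.identify_regulators(
            struct_records,
            graph,
            art["annotation"],
            region_halfwidth=config.region_halfwidth,
            tf_only=config.candidates_tf_only,
        )
        motifs = network.scan_scw_motifs(art["proteins"])
        log.info("regulators: %d candidates; top: %s", len(candidates),
                 candidates["regulator_gene"].iloc[0] if len(candidates) else None)
        art.update(candidates=candidates, motif_hits=motifs)
        files = {
            "candidates": outdir / "regulator_candidates.tsv",
            "motifs": outdir / "motif_hits.tsv",
        }
        candidates.to_csv(files["candidates"], sep="\t", index=False, float_format="%.6g")
        motifs.to_csv(files["motifs"], sep="\t", index=False)
        record("regulators", files, {
            "candidates": len(candidates),
            "motif_hits": len(motifs),
        })

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    art["manifest"] = manifest
    return art


def nx_write(coexpr, path: Path) -> None:
    import networkx as nx

    nx.write_graphml(coexpr.graph, str(path))
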