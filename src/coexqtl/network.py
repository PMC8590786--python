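"""Targeted TF x structural-gene co-expression network and regulator calls.

The network is built from the TOM of the merged expression panels at soft
power 9, keeping edges with weight >= 0.01. Hub nodes are called against a
permutation null that randomly reassigns every edge to a uniformly chosen
node pair. Candidate regulators are genes located inside an eQTL region
(leading SNP +- 20 kb) that are co-expressed (graph adjacency) with the
structural gene the eQTL was detected for, ranked by the number of
distinct structural genes they support. Candidate proteins can be scanned
for the conserved LP-/WQ-box activation motifs of secondary-cell-wall NAC
transcription factors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from coexqtl.coexpression import soft_adjacency, tom_similarity
from coexqtl.containers import warn
from coexqtl.simulate import LP_BOX, WQ_BOX


def merge_expression_panels(
    panel_a: pd.DataFrame, panel_b: pd.DataFrame, prefixes: tuple = ("a", "b")
) -> pd.DataFrame:
    """Column-wise concatenation of two panels on their shared genes.

    Sample ids are made unique with a panel prefix; a shrinking gene
    universe (intersection) is logged via a warning.
    """
    shared = panel_a.index.intersection(panel_b.index)
    if shared.empty:
        raise ValueError("expression panels share no genes")
    if len(shared) < max(len(panel_a), len(panel_b)):
        warn(
            f"panels intersect to {len(shared)} genes "
            f"(from {len(panel_a)} and {len(panel_b)})"
        )
    a = panel_a.loc[shared].add_prefix(f"{prefixes[0]}:", axis=1)
    b = panel_b.loc[shared].add_prefix(f"{prefixes[1]}:", axis=1)
    return pd.concat([a, b], axis=1)


@dataclass
class CoexprGraph:
    """Undirected weighted co-expression graph over structural genes + TFs."""

    graph: nx.Graph
    soft_power: float = 9.0
    weight_min: float = 0.01
    excluded_structural: list = field(default_factory=list)

    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]

    def edge_table(self, structural_tf_only: bool = True) -> pd.DataFrame:
        """Edge list; by default only structural-TF relations, the exported
        view (intra-role connections are retained internally)."""
        rows = []
        for u, v, data in self.graph.edges(data=True):
            roles = {self.graph.nodes[u]["role"], self.graph.nodes[v]["role"]}
            if structural_tf_only and roles != {"structural", "TF"}:
                continue
            rows.append({"gene_a": u, "gene_b": v, "weight": data["weight"]})
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])


def build_targeted_network(
    expr_merged: pd.DataFrame,
    structural_ids: list,
    tf_ids: list,
    beta: float = 9.0,
    weight_min: float = 0.01,
    log_transform: bool = True,
) -> CoexprGraph:
    """TOM network over the structural + TF gene set.

    Expression is log1p-transformed by default (FPKM-like input), the TOM
    is computed at soft power ``beta``, and edges with TOM >= ``weight_min``
    are kept. Structural genes with no TF edge are reported as excluded
    (they remain in the node set with degree possibly > 0 via intra-role
    edges).
    """
    structural_ids = list(structural_ids)
    tf_ids = list(tf_ids)
    if not structural_ids or not tf_ids:
        raise ValueError("structural and TF id lists must be non-empty")
    overlap = set(structural_ids) & set(tf_ids)
    if overlap:
        raise ValueError(f"role lists overlap: {sorted(overlap)[:5]}")
    nodes = structural_ids + tf_ids
    missing = set(nodes) - set(expr_merged.index)
    if missing:
        raise KeyError(f"genes absent from expression: {sorted(missing)[:5]}")

    x = expr_merged.loc[nodes]
    if log_transform:
        x = np.log1p(x)
    tom = tom_similarity(soft_adjacency(x, beta=beta))

    g = nx.Graph()
    roles = {gid: "structural" for gid in structural_ids}
    roles.update({gid: "TF" for gid in tf_ids})
    for gid in nodes:
        g.add_node(gid, role=roles[gid])
    iu, ju = np.triu_indices(len(nodes), k=1)
    keep = tom[iu, ju] >= weight_min
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(nodes[i], nodes[j], weight=float(tom[i, j]))

    excluded = [
        s
        for s in structural_ids
        if not any(roles[nbr] == "TF" for nbr in g.neighbors(s))
    ]
    if excluded:
        warn(f"{len(excluded)} structural genes have no TF edge")
    return CoexprGraph(
        graph=g, soft_power=beta, weight_min=weight_min, excluded_structural=excluded
    )


def hub_detection(
    coexpr: CoexprGraph | nx.Graph,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> tuple[list, int]:
    """Permutation-based hub calling on node degree.

    Null: each of the E edges is reassigned to a uniformly chosen unordered
    node pair (self-pairs excluded; a pair may receive several edges).
    Pooling node degrees over ``n_perm`` permutations, the cutoff is the
    smallest degree d whose pooled null fraction of nodes with degree >= d
    is <= ``alpha``; hubs are observed nodes with degree >= cutoff.
    Returns ``(hub_nodes, cutoff)``.
    """
    g = coexpr.graph if isinstance(coexpr, CoexprGraph) else coexpr
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n < 2 or e < 1:
        raise ValueError("need >= 2 nodes and >= 1 edge")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    i = rng.integers(0, n, size=(n_perm, e))
    j = rng.integers(0, n - 1, size=(n_perm, e))
    j = j + (j >= i)  # uniform over pairs with j != i
    null_degrees = np.empty((n_perm, n), dtype=np.int64)
    for p in range(n_perm):
        null_degrees[p] = np.bincount(i[p], minlength=n) + np.bincount(j[p], minlength=n)
    pooled = null_degrees.ravel()
    max_d = int(pooled.max())
    hist = np.bincount(pooled, minlength=max_d + 2)
    tail = hist[::-1].cumsum()[::-1] / pooled.size
    cutoff = int(np.argmax(tail <= alpha))
    if tail[cutoff] > alpha:
        cutoff = max_d + 1

    hubs = [node for node, deg in g.degree() if deg >= cutoff]
    return hubs, cutoff


def identify_regulators(
    eqtl_records: pd.DataFrame,
    coexpr: CoexprGraph,
    gene_models: pd.DataFrame,
    region_halfwidth: int = 20_000,
    tf_only: bool = False,
) -> pd.DataFrame:
    """Candidate regulators from eQTL-region x co-expression intersection.

    For each eQTL record of a structural gene, the candidate region is the
    leading SNP +- ``region_halfwidth``. Every annotated gene overlapping
    that region that has a network edge to the record's structural gene
    becomes a candidate (the structural gene itself is not its own
    candidate); the candidate's mode is inherited from the eQTL class.
    Candidates are aggregated over records and ranked by support (number of
    distinct structural genes), ties broken by total edge weight.
    """
    g = coexpr.graph
    if "class" not in eqtl_records.columns:
        raise ValueError("eqtl_records must carry a local/distant 'class' column")
    records = eqtl_records.rename(columns={"class": "eqtl_class"})
    candidates: dict[str, dict] = {}
    for rec in records.itertuples():
        target = rec.gene_id
        if target not in g:
            continue
        lo, hi = rec.snp_pos - region_halfwidth, rec.snp_pos + region_halfwidth
        in_region = gene_models[
            (gene_models["chrom"] == rec.snp_chrom)
            & (gene_models["end"] >= lo)
            & (gene_models["start"] <= hi)
        ]
        for cand in in_region.itertuples():
            gid = cand.gene_id
            if gid == target or not g.has_edge(gid, target):
                continue
            if tf_only and g.nodes[gid].get("role") != "TF":
                continue
            entry = candidates.setdefault(
                gid,
                {
                    "regulated": set(),
                    "weight": 0.0,
                    "modes": set(),
                    "regions": set(),
                },
            )
            entry["regulated"].add(target)
            entry["weight"] += g.edges[gid, target]["weight"]
            entry["modes"].add(rec.eqtl_class)
            entry["regions"].add((rec.snp_chrom, int(lo), int(hi)))

    rows = []
    for gid, entry in candidates.items():
        rows.append(
            {
                "regulator_gene": gid,
                "support": len(entry["regulated"]),
                "total_edge_weight": entry["weight"],
                "mode": ";".join(sorted(entry["modes"])),
                "n_regions": len(entry["regions"]),
                "regulated_genes": ",".join(sorted(entry["regulated"])),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "regulator_gene",
            "support",
            "total_edge_weight",
            "mode",
            "n_regions",
            "regulated_genes",
        ],
    )
    if not out.empty:
        out = out.sort_values(
            ["support", "total_edge_weight"], ascending=False, kind="mergesort"
        ).reset_index(drop=True)
    return out


_MOTIFS = {"LP": LP_BOX, "WQ": WQ_BOX}
_VALID_AA = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX*\-]*$")


def scan_scw_motifs(sequences: dict) -> pd.DataFrame:
    """Exact bracket-pattern scan for the LP-box and WQ-box motifs.

    Each bracket matches exactly one of its listed residues. All
    non-overlapping hits are reported with 1-based offsets. Sequences with
    characters outside the amino-acid alphabet trigger a warning (those
    positions simply cannot match).
    """
    compiled = {name: re.compile(pat) for name, pat in _MOTIFS.items()}
    rows = []
    for seq_id, seq in sequences.items():
        s = str(seq).upper()
        if not _VALID_AA.match(s):
            warn(f"sequence {seq_id} contains non-amino-acid characters")
        for name, rx in compiled.items():
            for m in rx.finditer(s):
                rows.append({"seq_id": seq_id, "motif": name, "offset": m.start() + 1})
    return pd.DataFrame(rows, columns=["seq_id", "motif", "offset"])
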