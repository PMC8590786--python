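# coexqtl

Systems genetics of a polygenic quality trait: weighted co-expression
modules, all-pairs eQTL mapping with hotspot detection, and regulator
prioritization by intersecting eQTL regions with co-expression.

The motivating problem is stone-cell lignocellulose formation in pear
fruit: stone cells are lignified sclerenchyma clusters whose secondary
cell walls (lignin + cellulose) make flesh gritty, and the content varies
~7-fold (3.2–22.6 g/100 g) across a diversity panel of ~200 cultivars.
Identifying the transcription factor that drives secondary-cell-wall (SCW)
structural genes requires combining three layers of evidence, all of which
this package implements:

1. **Co-expression modules** (`coexqtl.coexpression`). Unsigned weighted
   networks with soft-thresholded adjacency *a_ij = |cor(x_i, x_j)|^β*
   (β = 5), the topological overlap matrix

   TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

   average-linkage clustering of 1 − TOM, module eigengenes (first PC of
   the standardized module block), eigengene merging at dissimilarity
   0.3, and module/gene–trait association via the Student asymptotic
   p-value for Pearson *r* (t = r√(n−2)/√(1−r²), df = n − 2).
2. **eQTL mapping** (`coexqtl.eqtl`). Per SNP–gene pair, OLS of
   rank-normalized expression on additive dosage with nuisance covariates
   (K = 20 latent expression factors + 5 genotype PCs), Bonferroni
   threshold α/(#SNPs × #genes), greedy leading-SNP collapse within 20 kb,
   local/distant classification (local = SNP within 20 kb of the gene
   interval), and distant-eQTL hotspot calling: observed counts per 1-Mb
   window against a permutation null of uniform reassignment (1000
   permutations, bin-level exceedance at P ≤ 0.01).
3. **Targeted network and regulator calls** (`coexqtl.network`). A
   structural-gene × TF TOM network on merged cultivar + developmental
   panels (β = 9, edge weight ≥ 0.01), permutation hub calling on node
   degree, and the candidate-regulator rule: a gene located inside an
   eQTL region (leading SNP ± 20 kb) that is co-expressed with the
   structural gene the eQTL was detected for, ranked by the number of
   distinct supported targets. Candidate proteins can be scanned for the
   conserved LP-box `F[ML]QLPQLESP[KS]` and WQ-box
   `DQ[VL]TDWRALD[KR][LF][VL]AS[QH]L[SN]Q[DE]D` activation motifs of SCW
   NAC transcription factors.

Because the original ~0.5 TB RNA-seq panel is not desk-reproducible, the
package ships a first-class synthetic-data generator
(`coexqtl.simulate`) that emulates the study design with planted,
recorded ground truth — two diverged subpopulations (Balding–Nichols
allele frequencies), dense gene models (~90% of adjacent intergenic gaps
< 20 kb), factor-model expression with three modules, planted cis
effects, one trans master regulator whose local SNP drives a whole
module, and a module-driven trait rescaled to the observed stone-cell
range. Every stage is validated against this truth.

## Worked example

`examples/` contains one narrative script per capability. The end-to-end
run (`examples/05_full_pipeline.py`, or `coexqtl all --outdir run --seed 1`
from a shell) prints:

```
preprocess: 4998/5000 SNPs pass MAF/missingness
preprocess: 980/1000 genes expressed (median FPKM > 0)
preprocess: 18 latent factors kept (2 dropped as genetic), 5 genotype PCs
modules: 3 modules, trait-associated: [1]
eqtl: 180 significant pairs at p <= 1.02e-08 (df=181)
eqtl: 180 eQTLs (31 local, 149 distant), hotspot cutoff 12, 1 hotspots
network: 75 nodes, 1035 edges, hub cutoff 41, 46 hubs
regulators: 1 candidates; top: gene_00268
```

Reading the numbers: the scan tests 4998 × 980 pairs at the Bonferroni
threshold 0.05/(4998×980) ≈ 1.0e-8; two latent expression factors were
excluded from the covariates because they are under single-SNP genetic
control (they carry the planted trans-regulatory axis). The 149 distant
eQTLs — one per regulated gene, all pointing at the regulator's locus —
pile into a single 1-Mb window, far above the permutation cutoff of 12
per Mb expected by chance, and the region × co-expression intersection
returns exactly one candidate, `gene_00268`, which is the planted
regulator; its protein carries one LP-box and one WQ-box hit
(`examples/04_regulator_candidates.py`).

Module detection on the same run (`examples/02_coexpression_modules.py`)
recovers the three planted modules with adjusted Rand index 1.0, and only
module 1 — the one the trait was planted on — is trait-associated
(r = +0.68, p = 5.3e-29).

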