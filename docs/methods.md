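# Methods

This note documents the models, parameter choices and numerical
conventions behind `coexqtl`, and what the synthetic validation does and
does not demonstrate.

## The analysis model

The pipeline treats a diversity panel as three aligned data layers:
additive SNP dosages (individuals × SNPs), gene expression (genes ×
samples, FPKM-like), and quantitative traits. Its object of inference is
a *trans master regulator*: a gene whose local genetic variation
propagates to a whole co-expression module and, through it, to the trait.
Evidence is accumulated in three passes — module structure, genetic
association, and their intersection — none of which alone identifies the
regulator.

### Co-expression modules

Unsigned weighted networks: adjacency `|cor|^beta` with the soft power
β = 5 for genome-wide module detection and β = 9 for the small targeted
network (both taken from the motivating study's calibration; the
scale-free-fit procedure used to pick them is out of scope). The
topological overlap matrix down-weights edges unsupported by shared
neighbours and is the clustering substrate. Genes enter module detection
when mean FPKM ≥ 1.

Tree cutting is deliberately simpler than the Dynamic Hybrid algorithm:
average-linkage clustering of 1 − TOM is cut statically at
`cut_height_frac` (default 0.99) of the maximum merge height, and
clusters below `min_module_size` (30) become unassigned (label 0). The
validation surface here is planted-block recovery, not label-for-label
agreement with any particular dendrotomy implementation; on well-separated
blocks the two approaches coincide. Modules whose eigengenes (first PC of
the standardized block, sign-oriented toward the mean profile, unit
variance) correlate above 1 − 0.3 are merged iteratively, closest pair
first, recomputing eigengenes after each merge — this makes the result
independent of module enumeration order for disjoint merge pairs.

Trait association uses the Student asymptotic p-value of the Pearson
correlation (t = r√(n−2)/√(1−r²), df = n−2), with module selection at
P ≤ 0.01 and per-gene selection at P < 0.05. Constant inputs yield a
flagged degenerate association with p = 1; perfectly collinear inputs
report the smallest representable positive p, flagged.

### eQTL scan

Expression is rank-normalized per gene with the inverse normal transform
Φ⁻¹((rᵢ − a)/(n + 1 − 2a)), a = 3/8 for n ≤ 10 and 1/2 otherwise
(the classic plotting-position convention of R's `qqnorm`), ties sharing
average ranks. Covariates are K = 20 principal components of the
normalized samples × genes matrix — the standard surrogate for PEER-style
hidden-factor models, whose variational machinery adds nothing the scan
needs beyond nuisance-variance removal — plus the first 5 genotype PCs
(dosages mean-imputed per SNP before PCA and regression; the least-
assumption treatment of missingness).

**Genetically controlled factors are excluded from the covariates.** A
latent expression factor that is itself strongly associated with a single
SNP (Bonferroni over factors × SNPs) is very likely capturing a real
trans-regulatory axis rather than technical nuisance; regressing it out
would erase precisely the distant signal the scan exists to find. This
screen (toggleable, on by default) follows established practice in
trans-eQTL mapping, where expression components under genetic control are
retained in the data rather than removed as confounders. In the synthetic
panel the screen reliably drops the component carrying the planted
regulator axis; without it, distant detection collapses to near zero.

The scan residualizes expression and dosage on [intercept, covariates]
once and then tests the per-pair slope of residuals (t with
df = n − 2 − #covariates). By Frisch–Waugh this is algebraically
identical to the full per-pair OLS — asserted against `statsmodels` in
the tests — and runs in blocked matrix products so the full SNP × gene
grid never materializes. Monomorphic SNPs and zero-residual-variance
genes are skipped and counted. Significance is Bonferroni at
α/(#SNPs × #genes).

Significant SNPs per gene are collapsed by greedy best-p clumping: take
the smallest-p SNP (ties: smaller coordinate), discard everything within
±20 kb, repeat per chromosome. The alternative fixed-grid binning was
rejected because it splits association peaks at bin boundaries. eQTLs are
local when the SNP lies within the gene interval ± 20 kb (inclusive,
strand-agnostic — the source description does not disambiguate
strandedness, and the gene-interval reading is symmetric), else distant.
The 20-kb width matches the empirical intergenic-distance structure:
~90% of adjacent gene gaps fall below 20 kb, and
`derive_local_window` recomputes that quantile from any annotation as a
suggestion (default stays 20 kb).

Hotspots: distant eQTLs are binned into non-overlapping 1-Mb windows;
the null redistributes all of them uniformly across windows 1000 times;
the cutoff is the smallest per-window count whose pooled null exceedance
is ≤ 0.01. This is bin-level exceedance ("eQTLs/Mb by chance alone"),
not a max-statistic FWER control — deliberately, since the quantity of
interest is the chance occupancy of a single window.

### Targeted network and candidates

The structural-gene × TF network is built on the column-concatenation of
the cultivar panel with a small developmental series (samples prefixed
per panel, genes intersected), log1p-transformed, at β = 9 with edge
threshold TOM ≥ 0.01. "Co-expressed with" is operationalized as graph
adjacency at that threshold — the network *is* the co-expression
criterion. Hub calling permutes each edge onto a uniformly chosen
unordered node pair (self-pairs excluded, multi-assignment allowed) and
applies the same pooled-exceedance cutoff rule to node degree.

Candidate regions are leading SNP ± 20 kb. The source analysis never
states the region width; ±20 kb keeps it consistent with both the
clumping interval and the local/distant window, and this is the one
genuinely free choice in the candidate rule — widening it admits more
bystander genes but the co-expression clause still filters them.
Candidates are any annotated genes overlapping a region with an edge to
the eQTL's structural gene (the gene itself excluded), ranked by distinct
supported targets, ties by summed edge weight. A `tf_only` switch
restricts candidates to TF-role genes (off by default; role lists are
user input, not predicted). Motif scanning is exact bracket-pattern
matching of the LP-/WQ-box patterns with non-overlapping 1-based hits —
strictly more conservative than a probabilistic position-weight-matrix
scan with a match threshold.

## The synthetic panel

Defaults emulate the study conditions: 206 individuals in two
subpopulations (Balding–Nichols, F_ST 0.15 — enough that genotype PC1
separates the clades, the reason genotype PCs are covariates at all),
5000 biallelic SNPs with realized MAF in (0.05, 0.5] and 5% missingness
(`./.` in VCF, sentinel −1 in memory), three chromosomes of 10 Mb, 1000
genes whose adjacent gaps are a 90/10 mixture of short exponential
(mean 5 kb, capped at 19 kb) and long uniform (25–80 kb) spacers so
~90% fall under 20 kb.

Expression: gene g in module m has latent value
`loading_g · factor_m + cis + trans + noise`, loadings U(0.8, 1.25)
against unit noise — within-module correlations ~0.4–0.6, typical of
strong WGCNA modules and comfortably above the static-cut resolution
limit. Thirty cis genes receive a 1.0-SD effect from a SNP within 20 kb;
regulated (trans-driven) genes are excluded from that pool so each
planted signal tests exactly one mechanism. The regulator is a
trait-module member with a SNP in (or within 20 kb of) its own body; its
dosage enters its own expression (1.0 SD — making the locus a local eQTL
for itself) and every other module-1 gene's expression (1.0 SD — making
it a distant eQTL source). Latent values map to FPKM as
`exp(0.4·latent + baseline_g)`, baseline_g ~ N(1.5, 1); 2% of background
genes are silenced in 70% of samples to exercise the expressed-gene
filters. Only ordering survives rank normalization, so the monotone map
is inconsequential downstream.

The developmental mini-panel (7 stages × 3 cultivars) gives trait-module
genes a shared unit-SD trajectory scaled by amplitude 2.5 — developmental
SCW deposition dwarfs between-cultivar variation, which is exactly why
the network stage merges the panels — with 0.3-SD noise, while background
genes follow low-amplitude gene-specific curves. Gene baselines are
shared between panels (real data has consistent per-gene abundance);
without that, panel-specific mean shifts destroy pooled correlations.

Traits: stone-cell, lignin and cellulose contents are positive affine
maps of the module-1 factor plus independent noise (0.3 SD), the
stone-cell trait rescaled exactly onto [3.2, 22.6] g/100 g. The exact
rescaling makes the ~7-fold range a construction invariant rather than a
sampled quantity.

Proteins: random 300-aa sequences for the TF list; only the regulator
carries one embedded LP-box and one WQ-box instance at recorded offsets,
and background sequences are rejection-sampled to be motif-free.

No effect-size or heritability figures are reported for any real eQTL in
the motivating system, so the planted 1.0-SD effects are calibrated for
test power, not realism. What passing tests show: the implementation
correctly recovers module structure, cis and trans signals, hotspot
windows and the planted regulator under a generative model matching its
own assumptions (linear additive effects, Gaussian factors, no LD beyond
population structure, no batch structure beyond latent factors). What
they do not show: robustness to linkage disequilibrium, allelic
heterogeneity, non-linear regulation, or the far lower signal-to-noise
of real panels.

## Numerical conventions and problem sizes

- Coordinates 1-based inclusive throughout; VCF positions used as-is.
- Determinism: every stage draws from `default_rng([seed, stream])`;
  identical config + seed reproduces all outputs byte-identically.
- Degenerate cases: constant genes get zero correlation (adjacency) and
  zero normal scores (flagged); singular module blocks fall back to the
  mean profile; empty hotspot/candidate sets are valid outputs.
- Default validation sizes — 206 × 5000 SNPs × 1000 genes, 1000
  permutations, ten seeds for recovery rates — keep a full pipeline run
  under ~4 s and the whole validation under a minute while leaving all
  statistical margins wide; the scan's blocked evaluation supports much
  larger panels in principle.

## Known limitations

- The static tree cut will fragment or miss modules whose TOM contrast is
  weak; the Dynamic Hybrid algorithm is strictly more sensitive there.
- The hotspot null assumes equal-probability 1-Mb windows (tail windows
  of short chromosomes are slightly conservative).
- Exact motif matching cannot find degenerate motif instances a PWM scan
  would accept.
- The latent-factor genetic screen uses a single-SNP test; a factor
  driven polygenically would evade it and still absorb trans signal.
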