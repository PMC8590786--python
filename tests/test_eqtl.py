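"""Association scan, leading-SNP collapse, classification, hotspots."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from coexqtl import eqtl, preprocess, simulate
from coexqtl.config import SimConfig
from coexqtl.containers import CovariateSet, GenotypeMatrix


def make_geno(dosage, chrom=None, pos=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    return GenotypeMatrix(
        dosage=dosage,
        snp_ids=np.array([f"s{j}" for j in range(m)]),
        snp_chrom=np.array(chrom if chrom is not None else ["chr1"] * m),
        snp_pos=np.array(pos if pos is not None else np.arange(1, m + 1) * 1000),
        sample_ids=np.array([f"i{i}" for i in range(n)]),
    )


def expr_frame(values, geno):
    values = np.atleast_2d(values)
    return pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                        columns=geno.sample_ids)


class TestBonferroni:
    def test_single_and_simple(self):
        assert eqtl.bonferroni_threshold(1, 1) == pytest.approx(0.05)
        assert eqtl.bonferroni_threshold(100, 10) == pytest.approx(5e-5)
        with pytest.raises(ValueError):
            eqtl.bonferroni_threshold(0, 10)

    def test_overflow_safe_at_large_counts(self):
        assert eqtl.bonferroni_threshold(10**7, 10**7) == pytest.approx(5e-16)


class TestScan:
    def test_orthogonal_genotype_gives_null(self):
        dosage = np.array([0, 1, 2, 1, 0, 1, 2, 1], dtype=np.int8)[:, None]
        geno = make_geno(dosage)
        y = np.array([1.0, 0.0, 1.0, 0.0, -1.0, 0.0, -1.0, 0.0])
        y -= y.mean()
        d = dosage[:, 0] - dosage[:, 0].mean()
        y -= (y @ d) / (d @ d) * d  # exactly orthogonal to dosage
        res, _ = eqtl.scan(geno, expr_frame(y, geno), None, p_keep=1.0)
        assert res["beta"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_closed_form_ols(self):
        gen = np.random.default_rng(0)
        n = 50
        dosage = gen.integers(0, 3, size=(n, 1)).astype(np.int8)
        geno = make_geno(dosage)
        y = 0.4 * dosage[:, 0] + gen.standard_normal(n)
        res, summary = eqtl.scan(geno, expr_frame(y, geno), None, p_keep=1.0)
        # textbook simple-regression slope t-test
        x = dosage[:, 0].astype(float)
        xc, yc = x - x.mean(), y - y.mean()
        beta = (xc @ yc) / (xc @ xc)
        resid = yc - beta * xc
        se = np.sqrt(resid @ resid / (n - 2) / (xc @ xc))
        t = beta / se
        p = 2 * stats.t.sf(abs(t), df=n - 2)
        assert summary.df == n - 2
        assert res["beta"].iloc[0] == pytest.approx(beta, abs=1e-10)
        assert res["t_stat"].iloc[0] == pytest.approx(t, abs=1e-10)
        assert res["p"].iloc[0] == pytest.approx(p, abs=1e-10)

    def test_residualized_scan_equals_full_ols_with_covariates(self):
        """Frisch-Waugh: residualize-once must equal the per-pair full model."""
        gen = np.random.default_rng(1)
        n, m, g, k = 60, 8, 5, 3
        geno = make_geno(gen.integers(0, 3, size=(n, m)).astype(np.int8))
        cov = gen.standard_normal((n, k))
        expr = expr_frame(gen.standard_normal((g, n)), geno)
        covset = CovariateSet(latent_factors=cov, genotype_pcs=np.empty((n, 0)))
        res, summary = eqtl.scan(geno, expr, covset, p_keep=1.0)
        assert summary.df == n - 2 - k
        for row in res.sample(10, random_state=0).itertuples():
            x = geno.dosage_imputed()[:, geno.snp_ids == row.snp_id][:, 0]
            y = expr.loc[row.gene_id].to_numpy()
            design = sm.add_constant(np.column_stack([cov, x]))
            fit = sm.OLS(y, design).fit()
            assert row.beta == pytest.approx(fit.params[-1], abs=1e-10)
            assert row.t_stat == pytest.approx(fit.tvalues[-1], abs=1e-8)
            assert row.p == pytest.approx(fit.pvalues[-1], abs=1e-10)

    def test_null_pvalues_uniform(self):
        gen = np.random.default_rng(2)
        n = 100
        geno = make_geno(gen.integers(0, 3, size=(n, 500)).astype(np.int8))
        expr = expr_frame(gen.standard_normal((200, n)), geno)
        res, _ = eqtl.scan(geno, expr, None, p_keep=1.0)
        assert len(res) == 100_000
        ks = stats.kstest(res["p"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_skipped_and_rank_deficiency_rejected(self):
        gen = np.random.default_rng(3)
        n = 30
        dosage = gen.integers(0, 3, size=(n, 3)).astype(np.int8)
        dosage[:, 1] = 2  # monomorphic
        geno = make_geno(dosage)
        expr = expr_frame(gen.standard_normal(n), geno)
        res, summary = eqtl.scan(geno, expr, None, p_keep=1.0)
        assert summary.n_monomorphic_skipped == 1
        assert set(res["snp_id"]) == {"s0", "s2"}
        dup = gen.standard_normal((n, 1))
        bad = CovariateSet(latent_factors=np.hstack([dup, dup]),
                           genotype_pcs=np.empty((n, 0)))
        with pytest.raises(ValueError, match="rank-deficient"):
            eqtl.scan(geno, expr, bad, p_keep=1.0)

    def test_misaligned_samples_rejected(self):
        gen = np.random.default_rng(4)
        geno = make_geno(gen.integers(0, 3, size=(20, 5)).astype(np.int8))
        expr = expr_frame(gen.standard_normal(20), geno)
        expr.columns = [f"x{i}" for i in range(20)]
        with pytest.raises(ValueError, match="align"):
            eqtl.scan(geno, expr, None)


class TestCollapse:
    def _assoc(self, pos, p, chrom=None, gene="g0"):
        return pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(len(pos))],
            "snp_chrom": chrom or ["chr1"] * len(pos),
            "snp_pos": pos,
            "gene_id": gene,
            "p": p,
        })

    def test_single_snp_is_its_own_leader(self):
        out = eqtl.collapse_leading_snps(self._assoc([5000], [1e-10]))
        assert len(out) == 1

    def test_hand_traced_greedy(self):
        # 1 kb (1e-20), 5 kb (1e-15), 30 kb (1e-18): leaders at 1 kb and 30 kb
        out = eqtl.collapse_leading_snps(
            self._assoc([1000, 5000, 30000], [1e-20, 1e-15, 1e-18])
        )
        assert sorted(out["snp_pos"]) == [1000, 30000]

    def test_tie_broken_by_coordinate(self):
        out = eqtl.collapse_leading_snps(self._assoc([4000, 2000], [1e-9, 1e-9]))
        assert out["snp_pos"].tolist() == [2000]

    def test_chromosomes_independent(self):
        out = eqtl.collapse_leading_snps(
            self._assoc([1000, 2000], [1e-9, 1e-8], chrom=["chr1", "chr2"])
        )
        assert len(out) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_exhaustive_oracle(self, seed):
        """No discarded SNP is farther than the window from a better-or-equal
        leader; no two leaders within the window on one chromosome."""
        gen = np.random.default_rng(seed)
        n = gen.integers(5, 80)
        assoc = self._assoc(
            gen.integers(1, 200_000, size=n),
            10.0 ** gen.uniform(-30, -8, size=n),
            chrom=gen.choice(["chr1", "chr2"], size=n).tolist(),
        )
        leaders = eqtl.collapse_leading_snps(assoc, window=20_000)
        lead_set = set(zip(leaders["snp_chrom"], leaders["snp_pos"]))
        for row in leaders.itertuples():
            near = leaders[
                (leaders["snp_chrom"] == row.snp_chrom)
                & ((leaders["snp_pos"] - row.snp_pos).abs() <= 20_000)
            ]
            assert len(near) == 1
        for row in assoc.itertuples():
            if (row.snp_chrom, row.snp_pos) in lead_set:
                continue
            better = leaders[
                (leaders["snp_chrom"] == row.snp_chrom)
                & ((leaders["snp_pos"] - row.snp_pos).abs() <= 20_000)
                & (leaders["p"] <= row.p)
            ]
            assert len(better) >= 1


class TestClassify:
    GM = pd.DataFrame({
        "gene_id": ["gA", "gB"],
        "chrom": ["chr1", "chr2"],
        "start": [100_000, 50_000],
        "end": [105_000, 55_000],
        "strand": ["+", "-"],
    })

    def _rec(self, chrom, pos, gene):
        return pd.DataFrame({
            "snp_id": ["s"], "snp_chrom": [chrom], "snp_pos": [pos],
            "gene_id": [gene], "p": [1e-15],
        })

    def test_inside_gene_local(self):
        out = eqtl.classify_local_distant(self._rec("chr1", 102_000, "gA"), self.GM)
        assert out["class"].iloc[0] == "local"
        assert out["distance_bp"].iloc[0] == 0

    def test_boundary_20kb_inclusive(self):
        out = eqtl.classify_local_distant(self._rec("chr1", 125_000, "gA"), self.GM)
        assert out["class"].iloc[0] == "local"  # end + 20,000 exactly
        out = eqtl.classify_local_distant(self._rec("chr1", 125_001, "gA"), self.GM)
        assert out["class"].iloc[0] == "distant"

    def test_other_chromosome_distant(self):
        out = eqtl.classify_local_distant(self._rec("chr2", 102_000, "gA"), self.GM)
        assert out["class"].iloc[0] == "distant"
        assert pd.isna(out["distance_bp"].iloc[0])

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            eqtl.classify_local_distant(self._rec("chr1", 1, "nope"), self.GM)

    def test_partition_into_local_plus_distant(self, sim_default):
        geno = preprocess.filter_snps(sim_default["genotypes"])
        expr = preprocess.filter_genes_for_eqtl(sim_default["expression"])
        norm, _ = preprocess.rank_normalize_matrix(expr)
        cov = preprocess.build_covariates(norm, geno)
        thr = eqtl.bonferroni_threshold(geno.n_snps, len(norm))
        res, _ = eqtl.scan(geno, norm, cov, p_keep=thr)
        records = eqtl.collapse_all_genes(res)
        records = eqtl.classify_local_distant(records, sim_default["annotation"])
        n_local = (records["class"] == "local").sum()
        n_distant = (records["class"] == "distant").sum()
        assert n_local + n_distant == len(records)


class TestLocalWindow:
    def test_constant_gaps(self):
        gm = pd.DataFrame({
            "gene_id": ["a", "b", "c"], "chrom": "chr1",
            "start": [1, 12_001, 24_001], "end": [2000, 14_000, 26_000],
            "strand": "+",
        })
        assert eqtl.derive_local_window(gm) == 10_000

    def test_synthetic_annotation_near_20kb(self, sim_default):
        w = eqtl.derive_local_window(sim_default["annotation"], coverage=0.90)
        assert 10_000 <= w <= 30_000

    def test_coverage_one_is_max_gap(self):
        gm = pd.DataFrame({
            "gene_id": ["a", "b", "c"], "chrom": "chr1",
            "start": [1, 3001, 60_001], "end": [2000, 4000, 62_000],
            "strand": "+",
        })
        assert eqtl.derive_local_window(gm, coverage=1.0) == 56_000

    def test_single_gene_warns_default(self):
        gm = pd.DataFrame({"gene_id": ["a"], "chrom": ["chr1"],
                           "start": [1], "end": [100], "strand": ["+"]})
        with pytest.warns(UserWarning):
            assert eqtl.derive_local_window(gm) == 20_000


class TestHotspots:
    LENGTHS = {"chr1": 10_000_000, "chr2": 10_000_000}

    def _records(self, chrom, pos):
        return pd.DataFrame({"snp_chrom": chrom, "snp_pos": pos})

    def test_zero_records_empty(self):
        hs = eqtl.hotspot_detection(self._records([], []), self.LENGTHS)
        assert hs.hotspots.empty and hs.cutoff == 0

    def test_single_bin_concentration_is_hotspot(self):
        recs = self._records(["chr1"] * 200, [500_000] * 200)
        hs = eqtl.hotspot_detection(recs, self.LENGTHS, n_perm=200, seed=0)
        hot = hs.hotspots
        assert len(hot) == 1
        assert hot.iloc[0]["chrom"] == "chr1" and hot.iloc[0]["start"] == 1

    def test_uniform_records_rarely_flag(self):
        flagged = 0
        for seed in range(20):
            gen = np.random.default_rng(seed)
            recs = self._records(
                gen.choice(["chr1", "chr2"], size=60).tolist(),
                gen.integers(1, 10_000_000, size=60),
            )
            hs = eqtl.hotspot_detection(recs, self.LENGTHS, n_perm=300, seed=seed)
            flagged += int(len(hs.hotspots) > 0)
        # bin-level exceedance at alpha=0.01 over 20 bins: a false hotspot
        # should be the exception, not the rule
        assert flagged <= 5

    def test_cutoff_monotone_in_record_count(self):
        cuts = []
        for n in (50, 200, 800):
            gen = np.random.default_rng(1)
            recs = self._records(
                gen.choice(["chr1", "chr2"], size=n).tolist(),
                gen.integers(1, 10_000_000, size=n),
            )
            cuts.append(eqtl.hotspot_detection(recs, self.LENGTHS, n_perm=300, seed=2).cutoff)
        assert cuts == sorted(cuts)

    def test_planted_regulator_bin_flagged(self, sim_default):
        truth = sim_default["truth"]
        geno = preprocess.filter_snps(sim_default["genotypes"])
        expr = preprocess.filter_genes_for_eqtl(sim_default["expression"])
        norm, _ = preprocess.rank_normalize_matrix(expr)
        cov = preprocess.build_covariates(norm, geno)
        thr = eqtl.bonferroni_threshold(geno.n_snps, len(norm))
        res, _ = eqtl.scan(geno, norm, cov, p_keep=thr)
        records = eqtl.collapse_all_genes(res)
        records = eqtl.classify_local_distant(records, sim_default["annotation"])
        lengths = {f"chr{c}": 10_000_000 for c in (1, 2, 3)}
        hs = eqtl.hotspot_detection(
            records[records["class"] == "distant"], lengths, n_perm=500, seed=5
        )
        snp_idx = np.where(geno.snp_ids == truth.regulator_snp)[0][0]
        chrom, pos = geno.snp_chrom[snp_idx], geno.snp_pos[snp_idx]
        hot = hs.hotspots
        inside = (
            (hot["chrom"] == chrom) & (hot["start"] <= pos) & (hot["end"] >= pos)
        )
        assert inside.any()
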