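"""LD computation, pruning, catalog overlap, genic context, eQTL scan."""

import numpy as np
import pandas as pd
import pytest

from asmscan.errors import DataError
from asmscan.ld import (
    annotate_gene_context,
    enrichment_test,
    greedy_ld_prune,
    ld_r2,
    permutation_eqtl_test,
    proxy_match,
)
from asmscan.simulate import simulate_genotype_panel


class TestLdR2:
    def test_identical_vectors(self):
        assert ld_r2([0, 1, 2, 1, 0], [0, 1, 2, 1, 0]) == pytest.approx(1.0)

    def test_allele_swap_invariance(self):
        x = np.array([0, 0, 1, 1, 2, 2])
        assert ld_r2(x, 2 - x) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert ld_r2([0, 0, 1, 1, 2, 2], [0, 1, 0, 1, 0, 1]) == pytest.approx(0.0)

    def test_monomorphic_is_nan(self):
        assert np.isnan(ld_r2([1, 1, 1, 1], [0, 1, 2, 1]))

    def test_pairwise_complete_handling(self):
        x = [0.0, 1.0, 2.0, np.nan, 0.0, 2.0]
        y = [0.0, 1.0, 2.0, 1.0, 0.0, 2.0]
        assert ld_r2(x, y) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            ld_r2([0, 1], [0, 1, 2])


class TestGreedyPrune:
    def _panel(self):
        rng = np.random.default_rng(4)
        a = rng.binomial(2, 0.5, 200).astype(float)
        noise = rng.binomial(2, 0.5, 200).astype(float)
        b = np.where(rng.random(200) < 0.75, a, noise)       # r2(a,b) high
        c = rng.binomial(2, 0.5, 200).astype(float)
        cb = np.where(rng.random(200) < 0.75, b, c)          # correlated with b
        panel = pd.DataFrame({"A": a, "B": b, "C": cb})
        assert ld_r2(panel["A"], panel["B"]) > 0.3
        assert ld_r2(panel["B"], panel["C"]) > 0.3
        assert ld_r2(panel["A"], panel["C"]) < 0.3
        return panel

    def test_greedy_trace_keeps_first_of_correlated_pair(self):
        panel = self._panel()
        kept = greedy_ld_prune(["A", "B", "C"], panel, r2_max=0.3,
                               scan_order=[0, 1, 2])
        assert kept == ["A", "C"]

    def test_uncorrelated_snps_all_kept(self):
        panel = simulate_genotype_panel(100, 8, [1] * 8, maf=0.4, seed=3)
        kept = greedy_ld_prune(list(panel.columns), panel, r2_max=0.3, seed=0)
        assert kept == list(panel.columns)

    @pytest.mark.parametrize("seed", range(10))
    def test_postcondition_max_pairwise_r2(self, seed):
        """Every pruned set satisfies the pairwise r2 bound, any scan order."""
        panel = simulate_genotype_panel(80, 40, [8] * 5, maf=0.3,
                                        copy_prob=0.92, seed=1)
        kept = greedy_ld_prune(list(panel.columns), panel, r2_max=0.3, seed=seed)
        mat = panel[kept].to_numpy(float)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                r2 = ld_r2(mat[:, i], mat[:, j])
                if np.isfinite(r2):
                    assert r2 < 0.3

    def test_missing_snp_rejected(self):
        panel = simulate_genotype_panel(20, 4, [4], seed=0)
        with pytest.raises(DataError):
            greedy_ld_prune(["snp00001", "ghost"], panel)


class TestProxyMatch:
    def test_identity_and_proxy_and_miss(self):
        panel = simulate_genotype_panel(100, 6, [3, 3], maf=0.4, copy_prob=0.97,
                                        seed=2)
        catalog = ["snp00001", "snp00004"]
        out = proxy_match(["snp00001", "snp00002", "snp00006"], catalog, panel)
        by_q = out.set_index("query")
        assert by_q.loc["snp00001", "matched"] and \
            by_q.loc["snp00001", "reason"] == "identical"
        # snp2 is in snp1's block: high r2 proxy to catalog snp00001
        assert by_q.loc["snp00002", "matched"]
        assert by_q.loc["snp00002", "r2"] > 0.8

    def test_absent_snp_reported(self):
        panel = simulate_genotype_panel(50, 4, [4], seed=1)
        out = proxy_match(["ghost"], ["snp00001"], panel)
        assert not out.iloc[0]["matched"]
        assert out.iloc[0]["reason"] == "query_not_in_panel"

    def test_low_ld_no_match(self):
        panel = simulate_genotype_panel(200, 4, [1] * 4, maf=0.4, seed=7)
        out = proxy_match(["snp00002"], ["snp00003"], panel, r2_min=0.8)
        assert not out.iloc[0]["matched"]


class TestEnrichment:
    def test_equal_proportions_zero(self):
        chi2, p = enrichment_test(10, 100, 10, 100)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_value(self):
        chi2, _ = enrichment_test(90, 100, 10, 100)
        assert chi2 == pytest.approx(128.0)

    def test_zero_margin_missing(self):
        chi2, p = enrichment_test(0, 0, 0, 10)
        assert np.isnan(chi2) and np.isnan(p)

    def test_matches_closed_form_on_random_tables(self):
        """Pearson 2x2 chi-square: n(ad-bc)^2 / row/col products."""
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 80, 4)
            chi2, _ = enrichment_test(a, a + b, c, c + d)
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(closed)

    def test_invalid_counts_rejected(self):
        with pytest.raises(DataError):
            enrichment_test(5, 3, 0, 10)


class TestGeneContext:
    GENES = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [1000, 5000, 100],
        "end": [2000, 6000, 200],
        "gene": ["g1", "g2", "g3"],
        "feature": ["intron", "exon", "exon"],
    })

    def _annotate(self, pos, chrom="chr1"):
        snps = pd.DataFrame({"snp_id": ["x"], "chrom": [chrom], "pos": [pos]})
        return annotate_gene_context(snps, self.GENES).iloc[0]

    def test_inside_intron_is_genic(self):
        row = self._annotate(1500)
        assert row["context"] == "genic" and row["distance"] == 0

    def test_inclusive_end_boundary(self):
        assert self._annotate(2000)["context"] == "genic"
        assert self._annotate(2001)["context"] == "non_genic"

    def test_distance_to_nearest_gene(self):
        row = self._annotate(131000)
        assert row["context"] == "non_genic"
        assert row["distance"] == 131000 - 6000
        assert row["nearest_gene"] == "g2"

    def test_empty_gene_set_warns_infinite(self):
        snps = pd.DataFrame({"snp_id": ["x"], "chrom": ["chr1"], "pos": [5]})
        with pytest.warns(UserWarning):
            out = annotate_gene_context(snps, self.GENES.iloc[0:0])
        assert np.isinf(out.iloc[0]["distance"])


class TestPermutationEqtl:
    def test_perfect_association_is_significant(self):
        panel = simulate_genotype_panel(40, 5, [1] * 5, maf=0.4, seed=8)
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            {"g": panel["snp00003"] * 2.0 + rng.normal(0, 0.01, 40)},
            index=panel.index)
        genes, snps = permutation_eqtl_test(
            panel, expr, panel.attrs["positions"], pd.Series({"g": 5000}),
            n_perm=500, cis_window=100_000, seed=1)
        assert genes.iloc[0]["significant"]
        assert genes.iloc[0]["empirical_p"] <= 2 / 501
        assert snps.set_index("snp_id").loc["snp00003", "significant"]

    def test_null_calibration_about_five_percent(self):
        panel = simulate_genotype_panel(50, 10, [1] * 10, maf=0.4, seed=9)
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(0, 1, (50, 40)),
                            columns=[f"g{i}" for i in range(40)],
                            index=panel.index)
        tss = pd.Series({f"g{i}": 10_000 for i in range(40)})
        genes, _ = permutation_eqtl_test(panel, expr, panel.attrs["positions"],
                                         tss, n_perm=400, cis_window=100_000,
                                         seed=2)
        rate = genes["significant"].mean()
        assert rate <= 0.2  # 5% expectation, loose bound at 40 genes

    def test_single_snp_threshold_is_own_null_quantile(self):
        panel = simulate_genotype_panel(30, 1, [1], maf=0.4, seed=10)
        rng = np.random.default_rng(3)
        expr = pd.DataFrame({"g": rng.normal(0, 1, 30)}, index=panel.index)
        genes, _ = permutation_eqtl_test(panel, expr, panel.attrs["positions"],
                                         pd.Series({"g": 2000}), n_perm=300,
                                         cis_window=10_000, seed=4)
        # with one cis SNP the min-p null is that SNP's own permuted p's
        assert 0 < genes.iloc[0]["threshold"] < 0.2

    def test_constant_expression_skipped(self):
        panel = simulate_genotype_panel(25, 2, [2], maf=0.4, seed=11)
        expr = pd.DataFrame({"g": np.ones(25)}, index=panel.index)
        genes, snps = permutation_eqtl_test(panel, expr,
                                            panel.attrs["positions"],
                                            pd.Series({"g": 2000}),
                                            n_perm=50, seed=5)
        assert genes.empty and snps.empty


class TestCatalogAndMafMatching:
    def test_catalog_filter_keeps_stringent_entries(self):
        from asmscan.ld import filter_gwas_catalog

        cat = pd.DataFrame({
            "snp_id": ["a", "b", "c", "d"],
            "p_value": [1e-9, 1e-5, 5e-8, 1e-12],
            "sample_size": [1000, 2000, 400, np.nan],
        })
        out = filter_gwas_catalog(cat)
        assert list(out["snp_id"]) == ["a"]
        with pytest.raises(DataError):
            filter_gwas_catalog(cat.drop(columns=["p_value"]))

    def test_maf_matched_background_mirrors_bins(self):
        from asmscan.ld import maf_matched_background

        rng = np.random.default_rng(0)
        cand = pd.Series(rng.uniform(0.01, 0.5, 60),
                         index=[f"c{i}" for i in range(60)])
        bg = pd.Series(rng.uniform(0.01, 0.5, 600),
                       index=[f"b{i}" for i in range(600)])
        chosen = maf_matched_background(cand, bg, n_bins=10, seed=1)
        assert len(chosen) == 60
        edges = np.linspace(0, 0.5, 11)
        cand_hist = np.histogram(cand, edges)[0]
        chosen_hist = np.histogram(bg[chosen], edges)[0]
        assert np.array_equal(cand_hist, chosen_hist)

    def test_underpopulated_bin_warns(self):
        from asmscan.ld import maf_matched_background

        cand = pd.Series([0.05, 0.06, 0.07], index=["c1", "c2", "c3"])
        bg = pd.Series([0.05], index=["b1"])
        with pytest.warns(UserWarning, match="background"):
            chosen = maf_matched_background(cand, bg, n_bins=10, seed=0)
        assert chosen == ["b1"]
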