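"""Bisulfite confirmation: QC, genotyping, HWE, per-CpG association."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from asmscan.bisulfite import (
    bonferroni_adjust,
    confirm_pipeline,
    conversion_rate,
    cpg_association,
    direction_consistency,
    genotype_from_reads,
    hwe_exact_test,
    maf_relative_mean_difference,
    qc_filter,
)
from asmscan.errors import DataError


def hwe_p_by_slot_enumeration(n_rr: int, n_het: int, n_aa: int) -> float:
    """Independent oracle: enumerate placements of minor alleles into the
    2n ordered allele slots, pair consecutive slots into individuals, and
    tabulate the heterozygote-count distribution. Exponential cost; only
    usable for small n."""
    n = n_rr + n_het + n_aa
    n_minor = min(2 * n_rr + n_het, 2 * n_aa + n_het)
    if n_minor == 0:
        return 1.0
    slots = 2 * n
    dist = {}
    for placement in itertools.combinations(range(slots), n_minor):
        alleles = [0] * slots
        for i in placement:
            alleles[i] = 1
        het = sum(alleles[2 * i] != alleles[2 * i + 1] for i in range(n))
        dist[het] = dist.get(het, 0) + 1
    total = sum(dist.values())
    obs = dist[n_het] / total
    return sum(v / total for v in dist.values() if v / total <= obs * (1 + 1e-12))


def hwe_p_by_recurrence(n_rr: int, n_het: int, n_aa: int) -> float:
    """Second oracle: Levene weights built by the heterozygote-count
    recurrence w(h+2)/w(h) = 4 nAA(h) nBB(h) / ((h+2)(h+1))."""
    n = n_rr + n_het + n_aa
    n_minor = min(2 * n_rr + n_het, 2 * n_aa + n_het)
    if n_minor == 0:
        return 1.0
    h = n_minor % 2
    weights = {h: 1.0}
    while True:
        n_minor_hom = (n_minor - h) // 2
        n_major_hom = n - h - n_minor_hom
        if h + 2 > n_minor or n_major_hom <= 0:
            break
        weights[h + 2] = weights[h] * 4 * n_minor_hom * n_major_hom \
            / ((h + 2) * (h + 1))
        h += 2
    total = sum(weights.values())
    obs = weights[n_het] / total
    return sum(w / total for w in weights.values()
               if w / total <= obs * (1 + 1e-12))


class TestConversionRate:
    def _records(self, conv, tot, sample="s1", amp="a1"):
        return pd.DataFrame([{"sample_id": sample, "amplicon_id": amp,
                              "read_id": "r", "allele": "ref",
                              "cpg_states": "M", "noncpg_converted": conv,
                              "noncpg_total": tot}])

    def test_simple_rate(self):
        out = conversion_rate(self._records(99, 100))
        assert out.iloc[0]["mean_rate"] == pytest.approx(0.99)
        assert out.iloc[0]["passed"]

    def test_failing_sample(self):
        out = conversion_rate(self._records(94, 100))
        assert not out.iloc[0]["passed"]

    def test_unevaluable_sample_flagged(self):
        out = conversion_rate(self._records(0, 0))
        assert not out.iloc[0]["evaluable"]

    def test_overcount_rejected(self):
        with pytest.raises(DataError):
            conversion_rate(self._records(5, 3))


class TestGenotyping:
    def test_balanced_reads_call_het_with_confidence(self):
        gt, gq = genotype_from_reads(50, 50)
        assert gt == "het" and gq >= 20

    def test_unanimous_reads_call_homozygote(self):
        assert genotype_from_reads(100, 0)[0] == "ref_hom"
        assert genotype_from_reads(0, 100)[0] == "alt_hom"

    def test_zero_depth_nocall(self):
        assert genotype_from_reads(0, 0)[0] == "nocall"

    def test_low_depth_still_called(self):
        gt, gq = genotype_from_reads(8, 7)
        assert gt == "het"


class TestHweExact:
    def test_hand_value(self):
        # two individuals, two minor alleles: P(0 het)=1/3, P(2 het)=2/3
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_allele_label_symmetry(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_test(a, b, c) == pytest.approx(hwe_exact_test(c, b, a))

    def test_matches_slot_enumeration_for_small_n(self):
        for n in range(1, 7):
            for n_het in range(n + 1):
                for n_rr in range(n - n_het + 1):
                    n_aa = n - n_het - n_rr
                    assert hwe_exact_test(n_rr, n_het, n_aa) == pytest.approx(
                        hwe_p_by_slot_enumeration(n_rr, n_het, n_aa)), \
                        (n_rr, n_het, n_aa)

    def test_matches_recurrence_oracle_up_to_12_individuals(self):
        for n in range(1, 13):
            for n_het in range(n + 1):
                for n_rr in range(n - n_het + 1):
                    n_aa = n - n_het - n_rr
                    assert hwe_exact_test(n_rr, n_het, n_aa) == pytest.approx(
                        hwe_p_by_recurrence(n_rr, n_het, n_aa)), \
                        (n_rr, n_het, n_aa)

    def test_excess_heterozygosity_detected(self):
        assert hwe_exact_test(0, 40, 0) < 1e-6


class TestMafRmd:
    @pytest.mark.parametrize("obs,exp,value", [
        (0.25, 0.25, 0.0),
        (0.20, 0.25, 0.05 / 0.225),
        (0.10, 0.30, 1.0),
    ])
    def test_values(self, obs, exp, value):
        assert maf_relative_mean_difference(obs, exp) == pytest.approx(value)

    def test_both_zero_undefined(self):
        with pytest.raises(DataError):
            maf_relative_mean_difference(0.0, 0.0)


def _qc_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "amplicon_id", "depth",
                                       "genotype", "genotype_quality"])


class TestQcFilter:
    def test_amplicon_failing_majority_dropped(self):
        rows = []
        for s in range(10):
            rows.append((f"s{s}", "bad", 5 if s < 6 else 100, "het", 99))
            rows.append((f"s{s}", "good", 100, "het" if s % 2 else "ref_hom", 99))
        result = qc_filter(_qc_table(rows), hwe_alpha=1e-9)
        assert result.dropped_amplicons.get("bad") == "majority_depth_gq"
        assert "good" in result.kept_amplicons

    def test_hwe_deviant_amplicon_dropped(self):
        rows = [(f"s{s}", "hwe_bad", 100, "het", 99) for s in range(40)]
        rows += [(f"s{s}", "ok", 100,
                  ["ref_hom", "het", "het", "alt_hom"][s % 4], 99)
                 for s in range(40)]
        result = qc_filter(_qc_table(rows))
        assert result.dropped_amplicons.get("hwe_bad") == "hwe"
        assert "ok" in result.kept_amplicons

    def test_maf_deviation_dropped(self):
        rows = [(f"s{s}", "amp", 100, "ref_hom" if s < 39 else "het", 99)
                for s in range(40)]
        expected = pd.Series({"amp": 0.45})  # observed maf ~0.0125, rmd >> 0.25
        result = qc_filter(_qc_table(rows), expected_maf=expected)
        assert result.dropped_amplicons.get("amp") == "maf_rmd"

    def test_all_pass_identity(self):
        rows = [(f"s{s}", a, 100, ["ref_hom", "het", "alt_hom", "het"][s % 4], 99)
                for s in range(20) for a in ("a1", "a2")]
        result = qc_filter(_qc_table(rows))
        assert result.kept_amplicons == ["a1", "a2"]
        assert len(result.kept_samples) == 20


class TestCpgAssociation:
    def _reads(self, m_ref, u_ref, m_alt, u_alt, amp="a", sample="s1"):
        rows = []
        for state, allele, n in (("M", "ref", m_ref), ("U", "ref", u_ref),
                                 ("M", "alt", m_alt), ("U", "alt", u_alt)):
            for i in range(n):
                rows.append({"sample_id": sample, "amplicon_id": amp,
                             "read_id": f"{allele}{state}{i}", "allele": allele,
                             "cpg_states": state, "noncpg_converted": 10,
                             "noncpg_total": 10})
        return pd.DataFrame(rows)

    GENO = pd.DataFrame([{"sample_id": "s1", "amplicon_id": "a",
                          "genotype": "het"}])

    def test_hand_value_128(self):
        out = cpg_association(self._reads(90, 10, 10, 90), self.GENO, "a", 0)
        assert out.iloc[0]["chi2"] == pytest.approx(128.0)
        assert out.iloc[0]["methylated_allele"] == "REF"

    def test_equal_proportions_null(self):
        out = cpg_association(self._reads(40, 40, 40, 40), self.GENO, "a", 0)
        assert out.iloc[0]["chi2"] == pytest.approx(0.0)
        assert out.iloc[0]["p_raw"] == pytest.approx(1.0)

    def test_zero_margin_gives_missing_p(self):
        out = cpg_association(self._reads(50, 0, 50, 0), self.GENO, "a", 0)
        assert np.isnan(out.iloc[0]["p_raw"])

    def test_label_swap_preserves_chi2_flips_direction(self):
        a = cpg_association(self._reads(80, 20, 30, 70), self.GENO, "a", 0).iloc[0]
        b = cpg_association(self._reads(30, 70, 80, 20), self.GENO, "a", 0).iloc[0]
        assert a["chi2"] == pytest.approx(b["chi2"])
        assert {a["methylated_allele"], b["methylated_allele"]} == {"REF", "ALT"}

    def test_homozygote_reads_excluded(self):
        geno = pd.DataFrame([{"sample_id": "s1", "amplicon_id": "a",
                              "genotype": "ref_hom"}])
        out = cpg_association(self._reads(90, 10, 10, 90), geno, "a", 0)
        assert out.iloc[0][["m_ref", "u_ref", "m_alt", "u_alt"]].sum() == 0

    def test_per_sample_scope(self):
        reads = pd.concat([self._reads(30, 5, 5, 30, sample="s1"),
                           self._reads(20, 5, 5, 20, sample="s2")])
        geno = pd.DataFrame([{"sample_id": s, "amplicon_id": "a",
                              "genotype": "het"} for s in ("s1", "s2")])
        out = cpg_association(reads, geno, "a", 0, scope="per_sample")
        assert set(out["sample_id"]) == {"s1", "s2"}
        assert (out["p_raw"] < 0.01).all()

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(1, 60, 4))
            out = cpg_association(self._reads(a, b, c, d), self.GENO, "a", 0)
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d))
            assert out.iloc[0]["chi2"] == pytest.approx(closed)


class TestBonferroniAndDirection:
    @pytest.mark.parametrize("p,m,expected", [
        (0.001, 38, 0.038), (1.0, 10, 10.0), (0.5, 1, 0.5)])
    def test_uncapped_adjustment(self, p, m, expected):
        assert bonferroni_adjust(p, m) == pytest.approx(expected)

    def test_bad_m_rejected(self):
        with pytest.raises(DataError):
            bonferroni_adjust(0.5, 0)

    @pytest.mark.parametrize("seq,array_allele,mapping,expected", [
        ("REF", "A", "ref", "yes"),
        ("ALT", "A", "ref", "no"),
        ("ALT", "B", "ref", "yes"),
        ("REF", None, "ref", "not_applicable"),
        ("REF", "A", None, "not_applicable"),
    ])
    def test_direction_consistency(self, seq, array_allele, mapping, expected):
        assert direction_consistency(seq, array_allele, mapping) == expected


class TestConfirmPipeline:
    def test_differential_amplicon_detected_null_not(self, bs_sim_small):
        res = confirm_pipeline(bs_sim_small.reads, bs_sim_small.cpg_meta,
                               amplicon_meta=bs_sim_small.amplicon_meta)
        assoc = res["association"]
        assert res["status"] == "ok"
        diff = assoc[assoc["amplicon_id"] == "ampDiff"]
        null = assoc[assoc["amplicon_id"] == "ampNull"]
        assert (diff["p_bonferroni"] < 0.05).all()
        assert (diff["methylated_allele"] == "REF").all()
        assert not (null["p_bonferroni"] < 0.05).any()

    def test_array_consistency_flags(self, bs_sim_small):
        array_calls = pd.DataFrame({"amplicon_id": ["ampDiff", "ampNull"],
                                    "cis_allele": ["A", ""]})
        res = confirm_pipeline(bs_sim_small.reads, bs_sim_small.cpg_meta,
                               amplicon_meta=bs_sim_small.amplicon_meta,
                               array_calls=array_calls)
        assoc = res["association"]
        diff = assoc[assoc["amplicon_id"] == "ampDiff"]
        # array A allele is the ref allele and sequencing says REF methylated
        assert (diff["array_consistent"] == "yes").all()
        null = assoc[assoc["amplicon_id"] == "ampNull"]
        assert (null["array_consistent"] == "not_applicable").all()

    def test_failed_conversion_sample_removed(self, bs_sim_small):
        reads = bs_sim_small.reads.copy()
        bad = reads["sample_id"] == "B001"
        reads.loc[bad, "noncpg_converted"] = (
            0.5 * reads.loc[bad, "noncpg_total"]).astype(int)
        res = confirm_pipeline(reads, bs_sim_small.cpg_meta)
        conv = res["conversion"].set_index("sample_id")
        assert not conv.loc["B001", "passed"]
        assert "B001" not in set(res["genotypes"]["sample_id"])
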