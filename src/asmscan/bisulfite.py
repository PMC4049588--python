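"""Allele-resolved bisulfite confirmation: QC, genotyping, per-CpG tests.

Reads that observe both the target SNP allele and CpG methylation states
on the same molecule allow a direct 2x2 test of allele x methylation at
each CpG. The stage mirrors a resequencing confirmation workflow:
per-sample bisulfite conversion QC on non-CpG cytosines, a binomial
maximum-likelihood genotype caller with phred-scaled quality, sample and
amplicon filters on depth/genotype quality majorities, an exact
Hardy-Weinberg test (Levene conditional distribution of heterozygote
counts), a minor-allele-frequency sanity check, pooled and per-sample
chi-square association at each CpG, uncapped Bonferroni adjustment, and a
consistency check of the methylated allele against the array-stage call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "conversion_rate",
    "genotype_from_reads",
    "hwe_exact_test",
    "maf_relative_mean_difference",
    "qc_filter",
    "cpg_association",
    "bonferroni_adjust",
    "direction_consistency",
    "confirm_pipeline",
]


# ---------------------------------------------------------------------------
# conversion QC

def conversion_rate(records: pd.DataFrame, min_rate: float = 0.95) -> pd.DataFrame:
    """Per-sample non-CpG conversion rates with pass/fail at `min_rate`.

    The per-amplicon rate is total converted over total non-CpG cytosines;
    the sample statistic is the mean over its amplicons. Samples with no
    evaluable non-CpG cytosines are flagged unevaluable.
    """
    if (records["noncpg_converted"] > records["noncpg_total"]).any():
        raise DataError("noncpg_converted exceeds noncpg_total")
    per_amp = (records.groupby(["sample_id", "amplicon_id"])
               .agg(conv=("noncpg_converted", "sum"), tot=("noncpg_total", "sum"))
               .reset_index())
    with np.errstate(invalid="ignore"):
        per_amp["rate"] = np.where(per_amp["tot"] > 0,
                                   per_amp["conv"] / per_amp["tot"], np.nan)
    rows = []
    for sample, grp in per_amp.groupby("sample_id"):
        rates = grp["rate"].dropna()
        if rates.empty:
            rows.append({"sample_id": sample, "mean_rate": np.nan,
                         "passed": False, "evaluable": False})
        else:
            mean = float(rates.mean())
            rows.append({"sample_id": sample, "mean_rate": mean,
                         "passed": mean >= min_rate, "evaluable": True})
    out = pd.DataFrame(rows)
    out.attrs["per_amplicon"] = per_amp
    return out


# ---------------------------------------------------------------------------
# genotyping

def genotype_from_reads(n_ref: int, n_alt: int, error_rate: float = 0.01,
                        gq_cap: float = 99.0) -> tuple[str, float]:
    """ML diploid genotype from allele read counts with phred quality.

    Binomial read model with symmetric per-read error: P(alt read) is
    `error_rate` for ref_hom, 1/2 for het, 1 - error_rate for alt_hom.
    Genotype quality is -10 log10 of the posterior mass on the non-best
    genotypes under a uniform prior, capped at `gq_cap`.
    """
    depth = n_ref + n_alt
    if depth == 0:
        return "nocall", 0.0
    e = error_rate
    loglik = {
        "ref_hom": n_alt * math.log(e) + n_ref * math.log(1 - e),
        "het": depth * math.log(0.5),
        "alt_hom": n_ref * math.log(e) + n_alt * math.log(1 - e),
    }
    m = max(loglik.values())
    post = {g: math.exp(v - m) for g, v in loglik.items()}
    total = sum(post.values())
    best = max(post, key=post.get)
    p_other = 1.0 - post[best] / total
    if p_other <= 0:
        gq = gq_cap
    else:
        gq = min(-10.0 * math.log10(p_other), gq_cap)
    return best, float(gq)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Levene / Wigginton)

def _levene_log_pmf(n_het: int, n: int, n_a: int) -> float:
    """Log probability of `n_het` heterozygotes given n individuals and
    n_a copies of the minor allele (Levene conditional distribution)."""
    n_b = 2 * n - n_a
    n_aa = (n_a - n_het) // 2
    n_bb = n - n_aa - n_het
    lg = math.lgamma
    return (lg(n + 1) - lg(n_aa + 1) - lg(n_het + 1) - lg(n_bb + 1)
            + n_het * math.log(2)
            + lg(n_a + 1) + lg(n_b + 1) - lg(2 * n + 1))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg p via the Levene heterozygote distribution.

    Sums, over all heterozygote counts consistent with the observed
    allele counts, the probabilities not exceeding that of the observed
    count. Monomorphic data give p = 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise DataError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise DataError("need at least one individual")
    # minor-allele copy count; the test is symmetric in allele labels
    n_a = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_a == 0:
        return 1.0
    hets = range(n_a % 2, n_a + 1, 2)
    logs = {h: _levene_log_pmf(h, n, n_a) for h in hets}
    mx = max(logs.values())
    probs = {h: math.exp(v - mx) for h, v in logs.items()}
    z = sum(probs.values())
    obs = probs[n_het] / z
    p = sum(v / z for v in probs.values() if v / z <= obs * (1 + 1e-12))
    return float(min(p, 1.0))


def maf_relative_mean_difference(observed_maf: float, expected_maf: float) -> float:
    """|obs - exp| over their mean; used to spot genotyping artifacts."""
    if observed_maf < 0 or expected_maf < 0:
        raise DataError("allele frequencies must be non-negative")
    denom = (observed_maf + expected_maf) / 2.0
    if denom == 0:
        raise DataError("relative mean difference undefined for two zero MAFs")
    return abs(observed_maf - expected_maf) / denom


# ---------------------------------------------------------------------------
# QC filtering

@dataclass
class QCFilterResult:
    kept_samples: list
    kept_amplicons: list
    dropped_samples: dict = field(default_factory=dict)
    dropped_amplicons: dict = field(default_factory=dict)
    steps: list = field(default_factory=list)


def _majority_fail_amplicons(qc, samples, amplicons):
    sub = qc[qc["sample_id"].isin(samples) & qc["amplicon_id"].isin(amplicons)]
    frac = sub.groupby("amplicon_id")["pass_depth_gq"].mean()
    return [a for a in amplicons if a in frac.index and 1 - frac[a] > 0.5]


def _majority_fail_samples(qc, samples, amplicons):
    sub = qc[qc["sample_id"].isin(samples) & qc["amplicon_id"].isin(amplicons)]
    frac = sub.groupby("sample_id")["pass_depth_gq"].mean()
    return [s for s in samples if s in frac.index and 1 - frac[s] > 0.5]


def qc_filter(
    qc_table: pd.DataFrame,
    expected_maf: pd.Series | None = None,
    min_depth: int = 20,
    min_gq: float = 20.0,
    hwe_alpha: float = 0.01,
    maf_rmd_max: float = 0.25,
) -> QCFilterResult:
    """Drop failing amplicons and samples, then HWE/MAF-deviant amplicons.

    Step 1 drops amplicons failing depth/GQ in a majority (>50%) of
    samples; step 2 drops samples failing in a majority of the remaining
    amplicons; both steps are then repeated once (fixed order, logged).
    Step 3 recomputes genotype counts on the surviving grid and drops
    amplicons with exact Hardy-Weinberg p below `hwe_alpha` or an
    observed minor-allele frequency whose relative mean difference from
    `expected_maf` exceeds `maf_rmd_max`.
    """
    qc = qc_table.copy()
    qc["pass_depth_gq"] = (qc["depth"] >= min_depth) & (qc["genotype_quality"] >= min_gq)
    samples = sorted(qc["sample_id"].unique())
    amplicons = sorted(qc["amplicon_id"].unique())
    result = QCFilterResult(kept_samples=samples, kept_amplicons=amplicons)
    result.steps.append({"step": "input", "n_samples": len(samples),
                         "n_amplicons": len(amplicons)})

    for it in range(2):
        drop_a = _majority_fail_amplicons(qc, result.kept_samples, result.kept_amplicons)
        for a in drop_a:
            result.dropped_amplicons[a] = "majority_depth_gq"
        result.kept_amplicons = [a for a in result.kept_amplicons if a not in drop_a]
        drop_s = _majority_fail_samples(qc, result.kept_samples, result.kept_amplicons)
        for s in drop_s:
            result.dropped_samples[s] = "majority_depth_gq"
        result.kept_samples = [s for s in result.kept_samples if s not in drop_s]
        result.steps.append({"step": f"depth_gq_pass_{it + 1}",
                             "n_samples": len(result.kept_samples),
                             "n_amplicons": len(result.kept_amplicons)})

    gt_codes = {"ref_hom": 0, "het": 1, "alt_hom": 2}
    surviving = []
    for a in result.kept_amplicons:
        sub = qc[(qc["amplicon_id"] == a) & qc["sample_id"].isin(result.kept_samples)]
        counts = sub["genotype"].map(gt_codes).value_counts()
        n_rr, n_ra, n_aa = (int(counts.get(i, 0)) for i in (0, 1, 2))
        if n_rr + n_ra + n_aa == 0:
            result.dropped_amplicons[a] = "no_genotypes"
            continue
        p_hwe = hwe_exact_test(n_rr, n_ra, n_aa)
        if p_hwe < hwe_alpha:
            result.dropped_amplicons[a] = "hwe"
            continue
        if expected_maf is not None and a in expected_maf.index:
            total = 2 * (n_rr + n_ra + n_aa)
            alt_freq = (2 * n_aa + n_ra) / total
            obs_maf = min(alt_freq, 1 - alt_freq)
            try:
                rmd = maf_relative_mean_difference(obs_maf, float(expected_maf[a]))
            except DataError:
                rmd = np.inf
            if rmd > maf_rmd_max:
                result.dropped_amplicons[a] = "maf_rmd"
                continue
        surviving.append(a)
    result.kept_amplicons = surviving
    result.steps.append({"step": "hwe_maf", "n_samples": len(result.kept_samples),
                         "n_amplicons": len(result.kept_amplicons)})
    if not result.kept_amplicons or not result.kept_samples:
        result.steps.append({"step": "empty_result", "n_samples": 0, "n_amplicons": 0})
    return result


# ---------------------------------------------------------------------------
# association

def _chi2_2x2(m_ref: int, u_ref: int, m_alt: int, u_alt: int):
    table = np.array([[m_ref, u_ref], [m_alt, u_alt]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def _counts_for_cpg(records: pd.DataFrame, cpg_index: int):
    """2x2 allele x {M,U} counts from informative reads."""
    states = records["cpg_states"].str[cpg_index]
    informative = records["allele"].isin(["ref", "alt"]) & states.isin(["M", "U"])
    sub = records[informative]
    s = states[informative]
    m_ref = int(((sub["allele"] == "ref") & (s == "M")).sum())
    u_ref = int(((sub["allele"] == "ref") & (s == "U")).sum())
    m_alt = int(((sub["allele"] == "alt") & (s == "M")).sum())
    u_alt = int(((sub["allele"] == "alt") & (s == "U")).sum())
    return m_ref, u_ref, m_alt, u_alt


def _pct(m: int, u: int) -> float:
    return 100.0 * m / (m + u) if (m + u) > 0 else float("nan")


def _methylated_allele(pct_ref: float, pct_alt: float) -> str:
    # equal percentages reported as ALT: a display convention, not biology;
    # an undefined percentage (no informative reads on that allele) loses
    ref = -1.0 if np.isnan(pct_ref) else pct_ref
    alt = -1.0 if np.isnan(pct_alt) else pct_alt
    return "REF" if ref > alt else "ALT"


def cpg_association(
    records: pd.DataFrame,
    genotypes: pd.DataFrame,
    amplicon_id: str,
    cpg_index: int,
    scope: str = "pooled",
    yates: bool = False,
) -> pd.DataFrame:
    """Allele x methylation chi-square at one CpG.

    Only reads from heterozygous samples can inform an allele association;
    reads missing the allele or this CpG's state are excluded. `scope`
    ``pooled`` combines heterozygotes' reads into a single 2x2 test;
    ``per_sample`` tests each heterozygous sample. A zero row or column
    margin leaves the statistic undefined (NaN p, as published tables
    show NA).
    """
    if scope not in {"pooled", "per_sample"}:
        raise DataError(f"unknown scope: {scope}")
    het_samples = set(
        genotypes.loc[(genotypes["amplicon_id"] == amplicon_id)
                      & (genotypes["genotype"] == "het"), "sample_id"])
    recs = records[(records["amplicon_id"] == amplicon_id)
                   & records["sample_id"].isin(het_samples)]

    def one(sub: pd.DataFrame, sample_id: str) -> dict:
        m_ref, u_ref, m_alt, u_alt = _counts_for_cpg(sub, cpg_index)
        if yates:
            table = np.array([[m_ref, u_ref], [m_alt, u_alt]], dtype=float)
            if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
                chi2, p = float("nan"), float("nan")
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        else:
            chi2, p = _chi2_2x2(m_ref, u_ref, m_alt, u_alt)
        pct_ref, pct_alt = _pct(m_ref, u_ref), _pct(m_alt, u_alt)
        return {"amplicon_id": amplicon_id, "cpg_index": cpg_index,
                "sample_id": sample_id, "m_ref": m_ref, "u_ref": u_ref,
                "m_alt": m_alt, "u_alt": u_alt, "chi2": chi2, "p_raw": p,
                "pct_meth_ref": pct_ref, "pct_meth_alt": pct_alt,
                "methylated_allele": _methylated_allele(pct_ref, pct_alt)}

    if scope == "pooled":
        return pd.DataFrame([one(recs, "pooled")])
    rows = [one(grp, sid) for sid, grp in recs.groupby("sample_id")]
    return pd.DataFrame(rows)


def bonferroni_adjust(p_raw: float, m_tests: int) -> float:
    """Uncapped Bonferroni: raw p times the number of tests.

    Deliberately not truncated at 1 so adjusted values remain comparable
    across tables that print values above 1.
    """
    if m_tests < 1:
        raise DataError("m_tests must be >= 1")
    return p_raw * m_tests


def direction_consistency(methylated_allele: str, array_cis_allele: str | None,
                          array_a_is: str | None) -> str:
    """Compare the sequencing methylated allele with the array call.

    `array_cis_allele` is "A" or "B" from the population classification
    (None when the amplicon had no array ASM call); `array_a_is` maps the
    array A allele onto "ref" or "alt". Returns yes / no / not_applicable.
    """
    if not array_cis_allele or not array_a_is:
        if array_cis_allele and not array_a_is:
            warnings.warn("missing allele mapping: consistency not applicable")
        return "not_applicable"
    if array_a_is not in {"ref", "alt"}:
        raise DataError(f"array_a_is must be 'ref' or 'alt', got {array_a_is}")
    array_meth = array_a_is if array_cis_allele == "A" else (
        "alt" if array_a_is == "ref" else "ref")
    seq_meth = methylated_allele.lower()
    return "yes" if seq_meth == array_meth else "no"


# ---------------------------------------------------------------------------
# pipeline

def confirm_pipeline(
    reads: pd.DataFrame,
    cpg_meta: pd.DataFrame,
    amplicon_meta: pd.DataFrame | None = None,
    array_calls: pd.DataFrame | None = None,
    expected_maf: pd.Series | None = None,
    min_conversion: float = 0.95,
    min_depth: int = 20,
    min_gq: float = 20.0,
    hwe_alpha: float = 0.01,
    maf_rmd_max: float = 0.25,
    error_rate: float = 0.01,
    m_tests: int | None = None,
    yates: bool = False,
) -> dict:
    """Full confirmation pass: QC, genotyping, association, adjustment.

    Returns a dict with `conversion`, `genotypes`, `qc`, and the per-CpG
    `association` table (Bonferroni-adjusted over `m_tests`, defaulting
    to the number of CpG tests performed).
    """
    conv = conversion_rate(reads, min_rate=min_conversion)
    good_samples = set(conv.loc[conv["passed"], "sample_id"])
    kept = reads[reads["sample_id"].isin(good_samples)]

    # genotype each sample x amplicon from allele read counts
    geno_rows = []
    for (sid, amp), grp in kept.groupby(["sample_id", "amplicon_id"]):
        n_ref = int((grp["allele"] == "ref").sum())
        n_alt = int((grp["allele"] == "alt").sum())
        gt, gq = genotype_from_reads(n_ref, n_alt, error_rate=error_rate)
        geno_rows.append({"sample_id": sid, "amplicon_id": amp,
                          "depth": n_ref + n_alt, "genotype": gt,
                          "genotype_quality": gq})
    genotypes = pd.DataFrame(geno_rows)
    if genotypes.empty:
        return {"conversion": conv, "genotypes": genotypes, "qc": None,
                "association": pd.DataFrame(), "status": "empty"}

    qc = qc_filter(genotypes, expected_maf=expected_maf, min_depth=min_depth,
                   min_gq=min_gq, hwe_alpha=hwe_alpha, maf_rmd_max=maf_rmd_max)
    kept = kept[kept["sample_id"].isin(qc.kept_samples)
                & kept["amplicon_id"].isin(qc.kept_amplicons)]

    assoc_rows = []
    for amp in qc.kept_amplicons:
        for cpg in cpg_meta[cpg_meta["amplicon_id"] == amp].itertuples(index=False):
            row = cpg_association(kept, genotypes, amp, cpg.cpg_index,
                                  scope="pooled", yates=yates).iloc[0].to_dict()
            row["chrom"] = cpg.chrom
            row["pos"] = cpg.pos
            row["is_msre"] = cpg.is_msre
            assoc_rows.append(row)
    assoc = pd.DataFrame(assoc_rows)
    if not assoc.empty:
        m = m_tests if m_tests is not None else int(assoc["p_raw"].notna().sum())
        m = max(m, 1)
        assoc["p_bonferroni"] = assoc["p_raw"] * m
        assoc["m_tests"] = m
        if amplicon_meta is not None and array_calls is not None:
            a_map = amplicon_meta.set_index("amplicon_id")["array_a_allele"]
            cis = array_calls.set_index("amplicon_id")["cis_allele"] \
                if "amplicon_id" in array_calls.columns else array_calls
            flags = []
            for r in assoc.itertuples(index=False):
                allele_map = a_map.get(r.amplicon_id, "") or None
                cis_allele = cis.get(r.amplicon_id, "") or None
                flags.append(direction_consistency(r.methylated_allele,
                                                   cis_allele, allele_map))
            assoc["array_consistent"] = flags
        else:
            assoc["array_consistent"] = "not_applicable"
    return {"conversion": conv, "genotypes": genotypes, "qc": qc,
            "association": assoc, "status": "ok"}
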