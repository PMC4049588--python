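"""Pre-analysis technical filters for array amplicons.

Classifies every amplicon as MPR (assayable, has working MSRE sites),
MNR (no MSRE sites, used as an invariant/normalization set) or excluded,
and applies the reference-panel discrimination and replicate-concordance
checks that precede ASM calling.

Filter codes
------------
size_window   predicted amplicon size outside the assayable window
hhai_only     the only MSRE sites are HhaI (an enzyme whose digestion is
              unreliable on this assay, so such amplicons are dropped)
msre_snp      an MSRE-site variant with MAF above the cutoff could create
              or destroy a cut site in the study population
no_calls      reference panel produced no genotype calls
poor_discrimination   adjacent genotype clusters of panel log2(A/B) are
              separated by fewer than k pooled standard deviations
insufficient_clusters panel lacks the clusters needed to assess separation
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "AmpliconClass",
    "classify_amplicons",
    "reference_discrimination_filter",
    "replicate_concordance",
    "scan_msre_sites",
]

ENZYMES = ("AciI", "BsaHI", "HhaI", "HpaII", "HpyCH4IV")

# recognition motifs; BsaHI is degenerate (GRCGYC) and is expanded via IUPAC
_MOTIFS = {
    "AciI": ["CCGC"],
    "BsaHI": ["G[AG]CG[CT]C"],
    "HhaI": ["GCGC"],
    "HpaII": ["CCGG"],
    "HpyCH4IV": ["ACGT"],
}


@dataclass
class AmpliconClass:
    amplicon_id: str
    amplicon_class: str           # MPR | MNR | excluded
    reasons: list = field(default_factory=list)


def classify_amplicons(
    annotations: pd.DataFrame,
    size_min: int = 200,
    size_max: int = 1200,
    msre_snp_maf_max: float = 0.04,
) -> pd.DataFrame:
    """Partition amplicons into MPR / MNR / excluded with filter reasons.

    An amplicon is an MNR iff its size lies inside the window and it has
    zero MSRE sites of any kind. It is excluded if the size is outside the
    window, if its only MSRE sites are HhaI, or if any MSRE-site variant
    exceeds the MAF cutoff. Everything else is an assayable MPR.
    """
    required = {"amplicon_id", "predicted_size", "msre_snp_max_maf"} | {
        f"n_{e}" for e in ENZYMES}
    missing = required - set(annotations.columns)
    if missing:
        raise DataError(f"annotation table missing columns: {sorted(missing)}")
    if (annotations["predicted_size"] < 0).any():
        raise DataError("negative predicted_size in annotation table")

    counts = annotations[[f"n_{e}" for e in ENZYMES]].to_numpy()
    if (counts < 0).any():
        raise DataError("negative MSRE site count in annotation table")
    total_sites = counts.sum(axis=1)
    non_hhai = total_sites - annotations["n_HhaI"].to_numpy()
    size = annotations["predicted_size"].to_numpy()
    maf = annotations["msre_snp_max_maf"].to_numpy()

    size_bad = (size < size_min) | (size > size_max)
    hhai_only = (total_sites > 0) & (non_hhai == 0)
    maf_bad = maf > msre_snp_maf_max

    records = []
    for i, amp_id in enumerate(annotations["amplicon_id"]):
        reasons = []
        if size_bad[i]:
            reasons.append("size_window")
        if hhai_only[i]:
            reasons.append("hhai_only")
        if maf_bad[i]:
            reasons.append("msre_snp")
        if reasons:
            cls = "excluded"
        elif total_sites[i] == 0:
            cls = "MNR"
        else:
            cls = "MPR"
        records.append({"amplicon_id": amp_id, "amplicon_class": cls,
                        "reasons": ";".join(reasons)})
    return pd.DataFrame(records)


def reference_discrimination_filter(
    reference_panel: pd.DataFrame,
    k: float = 2.0,
    min_cluster_n: int = 2,
) -> pd.DataFrame:
    """Pass/fail each MPR on reference-panel genotype-cluster separation.

    Adjacent cluster pairs (AA vs AB, AB vs BB) must be separated by at
    least `k` pooled standard deviations. MPRs with no panel calls fail
    outright; panels lacking a heterozygote cluster (or any homozygote
    cluster) cannot be assessed and fail as `insufficient_clusters`.
    """
    needed = {"probeset_id", "n_calls"} | {
        f"{stat}_{g}" for stat in ("mean", "sd", "n") for g in ("AA", "AB", "BB")}
    missing = needed - set(reference_panel.columns)
    if missing:
        raise DataError(f"reference panel missing cluster stats: {sorted(missing)}")

    out = []
    for row in reference_panel.itertuples(index=False):
        reasons = []
        if row.n_calls == 0:
            out.append({"probeset_id": row.probeset_id, "passed": False,
                        "reasons": "no_calls"})
            continue
        clusters = {}
        for g in ("AA", "AB", "BB"):
            n = getattr(row, f"n_{g}")
            sd = getattr(row, f"sd_{g}")
            if n >= min_cluster_n and np.isfinite(sd):
                clusters[g] = (getattr(row, f"mean_{g}"), sd)
        homs = [g for g in ("AA", "BB") if g in clusters]
        if "AB" not in clusters or not homs:
            out.append({"probeset_id": row.probeset_id, "passed": False,
                        "reasons": "insufficient_clusters"})
            continue
        for g in homs:
            m1, s1 = clusters["AB"]
            m2, s2 = clusters[g]
            pooled = np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
            if pooled == 0 or abs(m1 - m2) / pooled < k:
                reasons.append("poor_discrimination")
                break
        out.append({"probeset_id": row.probeset_id, "passed": not reasons,
                    "reasons": ";".join(reasons)})
    return pd.DataFrame(out)


def replicate_concordance(
    probes: pd.DataFrame,
    n_sd: float = 2.5,
) -> pd.DataFrame:
    """Per-sample replicate-pair R-squared with cohort outlier flags.

    Regresses replicate-2 un-normalized intensities (A and B channels
    stacked) on replicate-1 per sample; pairs whose coefficient of
    determination falls below cohort mean minus `n_sd` standard deviations
    are flagged as poor hybridizations.
    """
    reps = sorted(probes["replicate"].unique())
    if len(reps) < 2:
        import warnings
        warnings.warn("single replicate: concordance check skipped")
        return pd.DataFrame(columns=["sample_id", "r2", "flagged"])

    r1, r2 = reps[0], reps[1]
    wide = probes.pivot_table(index=["probeset_id", "sample_id"],
                              columns="replicate",
                              values=["intensity_A", "intensity_B"])
    rows = []
    for sample, grp in wide.groupby(level="sample_id"):
        x = np.concatenate([grp[("intensity_A", r1)].to_numpy(),
                            grp[("intensity_B", r1)].to_numpy()])
        y = np.concatenate([grp[("intensity_A", r2)].to_numpy(),
                            grp[("intensity_B", r2)].to_numpy()])
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            r2_val = np.nan
        else:
            r2_val = float(np.corrcoef(x, y)[0, 1] ** 2)
        rows.append({"sample_id": sample, "r2": r2_val})
    result = pd.DataFrame(rows)
    vals = result["r2"].to_numpy()
    mean, sd = np.nanmean(vals), np.nanstd(vals, ddof=1)
    cutoff = mean - n_sd * sd
    result["flagged"] = result["r2"] < cutoff
    result.attrs["r2_mean"] = float(mean)
    result.attrs["r2_sd"] = float(sd)
    result.attrs["cutoff"] = float(cutoff)
    return result


def scan_msre_sites(sequence: str) -> dict:
    """Count MSRE recognition sites in a sequence (simulation helper).

    Scans the forward strand and the reverse complement; the degenerate
    BsaHI motif GRCGYC is matched by IUPAC expansion. Overlapping matches
    are counted; a site found on both strands at the same position (all
    these motifs except AciI are palindromic) is counted once.
    """
    comp = str.maketrans("ACGT", "TGCA")
    seq = sequence.upper()
    rc = seq.translate(comp)[::-1]
    lengths = {"AciI": 4, "BsaHI": 6, "HhaI": 4, "HpaII": 4, "HpyCH4IV": 4}
    counts = {}
    for enz, (pattern,) in _MOTIFS.items():
        rx = re.compile(f"(?={pattern})")
        fwd = {m.start() for m in rx.finditer(seq)}
        # map reverse-complement match starts back to forward coordinates
        rev = {len(seq) - m.start() - lengths[enz] for m in rx.finditer(rc)}
        counts[enz] = len(fwd | rev)
    return counts
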