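"""Per-sample, per-MPR ASM calling from normalized probe intensities.

The calling statistic is the Standard Score: a heterozygote's post-digest
log2(A/B) for an MPR, z-normalized against the reference panel's
heterozygote log2(A/B) distribution for the same MPR. Per-sample cutoffs
come from the sample's own MNR Standard Score distribution — its empirical
2.5th and 97.5th percentiles — so by construction 95% of a sample's MNRs
fall inside the cutoffs and a null MPR is called ASM about 5% of the time.

Biallelically unmethylated regions lose both amplicons to digestion and
their allele ratio is background noise; they are removed by the intensity
ratio filter (sample total intensity over the reference panel total) at a
default cutoff of 0.2.

Call vocabulary: not_het, filtered_low_intensity, none, ASM_A, ASM_B.
ASM_A means the A allele carries the methylation (its amplicon was
protected, so log2(A/B) rises above the panel heterozygote center).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "SampleThresholds",
    "log_ratio",
    "standard_score",
    "intensity_ratio",
    "mnr_thresholds",
    "call_asm",
    "call_asm_table",
    "build_reference_distribution",
]

INTENSITY_EPS = 1e-6


@dataclass
class SampleThresholds:
    """Per-sample MNR Standard Score percentile cutoffs (open interval)."""

    sample_id: str
    mnr_lo: float
    mnr_hi: float
    n_scores: int = 0

    def __post_init__(self):
        if not self.mnr_lo < self.mnr_hi:
            raise DataError(
                f"degenerate thresholds for {self.sample_id}: "
                f"lo {self.mnr_lo} !< hi {self.mnr_hi}")


def log_ratio(intensity_a: float, intensity_b: float) -> float:
    """log2 of the A/B intensity ratio."""
    if intensity_a <= 0 or intensity_b <= 0:
        raise DataError("intensities must be positive for log2(A/B)")
    return float(np.log2(intensity_a / intensity_b))


def standard_score(log_ratio_value: float, het_mean: float, het_sd: float) -> float:
    """z-score of a log2(A/B) value against the panel heterozygote distribution."""
    if not het_sd > 0:
        raise DataError(f"het_sd must be > 0, got {het_sd}")
    return (log_ratio_value - het_mean) / het_sd


def intensity_ratio(sample_total: float, ref_total_intensity: float) -> float:
    """Sample total (A+B) intensity over the reference-panel total."""
    if not ref_total_intensity > 0:
        raise DataError(f"ref_total_intensity must be > 0, got {ref_total_intensity}")
    return sample_total / ref_total_intensity


def mnr_thresholds(scores, sample_id: str = "", pct_lo: float = 2.5,
                   pct_hi: float = 97.5) -> SampleThresholds:
    """Empirical percentile cutoffs from a sample's MNR Standard Scores.

    Percentiles use linear interpolation between closest order statistics
    (numpy's default, the "type 7" convention).
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if scores.size < 2:
        raise DataError(f"need >= 2 MNR scores to set thresholds ({sample_id})")
    if scores.size < 40:
        warnings.warn(
            f"only {scores.size} MNR scores for {sample_id}: percentiles unstable")
    lo, hi = np.percentile(scores, [pct_lo, pct_hi])
    if lo == hi:
        raise DataError(f"degenerate MNR score distribution for {sample_id}")
    return SampleThresholds(sample_id=sample_id, mnr_lo=float(lo), mnr_hi=float(hi),
                            n_scores=int(scores.size))


def call_asm(z: float, thresholds: SampleThresholds, ratio: float,
             genotype: str, ratio_min: float = 0.2) -> str:
    """One ASM call. Thresholds are open intervals (strict inequalities)."""
    if genotype is None or (isinstance(genotype, float) and np.isnan(genotype)):
        warnings.warn("missing genotype treated as not_het")
        return "not_het"
    if genotype != "AB":
        return "not_het"
    if ratio < ratio_min:
        return "filtered_low_intensity"
    if z > thresholds.mnr_hi:
        return "ASM_A"
    if z < thresholds.mnr_lo:
        return "ASM_B"
    return "none"


def build_reference_distribution(probes: pd.DataFrame,
                                 genotypes: pd.DataFrame) -> pd.DataFrame:
    """Summarize reference-panel arrays into per-probeset distributions.

    For each probeset: per-genotype-cluster count/mean/sd of log2(A/B),
    the heterozygote mean/sd (the standard-scoring target), the mean
    heterozygote total (A+B) intensity, and the panel call count. Uses
    normalized intensities when present, so panel statistics live on the
    same scale as the study arrays they calibrate.
    """
    col_a = "normalized_A" if "normalized_A" in probes.columns else "intensity_A"
    col_b = "normalized_B" if "normalized_B" in probes.columns else "intensity_B"
    df = probes[["probeset_id", "sample_id", col_a, col_b]].copy()
    a = np.maximum(df[col_a].to_numpy(dtype=float), INTENSITY_EPS)
    b = np.maximum(df[col_b].to_numpy(dtype=float), INTENSITY_EPS)
    df["logr"] = np.log2(a / b)
    df["total"] = a + b
    geno = genotypes.set_index(["probeset_id", "sample_id"])["genotype"]
    df = df.join(geno, on=["probeset_id", "sample_id"])

    out = {"probeset_id": []}
    stats_cols = {f"{s}_{g}": [] for g in ("AA", "AB", "BB")
                  for s in ("n", "mean", "sd")}
    extra = {"het_mean": [], "het_sd": [], "ref_total_intensity": [], "n_calls": []}
    for ps, grp in df.groupby("probeset_id", sort=True):
        out["probeset_id"].append(ps)
        for g in ("AA", "AB", "BB"):
            sel = grp[grp["genotype"] == g]
            stats_cols[f"n_{g}"].append(len(sel))
            stats_cols[f"mean_{g}"].append(sel["logr"].mean() if len(sel) else np.nan)
            stats_cols[f"sd_{g}"].append(sel["logr"].std(ddof=1) if len(sel) > 1 else np.nan)
        het = grp[grp["genotype"] == "AB"]
        extra["het_mean"].append(het["logr"].mean() if len(het) else np.nan)
        extra["het_sd"].append(het["logr"].std(ddof=1) if len(het) > 1 else np.nan)
        extra["ref_total_intensity"].append(het["total"].mean() if len(het) else np.nan)
        extra["n_calls"].append(int(grp["genotype"].notna().sum()))
    return pd.DataFrame({**out, **stats_cols, **extra})


def _per_unit_scores(probes: pd.DataFrame, reference: pd.DataFrame,
                     replicate_rule: str):
    """Scores per (probeset, sample[, replicate]) unit with ratio attached.

    Under the `mean` rule replicate log2(A/B) values and totals are
    averaged first, giving one scoring unit per sample; under `both` /
    `either` each replicate is a unit.
    """
    col_a = "normalized_A" if "normalized_A" in probes.columns else "intensity_A"
    col_b = "normalized_B" if "normalized_B" in probes.columns else "intensity_B"
    df = probes[["probeset_id", "sample_id", "replicate", col_a, col_b]].copy()
    a = np.maximum(df[col_a].to_numpy(dtype=float), INTENSITY_EPS)
    b = np.maximum(df[col_b].to_numpy(dtype=float), INTENSITY_EPS)
    if (df[col_a] <= 0).any() or (df[col_b] <= 0).any():
        warnings.warn("non-positive intensities floored before log2(A/B)")
    df["logr"] = np.log2(a / b)
    df["total"] = a + b

    if replicate_rule == "mean":
        units = (df.groupby(["probeset_id", "sample_id"], sort=True, as_index=False)
                 .agg(logr=("logr", "mean"), total=("total", "mean")))
    else:
        units = df[["probeset_id", "sample_id", "replicate", "logr", "total"]]

    ref = reference.set_index("probeset_id")
    units = units.merge(
        ref[["het_mean", "het_sd", "ref_total_intensity"]],
        left_on="probeset_id", right_index=True, how="left")
    valid_sd = units["het_sd"].to_numpy() > 0
    units["z"] = np.where(valid_sd,
                          (units["logr"] - units["het_mean"]) / units["het_sd"],
                          np.nan)
    units["ratio"] = units["total"] / units["ref_total_intensity"]
    return units


def call_asm_table(
    probes: pd.DataFrame,
    reference: pd.DataFrame,
    genotypes: pd.DataFrame,
    amplicon_classes: pd.DataFrame,
    ratio_min: float = 0.2,
    pct_lo: float = 2.5,
    pct_hi: float = 97.5,
    replicate_rule: str = "mean",
) -> tuple[pd.DataFrame, dict]:
    """Vectorized calling over a whole probe table.

    Returns (calls, thresholds): one call per sample x MPR, and the
    per-sample MNR threshold objects. MPRs without a usable panel
    heterozygote sd are dropped with a warning. `replicate_rule`:

    - ``mean``   average replicate log2(A/B) and totals, score once
                 (default; keeps the 5% MNR calibration exact)
    - ``both``   call each replicate; final ASM only if all replicates
                 agree on the same side
    - ``either`` final ASM if any replicate crosses a cutoff
    """
    if replicate_rule not in {"mean", "both", "either"}:
        raise DataError(f"unknown replicate_rule: {replicate_rule}")
    cls = amplicon_classes.set_index("amplicon_id")["amplicon_class"]
    mpr_ids = set(cls[cls == "MPR"].index)
    mnr_ids = set(cls[cls == "MNR"].index)
    if not mpr_ids or not mnr_ids:
        raise DataError("need both MPR and MNR probesets to call ASM")

    units = _per_unit_scores(probes, reference, replicate_rule)
    geno = genotypes.set_index(["probeset_id", "sample_id"])["genotype"]
    units = units.join(geno, on=["probeset_id", "sample_id"])

    # thresholds from heterozygous MNR scores of each sample
    is_mnr = units["probeset_id"].isin(mnr_ids)
    mnr_scores = units[is_mnr & (units["genotype"] == "AB")]
    thresholds = {}
    for sample, grp in mnr_scores.groupby("sample_id"):
        thresholds[sample] = mnr_thresholds(grp["z"].to_numpy(), sample_id=sample,
                                            pct_lo=pct_lo, pct_hi=pct_hi)

    mpr_units = units[units["probeset_id"].isin(mpr_ids)].copy()
    dropped = mpr_units["het_sd"].isna() | (mpr_units["het_sd"] <= 0)
    if dropped.any():
        n_dropped = mpr_units.loc[dropped, "probeset_id"].nunique()
        warnings.warn(f"{n_dropped} MPRs dropped: unusable panel heterozygote sd")
        mpr_units = mpr_units[~dropped]

    lo = mpr_units["sample_id"].map(lambda s: thresholds[s].mnr_lo)
    hi = mpr_units["sample_id"].map(lambda s: thresholds[s].mnr_hi)
    z = mpr_units["z"].to_numpy()
    ratio = mpr_units["ratio"].to_numpy()
    is_het = (mpr_units["genotype"] == "AB").to_numpy()

    call = np.full(len(mpr_units), "none", dtype=object)
    call[z > hi.to_numpy()] = "ASM_A"
    call[z < lo.to_numpy()] = "ASM_B"
    call[ratio < ratio_min] = "filtered_low_intensity"
    call[~is_het] = "not_het"
    mpr_units["call"] = call

    if replicate_rule == "mean":
        calls = mpr_units
    else:
        calls = _combine_replicates(mpr_units, replicate_rule)

    calls = calls[["probeset_id", "sample_id", "genotype", "z", "ratio", "call"]]
    calls = calls.rename(columns={"probeset_id": "mpr_id"}).reset_index(drop=True)
    return calls, thresholds


def _combine_replicates(units: pd.DataFrame, rule: str) -> pd.DataFrame:
    """Collapse per-replicate calls to one call per sample x MPR."""
    def combine(grp: pd.DataFrame) -> pd.Series:
        calls = set(grp["call"])
        rep = grp.iloc[0]
        if calls == {"not_het"}:
            final = "not_het"
        elif "filtered_low_intensity" in calls:
            final = "filtered_low_intensity"
        elif rule == "both":
            final = calls.pop() if len(calls) == 1 and calls & {"ASM_A", "ASM_B"} else "none"
        else:  # either
            asm = calls & {"ASM_A", "ASM_B"}
            final = asm.pop() if len(asm) == 1 else ("none" if not asm else "none")
        return pd.Series({"genotype": rep["genotype"], "z": grp["z"].mean(),
                          "ratio": grp["ratio"].mean(), "call": final})

    out = (units.groupby(["probeset_id", "sample_id"], sort=True)
           .apply(combine, include_groups=False).reset_index())
    return out
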