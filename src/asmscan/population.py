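"""Population-level classification of ASM at each SNP.

Across heterozygous individuals, cis-regulated ASM always methylates the
same allele; stochastic (possibly imprinted) ASM methylates either. The
classifier aggregates per-sample calls per SNP, requires at least
`min_het` informative heterozygotes and `min_events` ASM events, tests
allelic choice with a two-sided exact binomial test against p = 1/2, and
labels unanimous-allele SNPs cis_regulated. Six unanimous events is the
smallest number giving p < 0.05, which is why both defaults are 6.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "exact_binomial_allelic_test",
    "min_samples_for_significance",
    "classify_snp",
    "classify_population",
    "false_positive_assessment",
]


def exact_binomial_allelic_test(n_a: int, n_b: int) -> float:
    """Two-sided exact binomial p for allelic choice under p = 1/2.

    The two-sided p is the sum of probabilities of all outcomes whose
    point probability does not exceed that of the observed outcome
    (the minimum-likelihood definition). Empty data gives p = 1.
    """
    if n_a < 0 or n_b < 0:
        raise DataError("event counts must be non-negative")
    n = n_a + n_b
    if n == 0:
        return 1.0
    return float(stats.binomtest(n_a, n, p=0.5, alternative="two-sided").pvalue)


def min_samples_for_significance(alpha: float = 0.05, n_max: int = 1000) -> int:
    """Smallest n for which n unanimous events reject random choice at alpha."""
    if not 0.0 < alpha <= 1.0:
        raise DataError(f"alpha must lie in (0, 1], got {alpha}")
    for n in range(1, n_max + 1):
        if exact_binomial_allelic_test(n, 0) < alpha:
            return n
    raise DataError(f"no n <= {n_max} reaches alpha = {alpha}")


def classify_snp(
    calls: pd.DataFrame,
    min_het: int = 6,
    min_events: int = 6,
    alpha: float = 0.05,
    cis_rule: str = "unanimous",
) -> dict:
    """Classify one SNP from its per-sample calls.

    `calls` must hold one row per sample with a `call` column. Counting:
    heterozygotes are samples whose call is none/ASM_A/ASM_B (low-intensity
    filtered samples are tracked separately and do not count toward
    n_het). Classes: insufficient (< min_het heterozygotes), no_asm,
    some_asm (1..min_events-1 events), then cis_regulated when the allelic
    choice is unanimous (or binomial-significant under cis_rule
    ``binomial``), else candidate_random.
    """
    if cis_rule not in {"unanimous", "binomial"}:
        raise DataError(f"unknown cis_rule: {cis_rule}")
    if calls["sample_id"].duplicated().any():
        raise DataError("duplicate sample ids in calls for one SNP")
    c = calls["call"]
    n_asm_a = int((c == "ASM_A").sum())
    n_asm_b = int((c == "ASM_B").sum())
    n_het = int(c.isin(["none", "ASM_A", "ASM_B"]).sum())
    n_filtered = int((c == "filtered_low_intensity").sum())
    events = n_asm_a + n_asm_b
    p = exact_binomial_allelic_test(n_asm_a, n_asm_b)

    if n_het < min_het:
        cls = "insufficient"
    elif events == 0:
        cls = "no_asm"
    elif events < min_events:
        cls = "some_asm"
    else:
        if cis_rule == "unanimous":
            is_cis = n_asm_a == 0 or n_asm_b == 0
        else:
            is_cis = p < alpha
        cls = "cis_regulated" if is_cis else "candidate_random"

    allele = ""
    if cls == "cis_regulated":
        allele = "A" if n_asm_a >= n_asm_b else "B"
    return {"n_het": n_het, "n_asm_A": n_asm_a, "n_asm_B": n_asm_b,
            "n_filtered": n_filtered, "binomial_p": p, "asm_class": cls,
            "cis_allele": allele}


def classify_population(
    calls: pd.DataFrame,
    min_het: int = 6,
    min_events: int = 6,
    alpha: float = 0.05,
    cis_rule: str = "unanimous",
) -> pd.DataFrame:
    """Apply `classify_snp` to every MPR in a calls table."""
    rows = []
    for mpr_id, grp in calls.groupby("mpr_id", sort=True):
        rec = classify_snp(grp, min_het=min_het, min_events=min_events,
                           alpha=alpha, cis_rule=cis_rule)
        rec["mpr_id"] = mpr_id
        rows.append(rec)
    out = pd.DataFrame(rows)
    cols = ["mpr_id", "n_het", "n_asm_A", "n_asm_B", "n_filtered",
            "binomial_p", "asm_class", "cis_allele"]
    return out[cols]


def false_positive_assessment(
    calls: pd.DataFrame,
    expected_rate: float = 0.05,
) -> pd.DataFrame:
    """Observed vs expected per-sample ASM counts with a chi-square GOF p.

    A sample's assessed MPRs are its heterozygous, non-filtered calls; the
    expectation is `expected_rate` of those (the MNR-percentile
    construction predicts 5%). The test is the one-cell-vs-rest chi-square
    goodness of fit on (observed ASM, observed non-ASM).
    """
    rows = []
    for sample, grp in calls.groupby("sample_id", sort=True):
        assessed = grp["call"].isin(["none", "ASM_A", "ASM_B"])
        n_assessed = int(assessed.sum())
        observed = int(grp["call"].isin(["ASM_A", "ASM_B"]).sum())
        expected = expected_rate * n_assessed
        if n_assessed == 0:
            rows.append({"sample_id": sample, "n_assessed": 0, "expected": 0.0,
                         "observed": 0, "fold": np.nan, "chi2": np.nan,
                         "p": np.nan})
            continue
        fold = observed / expected if expected > 0 else np.nan
        exp_non = n_assessed - expected
        chi2 = (observed - expected) ** 2 / expected \
            + ((n_assessed - observed) - exp_non) ** 2 / exp_non
        p = float(stats.chi2.sf(chi2, df=1))
        rows.append({"sample_id": sample, "n_assessed": n_assessed,
                     "expected": expected, "observed": observed, "fold": fold,
                     "chi2": float(chi2), "p": p})
    return pd.DataFrame(rows)
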