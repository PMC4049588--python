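"""Linkage disequilibrium, catalog overlap, genic context and eQTL testing.

r-squared here is the squared Pearson correlation of genotype dosages
(composite LD) computed over pairwise-complete observations, which needs
no phasing. Pruning is greedy over a seeded random scan order so that
repeated prunes with different seeds reproduce the "ten random LD-pruned
sets" design; every output set satisfies max pairwise r-squared below the
cutoff. The eQTL procedure is Spearman rank correlation per cis-SNP with
a per-gene permutation null built from the minimum nominal p over cis
SNPs in each of `n_perm` expression permutations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .errors import DataError

__all__ = [
    "ld_r2",
    "greedy_ld_prune",
    "proxy_match",
    "enrichment_test",
    "annotate_gene_context",
    "permutation_eqtl_test",
    "filter_gwas_catalog",
    "maf_matched_background",
]

GENIC_FEATURES = {"5UTR", "3UTR", "exon", "intron"}


def ld_r2(genotypes_x, genotypes_y) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing values (NaN or negative) are removed pairwise; a monomorphic
    subset leaves r-squared undefined (NaN).
    """
    x = np.asarray(genotypes_x, dtype=float)
    y = np.asarray(genotypes_y, dtype=float)
    if x.shape != y.shape:
        raise DataError("genotype vectors differ in length")
    ok = np.isfinite(x) & np.isfinite(y) & (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise DataError("need >= 2 complete genotype pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_against(panel: np.ndarray, j: int, others: np.ndarray) -> np.ndarray:
    """r-squared of column j against a set of columns (complete data)."""
    x = panel[:, j]
    block = panel[:, others]
    xc = x - x.mean()
    bc = block - block.mean(axis=0)
    denom = np.sqrt((xc ** 2).sum() * (bc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ bc) / denom
    return r ** 2


def greedy_ld_prune(
    snp_ids,
    panel: pd.DataFrame,
    r2_max: float = 0.3,
    window_bp: int | None = None,
    positions: pd.Series | None = None,
    seed: int = 0,
    scan_order=None,
) -> list:
    """Greedy LD pruning over a seeded random scan order.

    A SNP is kept iff its r-squared against every already-kept SNP
    (within `window_bp`, when given) stays below `r2_max`. Monomorphic
    SNPs carry no LD information and are always kept. `scan_order` (a
    permutation of indices) overrides the seeded shuffle, e.g. for
    positional-order pruning.
    """
    snp_ids = list(snp_ids)
    missing = [s for s in snp_ids if s not in panel.columns]
    if missing:
        raise DataError(f"panel does not cover SNPs: {missing[:5]}")
    if scan_order is not None:
        order = list(scan_order)
        if sorted(order) != list(range(len(snp_ids))):
            raise DataError("scan_order must be a permutation of SNP indices")
    else:
        rng = substream(seed, "ld_prune")
        order = rng.permutation(len(snp_ids))

    mat = panel[snp_ids].to_numpy(dtype=float)
    kept: list[int] = []
    for idx in order:
        candidates = kept
        if window_bp is not None and positions is not None:
            pos = positions[snp_ids[idx]]
            candidates = [k for k in kept
                          if abs(positions[snp_ids[k]] - pos) <= window_bp]
        if candidates:
            r2 = _r2_against(mat, idx, np.array(candidates))
            if np.any(r2[np.isfinite(r2)] >= r2_max):
                continue
        kept.append(idx)
    kept_ids = [snp_ids[i] for i in sorted(kept)]
    return kept_ids


def proxy_match(
    query_snps,
    catalog_snps,
    panel: pd.DataFrame,
    r2_min: float = 0.8,
) -> pd.DataFrame:
    """Match query SNPs to catalog entries directly or through LD proxies.

    A query matches a catalog SNP if it is the same SNP, or if their
    dosage r-squared exceeds `r2_min`. SNPs absent from the panel are
    reported unmatched with a reason.
    """
    catalog = list(dict.fromkeys(catalog_snps))
    rows = []
    for q in query_snps:
        if q in catalog:
            rows.append({"query": q, "matched": True, "proxy": q, "r2": 1.0,
                         "reason": "identical"})
            continue
        if q not in panel.columns:
            rows.append({"query": q, "matched": False, "proxy": "", "r2": np.nan,
                         "reason": "query_not_in_panel"})
            continue
        best, best_r2 = "", -1.0
        for c in catalog:
            if c not in panel.columns:
                continue
            r2 = ld_r2(panel[q], panel[c])
            if np.isfinite(r2) and r2 > best_r2:
                best, best_r2 = c, r2
        if best and best_r2 > r2_min:
            rows.append({"query": q, "matched": True, "proxy": best,
                         "r2": best_r2, "reason": "ld_proxy"})
        else:
            rows.append({"query": q, "matched": False, "proxy": "",
                         "r2": best_r2 if best else np.nan,
                         "reason": "no_proxy"})
    return pd.DataFrame(rows)


def enrichment_test(
    n_hits_a: int, n_a: int, n_hits_b: int, n_b: int,
    continuity: bool = False,
):
    """2x2 chi-square comparing hit proportions between two SNP sets.

    Returns (statistic, p); both NaN when a table margin is zero.
    """
    if min(n_hits_a, n_a, n_hits_b, n_b) < 0:
        raise DataError("counts must be non-negative")
    if n_hits_a > n_a or n_hits_b > n_b:
        raise DataError("hits cannot exceed set size")
    table = np.array([[n_hits_a, n_a - n_hits_a],
                      [n_hits_b, n_b - n_hits_b]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(chi2), float(p)


def annotate_gene_context(
    snp_positions: pd.DataFrame,
    gene_intervals: pd.DataFrame,
) -> pd.DataFrame:
    """Genic / non-genic context and distance to the nearest gene.

    `snp_positions`: snp_id, chrom, pos (1-based). `gene_intervals`:
    chrom, start, end (1-based inclusive), gene, feature. A SNP is genic
    when it falls inside any 5UTR/3UTR/exon/intron interval (inclusive
    ends); otherwise distance is to the nearest gene boundary on the
    same chromosome.
    """
    if gene_intervals.empty:
        warnings.warn("empty gene set: all SNPs non-genic with infinite distance")
        out = snp_positions[["snp_id"]].copy()
        out["context"] = "non_genic"
        out["nearest_gene"] = ""
        out["distance"] = np.inf
        return out
    bad = gene_intervals["end"] < gene_intervals["start"]
    if bad.any():
        raise DataError("gene interval with end < start")

    genic = gene_intervals[gene_intervals["feature"].isin(GENIC_FEATURES)]
    rows = []
    for snp in snp_positions.itertuples(index=False):
        on_chrom = gene_intervals[gene_intervals["chrom"] == snp.chrom]
        g_chrom = genic[genic["chrom"] == snp.chrom]
        inside = g_chrom[(g_chrom["start"] <= snp.pos) & (snp.pos <= g_chrom["end"])]
        if len(inside):
            rows.append({"snp_id": snp.snp_id, "context": "genic",
                         "nearest_gene": inside.iloc[0]["gene"], "distance": 0})
            continue
        if on_chrom.empty:
            rows.append({"snp_id": snp.snp_id, "context": "non_genic",
                         "nearest_gene": "", "distance": np.inf})
            continue
        d = np.where(snp.pos < on_chrom["start"], on_chrom["start"] - snp.pos,
                     np.where(snp.pos > on_chrom["end"], snp.pos - on_chrom["end"], 0))
        i = int(np.argmin(d))
        rows.append({"snp_id": snp.snp_id, "context": "non_genic",
                     "nearest_gene": on_chrom.iloc[i]["gene"],
                     "distance": int(d[i])})
    out = pd.DataFrame(rows)
    out.attrs["non_genic_median_distance"] = float(
        np.median([r["distance"] for r in rows if r["context"] == "non_genic"])
    ) if any(r["context"] == "non_genic" for r in rows) else np.nan
    return out


def filter_gwas_catalog(catalog: pd.DataFrame, p_max: float = 1e-7,
                        min_sample_size: int = 500) -> pd.DataFrame:
    """Restrict a GWAS-catalog table to well-powered, stringent entries.

    Keeps rows with an annotated association p-value below `p_max` and an
    initial sample size of at least `min_sample_size`. Expected columns:
    snp_id, p_value, sample_size (extra columns pass through); rows with
    missing values in either field are dropped.
    """
    needed = {"snp_id", "p_value", "sample_size"}
    missing = needed - set(catalog.columns)
    if missing:
        raise DataError(f"catalog missing columns: {sorted(missing)}")
    out = catalog.dropna(subset=["p_value", "sample_size"])
    out = out[(out["p_value"] < p_max) & (out["sample_size"] >= min_sample_size)]
    return out.reset_index(drop=True)


def maf_matched_background(candidate_maf: pd.Series, background_maf: pd.Series,
                           n_bins: int = 10, seed: int = 0) -> list:
    """Sample a background SNP set matching the candidates' MAF spectrum.

    MAFs (values in (0, 0.5]) are binned into `n_bins` equal-width bins
    over (0, 0.5]; for each bin, as many background SNPs as there are
    candidates in that bin are drawn without replacement (all of them,
    with a warning, if the bin is under-populated).
    """
    rng = substream(seed, "maf_match")
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    cand_bins = np.clip(np.digitize(candidate_maf.to_numpy(), edges) - 1,
                        0, n_bins - 1)
    bg_bins = np.clip(np.digitize(background_maf.to_numpy(), edges) - 1,
                      0, n_bins - 1)
    chosen = []
    bg_ids = np.asarray(background_maf.index)
    for b in range(n_bins):
        need = int(np.sum(cand_bins == b))
        if need == 0:
            continue
        pool = bg_ids[bg_bins == b]
        if len(pool) < need:
            warnings.warn(f"MAF bin {b}: only {len(pool)} background SNPs "
                          f"for {need} candidates")
            chosen.extend(pool.tolist())
        else:
            chosen.extend(rng.choice(pool, size=need, replace=False).tolist())
    return chosen


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via the t approximation."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    return p


def permutation_eqtl_test(
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    snp_positions: pd.Series,
    gene_tss: pd.Series,
    n_perm: int = 10_000,
    cis_window: int = 1_000_000,
    alpha: float = 0.05,
    min_samples: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene permutation eQTL scan with Spearman nominal p-values.

    For each gene, cis SNPs are those within `cis_window` of its TSS.
    The permutation null is the distribution of the minimum nominal p
    over cis SNPs per expression permutation; a SNP is a significant
    eQTL iff its nominal p lies below the `alpha` quantile of that null.
    Genes with constant expression are skipped.

    Returns (gene_table, snp_table).
    """
    n = len(genotypes)
    if len(expression) != n:
        raise DataError("genotypes and expression must cover the same samples")
    if n < min_samples:
        raise DataError(f"need >= {min_samples} samples, got {n}")
    rng = substream(seed, "eqtl_perm")

    gene_rows, snp_rows = [], []
    for gene in expression.columns:
        y = expression[gene].to_numpy(dtype=float)
        if np.std(y) == 0:
            continue
        tss = gene_tss[gene]
        cis = [s for s in genotypes.columns
               if abs(snp_positions[s] - tss) <= cis_window]
        cis = [s for s in cis if np.std(genotypes[s].to_numpy(dtype=float)) > 0]
        if not cis:
            continue
        g_rank = stats.rankdata(genotypes[cis].to_numpy(dtype=float), axis=0)
        gz = (g_rank - g_rank.mean(axis=0)) / g_rank.std(axis=0)
        y_rank = stats.rankdata(y)
        yz = (y_rank - y_rank.mean()) / y_rank.std()

        rho_obs = yz @ gz / n
        p_obs = _spearman_p(rho_obs, n)

        perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
        yz_perm = yz[perm_idx]                      # n_perm x n
        rho_perm = yz_perm @ gz / n                 # n_perm x n_snps
        p_perm = _spearman_p(rho_perm, n)
        min_p = p_perm.min(axis=1)

        threshold = float(np.quantile(min_p, alpha))
        p_min_obs = float(p_obs.min())
        gene_p = (1 + int(np.sum(min_p <= p_min_obs))) / (n_perm + 1)
        gene_rows.append({"gene": gene, "n_cis_snps": len(cis),
                          "min_nominal_p": p_min_obs, "threshold": threshold,
                          "empirical_p": gene_p,
                          "significant": p_min_obs < threshold})
        for s, rho, p in zip(cis, rho_obs, p_obs):
            snp_rows.append({"gene": gene, "snp_id": s, "rho": float(rho),
                             "nominal_p": float(p),
                             "significant": bool(p < threshold)})
    return pd.DataFrame(gene_rows), pd.DataFrame(snp_rows)
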