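"""Table schemas, readers/writers, minimal VCF/BED handling, run config.

All user-facing genomic positions are 1-based inclusive. BED input
(0-based half-open) is converted at the boundary. Tables are
tab-separated with exact headers; writing then reading a table returns
equal records, and numbers are serialized with full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError

__all__ = [
    "SCHEMAS", "read_table", "write_table",
    "write_vcf", "read_vcf_dosage", "read_bed_genes",
    "RunConfig",
]

SCHEMAS = {
    "probes": ["probeset_id", "sample_id", "replicate", "digested",
               "intensity_A", "intensity_B"],
    "reference_panel": ["probeset_id", "region_type",
                        "n_AA", "mean_AA", "sd_AA", "n_AB", "mean_AB", "sd_AB",
                        "n_BB", "mean_BB", "sd_BB", "het_mean", "het_sd",
                        "ref_total_intensity", "n_calls"],
    "amplicons": ["amplicon_id", "snp_id", "chrom", "start", "end",
                  "enzyme_frame", "predicted_size", "msre_snp_max_maf",
                  "n_AciI", "n_BsaHI", "n_HhaI", "n_HpaII", "n_HpyCH4IV"],
    "amplicon_class": ["amplicon_id", "amplicon_class", "reasons"],
    "asm_calls": ["mpr_id", "sample_id", "genotype", "z", "ratio", "call"],
    "population_asm": ["mpr_id", "n_het", "n_asm_A", "n_asm_B", "n_filtered",
                       "binomial_p", "asm_class", "cis_allele"],
    "reads": ["sample_id", "amplicon_id", "read_id", "allele", "cpg_states",
              "noncpg_converted", "noncpg_total"],
    "genotypes": ["probeset_id", "sample_id", "genotype"],
    "truth_regions": ["probeset_id", "region_type", "true_class"],
    "truth_samples": ["probeset_id", "sample_id", "genotype", "meth_state"],
}


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> None:
    """Write a TSV; when `schema` is given, columns are checked and ordered."""
    df = df.copy()
    if schema is not None:
        cols = SCHEMAS[schema]
        missing = set(cols) - set(df.columns)
        if missing:
            raise SchemaError(f"missing column(s) for schema '{schema}': "
                              f"{sorted(missing)}")
        df = df[cols]
    # pandas default float formatting is the shortest round-trip repr
    df.to_csv(path, sep="\t", index=False)


def read_table(path, schema: str | None = None) -> pd.DataFrame:
    """Read a TSV; when `schema` is given, the header must match exactly."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if schema is not None:
        cols = SCHEMAS[schema]
        missing = [c for c in cols if c not in df.columns]
        extra = [c for c in df.columns if c not in cols]
        if missing:
            raise SchemaError(f"'{Path(path).name}' missing column(s) "
                              f"{missing} for schema '{schema}'")
        if extra:
            raise SchemaError(f"'{Path(path).name}' has unexpected column(s) "
                              f"{extra} for schema '{schema}'")
        df = df[cols]
    return df


# ---------------------------------------------------------------------------
# minimal VCF and BED

def write_vcf(panel: pd.DataFrame, path, chrom: str | None = None,
              positions: pd.Series | None = None) -> None:
    """Write a dosage panel (samples x SNPs) as a minimal GT-only VCF."""
    chrom = chrom or panel.attrs.get("chrom", "chr1")
    if positions is None:
        positions = panel.attrs.get("positions")
    if positions is None:
        positions = pd.Series(np.arange(1, panel.shape[1] + 1) * 1000,
                              index=panel.columns)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    samples = list(panel.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for snp in panel.columns:
            gts = "\t".join(gt_map[int(v)] for v in panel[snp])
            fh.write(f"{chrom}\t{int(positions[snp])}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf_dosage(path) -> pd.DataFrame:
    """Read a VCF into a samples x SNPs dosage DataFrame (GT field only)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, positions, rows, chroms = [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
        chroms.append(var.CHROM)
        # with gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 missing
        dos = np.asarray(var.gt_types, dtype=float)
        dos[dos == 3] = np.nan
        rows.append(dos)
    vcf.close()
    panel = pd.DataFrame(np.column_stack(rows) if rows else np.empty((len(samples), 0)),
                         index=samples, columns=ids)
    panel.attrs["positions"] = pd.Series(positions, index=ids, dtype=int)
    panel.attrs["chrom"] = chroms[0] if chroms else ""
    return panel


def read_bed_genes(path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open) into 1-based inclusive.

    Columns: chrom, start, end, gene[, feature]; a missing feature column
    defaults to 'exon' so plain gene BED files count as genic intervals.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise SchemaError("BED needs at least chrom, start, end, name columns")
    df = df.iloc[:, :5] if df.shape[1] >= 5 else df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "gene"] + (
        ["feature"] if df.shape[1] == 5 else [])
    if "feature" not in df.columns:
        df["feature"] = "exon"
    out = df.copy()
    out["start"] = out["start"].astype(int) + 1   # 0-based half-open -> 1-based
    out["end"] = out["end"].astype(int)           # half-open end == inclusive end
    if (out["end"] < out["start"]).any():
        raise SchemaError("BED interval with end < start after conversion")
    return out


# ---------------------------------------------------------------------------
# run configuration

_ALLOWED = {
    "seed": int,
    "outdir": str,
    "array": {"n_samples", "n_mpr", "n_mnr", "n_reference", "maf",
              "cis_asm_fraction", "random_asm_fraction", "penetrance",
              "digestion_efficiency", "noise_sd", "baseline_intensity",
              "background_fraction", "biallelic_unmeth_fraction",
              "array_scale_sd", "n_replicates", "n_excluded"},
    "qc": {"size_min", "size_max", "msre_snp_maf", "discrimination_k"},
    "calling": {"ratio_min", "pct_lo", "pct_hi", "replicate_rule"},
    "population": {"min_het", "min_events", "alpha", "cis_rule"},
    "bisulfite": {"n_samples", "reads_per_sample_amplicon",
                  "conversion_failure_rate", "read_dropout", "noncpg_per_read",
                  "min_depth", "min_gq", "hwe_p", "maf_rmd", "min_conversion"},
}


@dataclass
class RunConfig:
    """Validated, nested pipeline configuration."""

    seed: int = 0
    outdir: str = "asmscan_run"
    array: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    calling: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    bisulfite: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(_ALLOWED)
        if unknown:
            raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
        for section, allowed in _ALLOWED.items():
            if isinstance(allowed, set) and section in data:
                bad = set(data[section]) - allowed
                if bad:
                    raise ConfigurationError(
                        f"unknown key(s) in [{section}]: {sorted(bad)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
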