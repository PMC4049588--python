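"""Generative model of allele-tagged bisulfite amplicon reads.

Each simulated read observes, on the same molecule, the allele at a target
SNP and the methylation state of every CpG in the amplicon. Bisulfite
chemistry converts unmethylated cytosines (read as T); methylated
cytosines are protected. Conversion failures leave an unmethylated
cytosine looking methylated, at non-CpG cytosines as well as CpGs — the
non-CpG columns are what the per-sample conversion-rate QC measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .._rng import substream
from ..errors import ConfigurationError

__all__ = ["BsAmpliconSpec", "BsSimConfig", "BsSimResult", "simulate_bisulfite_experiment"]


@dataclass
class BsAmpliconSpec:
    """One target amplicon: its CpGs, MSRE flags and SNP.

    meth_prob_ref / meth_prob_alt are per-CpG methylation probabilities on
    reads carrying the reference / alternate allele; a scalar is broadcast
    over CpGs. `array_a_allele` records which bisulfite allele corresponds
    to the array's A allele (for cross-assay direction checks); None means
    no array call is available.
    """

    amplicon_id: str
    n_cpg: int
    msre_flags: Sequence[bool]
    snp_maf: float
    meth_prob_ref: float | Sequence[float] = 0.9
    meth_prob_alt: float | Sequence[float] = 0.9
    chrom: str = "chr1"
    start: int = 1000
    cpg_spacing: int = 25
    array_a_allele: str | None = None  # "ref", "alt" or None

    def validate(self) -> None:
        if self.n_cpg <= 0:
            raise ConfigurationError("n_cpg must be a positive count")
        if len(self.msre_flags) != self.n_cpg:
            raise ConfigurationError("msre_flags length must equal n_cpg")
        if not 0.0 < self.snp_maf < 1.0:
            raise ConfigurationError(f"snp_maf must lie in (0, 1), got {self.snp_maf}")
        for name in ("meth_prob_ref", "meth_prob_alt"):
            p = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if p.size not in (1, self.n_cpg):
                raise ConfigurationError(f"{name} must be scalar or length n_cpg")
            if np.any((p < 0) | (p > 1)):
                raise ConfigurationError(f"{name} must lie in [0, 1]")

    def probs(self, allele: str) -> np.ndarray:
        p = self.meth_prob_ref if allele == "ref" else self.meth_prob_alt
        return np.broadcast_to(np.atleast_1d(np.asarray(p, dtype=float)),
                               (self.n_cpg,)).copy()


@dataclass
class BsSimConfig:
    """Study conditions for the bisulfite confirmation simulation.

    The 1.3% conversion-failure default reproduces the ~98.7% mean non-CpG
    conversion a well-behaved bisulfite run achieves.
    """

    n_samples: int = 70
    amplicons: Sequence[BsAmpliconSpec] = field(default_factory=list)
    reads_per_sample_amplicon: int = 200
    conversion_failure_rate: float = 0.013
    read_dropout: float = 0.1       # reads missing the SNP observation
    noncpg_per_read: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigurationError("n_samples must be a positive count")
        if self.reads_per_sample_amplicon < 1:
            raise ConfigurationError("reads_per_sample_amplicon must be >= 1")
        if not self.amplicons:
            raise ConfigurationError("amplicons must be non-empty")
        for name in ("conversion_failure_rate", "read_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.noncpg_per_read < 1:
            raise ConfigurationError("noncpg_per_read must be >= 1")
        for amp in self.amplicons:
            amp.validate()


@dataclass
class BsSimResult:
    reads: pd.DataFrame        # sample_id, amplicon_id, read_id, allele, cpg_states, ...
    amplicon_meta: pd.DataFrame   # amplicon-level metadata incl. allele mapping
    cpg_meta: pd.DataFrame     # amplicon_id, cpg_index, chrom, pos, is_msre
    truth_genotypes: pd.DataFrame  # sample_id, amplicon_id, genotype
    config: BsSimConfig = field(repr=False, default=None)


_GT_NAMES = np.array(["ref_hom", "het", "alt_hom"])


def simulate_bisulfite_experiment(config: BsSimConfig) -> BsSimResult:
    """Simulate per-read allele + CpG methylation observations.

    Reproducible given the config seed. Genotypes are drawn under HWE at
    each amplicon's SNP MAF; each read samples one of the individual's two
    alleles uniformly, then per-CpG methylation from that allele's
    probability, then conversion failures flip U -> M independently.
    """
    cfg = config
    cfg.validate()
    rng = substream(cfg.seed, "bisulfite")

    sample_ids = [f"B{i + 1:03d}" for i in range(cfg.n_samples)]
    rows = []
    truth_rows = []
    meta_rows = []
    cpg_rows = []

    for amp in cfg.amplicons:
        geno = rng.binomial(2, amp.snp_maf, size=cfg.n_samples)  # alt-allele count
        p_by_allele = {"ref": amp.probs("ref"), "alt": amp.probs("alt")}
        meta_rows.append({
            "amplicon_id": amp.amplicon_id, "chrom": amp.chrom,
            "snp_pos": amp.start, "snp_maf": amp.snp_maf, "n_cpg": amp.n_cpg,
            "array_a_allele": amp.array_a_allele or "",
        })
        for k in range(amp.n_cpg):
            cpg_rows.append({
                "amplicon_id": amp.amplicon_id, "cpg_index": k,
                "chrom": amp.chrom, "pos": amp.start + (k + 1) * amp.cpg_spacing,
                "is_msre": bool(amp.msre_flags[k]),
            })
        n_reads = cfg.reads_per_sample_amplicon
        for s_idx, sid in enumerate(sample_ids):
            truth_rows.append({"sample_id": sid, "amplicon_id": amp.amplicon_id,
                               "genotype": _GT_NAMES[geno[s_idx]]})
            # allele of each read: draw one of the two chromosomes
            alt_copies = geno[s_idx]
            is_alt = rng.random(n_reads) < alt_copies / 2.0
            alleles = np.where(is_alt, "alt", "ref")
            dropped = rng.random(n_reads) < cfg.read_dropout
            meth = np.empty((n_reads, amp.n_cpg), dtype=bool)
            for allele in ("ref", "alt"):
                m = alleles == allele
                if m.any():
                    meth[m] = rng.random((int(m.sum()), amp.n_cpg)) < p_by_allele[allele]
            # conversion failure makes an unmethylated CpG read as methylated
            fail = rng.random((n_reads, amp.n_cpg)) < cfg.conversion_failure_rate
            observed = meth | (~meth & fail)
            noncpg_conv = rng.binomial(cfg.noncpg_per_read,
                                       1.0 - cfg.conversion_failure_rate, size=n_reads)
            states = np.where(observed, "M", "U")
            for r in range(n_reads):
                rows.append({
                    "sample_id": sid,
                    "amplicon_id": amp.amplicon_id,
                    "read_id": f"{amp.amplicon_id}:{sid}:{r:05d}",
                    "allele": "missing" if dropped[r] else alleles[r],
                    "cpg_states": "".join(states[r]),
                    "noncpg_converted": int(noncpg_conv[r]),
                    "noncpg_total": cfg.noncpg_per_read,
                })

    return BsSimResult(
        reads=pd.DataFrame(rows),
        amplicon_meta=pd.DataFrame(meta_rows),
        cpg_meta=pd.DataFrame(cpg_rows),
        truth_genotypes=pd.DataFrame(truth_rows),
        config=cfg,
    )
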