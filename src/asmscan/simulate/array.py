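"""Generative model of the MSRE-digest SNP-array ASM assay.

The assay: genomic DNA is digested with methylation-sensitive restriction
enzymes (MSREs), which cut their recognition site only when its CpG is
unmethylated. PCR amplicons from an unmethylated allele are therefore
ablated, and the allele-ratio signal of an MSRE-positive region (MPR) on a
SNP genotyping array shifts toward the methylated allele. Amplicons without
MSRE sites (MNRs) are unaffected by digestion and serve as a per-sample
null. A reference panel of undigested samples provides the per-MPR
heterozygote log2(A/B) distribution that post-digest values are scored
against.

This module inverts that description into a simulator with known ground
truth: per-MPR cis/random ASM classes, per-sample genotypes drawn under
Hardy-Weinberg equilibrium, four per-heterozygote methylation states
(biallelic methylated, monoallelic-A, monoallelic-B, biallelic
unmethylated), probabilistic digestion of unmethylated allele copies,
lognormal (multiplicative) probe noise, and per-array scale distortions
that the invariant-probeset normalization is meant to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._rng import substream
from ..errors import ConfigurationError

__all__ = ["ArraySimConfig", "ArraySimResult", "simulate_array_experiment"]

ENZYMES = ("AciI", "BsaHI", "HhaI", "HpaII", "HpyCH4IV")

# per-MPR truth classes
CLASS_NONE = "none"
CLASS_CIS_A = "cis_A"
CLASS_CIS_B = "cis_B"
CLASS_RANDOM = "random"

# per-sample methylation states (integer codes used internally)
STATE_NAMES = np.array(["biallelic_meth", "mono_A", "mono_B", "biallelic_unmeth"])
_BI_METH, _MONO_A, _MONO_B, _BI_UNMETH = 0, 1, 2, 3

GENOTYPE_NAMES = np.array(["AA", "AB", "BB"])

_LN2 = np.log(2.0)


@dataclass
class ArraySimConfig:
    """Study conditions for the array-stage simulation.

    Defaults mirror the design of the original screen: 42 digested study
    samples run in duplicate, an undigested reference panel, roughly 4-5%
    of MPRs under cis control with incomplete penetrance, and strong but
    imperfect digestion. Noise magnitudes are calibration choices (the
    assay publishes no quantitative noise model); see docs/methods.md.
    """

    n_samples: int = 42
    n_mpr: int = 1000
    n_mnr: int = 500
    n_reference: int = 90
    maf: float = 0.3
    cis_asm_fraction: float = 0.05
    random_asm_fraction: float = 0.01
    penetrance: float = 0.8
    digestion_efficiency: float = 0.95
    noise_sd: float = 0.15          # sd of log2-scale multiplicative probe noise
    baseline_intensity: float = 1000.0
    probe_affinity_sd: float = 0.7  # per-probeset, per-channel affinity spread, log2 units
    background_fraction: float = 0.02   # ablated-amplicon signal, fraction of baseline
    biallelic_unmeth_fraction: float = 0.10  # rate of the low-intensity unmethylated state
    array_scale_sd: float = 0.25    # per-array multiplicative distortion, log2 units
    n_replicates: int = 2
    n_excluded: int = 0             # defective amplicons to exercise array QC
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_mpr", "n_mnr", "n_reference", "n_replicates"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.n_excluded < 0:
            raise ConfigurationError("n_excluded must be >= 0")
        for name in ("maf", "cis_asm_fraction", "random_asm_fraction", "penetrance",
                     "digestion_efficiency", "background_fraction",
                     "biallelic_unmeth_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.cis_asm_fraction + self.random_asm_fraction > 1.0:
            raise ConfigurationError(
                "cis_asm_fraction + random_asm_fraction must not exceed 1")
        if not self.noise_sd > 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.array_scale_sd < 0:
            raise ConfigurationError("array_scale_sd must be >= 0")
        if self.probe_affinity_sd < 0:
            raise ConfigurationError("probe_affinity_sd must be >= 0")
        if not self.baseline_intensity > 0:
            raise ConfigurationError("baseline_intensity must be > 0")


@dataclass
class ArraySimResult:
    """All outputs of one simulated array experiment."""

    probes: pd.DataFrame            # probeset_id, sample_id, replicate, digested, intensity_A/B
    reference_probes: pd.DataFrame  # undigested panel arrays, same dialect
    reference_genotypes: pd.DataFrame  # panel genotypes (probeset_id, sample_id, genotype)
    reference_panel: pd.DataFrame   # per-probeset panel summary on the raw scale
    amplicons: pd.DataFrame         # annotation consumed by array QC
    truth_regions: pd.DataFrame     # probeset_id, region_type, true_class
    truth_samples: pd.DataFrame     # probeset_id, sample_id, genotype, meth_state
    config: ArraySimConfig = field(repr=False, default=None)

    @property
    def genotypes(self) -> pd.DataFrame:
        """Long genotype table (probeset_id, sample_id, genotype) for the caller."""
        return self.truth_samples[["probeset_id", "sample_id", "genotype"]].copy()


def _draw_states(cfg: ArraySimConfig, true_class: np.ndarray, g: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Methylation state per probeset x sample.

    Heterozygotes at ASM probesets express the monoallelic state with
    probability `penetrance`; everything else is biallelically methylated
    except a `biallelic_unmeth_fraction` share of low-methylation sites.
    """
    n_ps, n_s = g.shape
    state = np.full((n_ps, n_s), _BI_METH, dtype=np.int8)
    state[rng.random((n_ps, n_s)) < cfg.biallelic_unmeth_fraction] = _BI_UNMETH

    het = g == 1
    expressing = het & (rng.random((n_ps, n_s)) < cfg.penetrance)
    cls = true_class[:, None]
    state[(cls == CLASS_CIS_A) & expressing] = _MONO_A
    state[(cls == CLASS_CIS_B) & expressing] = _MONO_B
    random_expr = (cls == CLASS_RANDOM) & expressing
    coin = rng.random((n_ps, n_s)) < 0.5
    state[random_expr & coin] = _MONO_A
    state[random_expr & ~coin] = _MONO_B
    return state


def _methylated_copies(g: np.ndarray, state: np.ndarray):
    """Per-channel (A, B) methylated and unmethylated copy counts."""
    copies_a = 2 - g
    copies_b = g
    meth_a = np.where(state == _BI_METH, copies_a,
                      np.where(state == _MONO_A, np.minimum(copies_a, 1), 0))
    meth_b = np.where(state == _BI_METH, copies_b,
                      np.where(state == _MONO_B, np.minimum(copies_b, 1), 0))
    return copies_a, copies_b, meth_a, meth_b


def _intensities(cfg: ArraySimConfig, retained_a, retained_b,
                 rng: np.random.Generator, affinity_a, affinity_b, scale=None):
    """Lognormal-noise intensities given retained copy counts per channel.

    `affinity_a` / `affinity_b` are fixed per-probeset, per-channel
    multipliers shared by study samples and the reference panel; they
    model probe-sequence affinity differences and give each probeset a
    nonzero heterozygote log2(A/B) center (the reason calling z-scores
    against a per-MPR reference distribution in the first place).
    """
    shape = retained_a.shape
    sigma = cfg.noise_sd * _LN2
    noise_a = np.exp(rng.normal(0.0, sigma, shape))
    noise_b = np.exp(rng.normal(0.0, sigma, shape))
    ia = cfg.baseline_intensity * affinity_a[:, None] \
        * (retained_a + cfg.background_fraction) * noise_a
    ib = cfg.baseline_intensity * affinity_b[:, None] \
        * (retained_b + cfg.background_fraction) * noise_b
    if scale is not None:
        ia = ia * scale
        ib = ib * scale
    return ia, ib


def _amplicon_table(cfg: ArraySimConfig, probeset_ids, region_type,
                    rng: np.random.Generator) -> pd.DataFrame:
    n = len(probeset_ids)
    sizes = rng.integers(250, 1101, size=n)
    counts = rng.poisson(0.6, size=(n, len(ENZYMES)))
    maf = rng.uniform(0.0, 0.04, size=n)

    is_mnr = region_type == "MNR"
    counts[is_mnr] = 0
    maf[is_mnr] = 0.0
    # MPRs must carry at least one non-HhaI site to stay assayable
    is_mpr = region_type == "MPR"
    non_hhai = counts[:, [0, 1, 3, 4]].sum(axis=1)
    fix = is_mpr & (non_hhai == 0)
    counts[fix, 3] = 1  # HpaII

    # defective amplicons cycle through the three exclusion modes
    exc_idx = np.flatnonzero(region_type == "EXC")
    for j, i in enumerate(exc_idx):
        mode = j % 3
        if mode == 0:        # HhaI-only sites
            counts[i] = [0, 0, 2, 0, 0]
        elif mode == 1:      # size outside the 200-1200 bp window
            counts[i] = [1, 0, 0, 1, 0]
            sizes[i] = 1500
        else:                # polymorphic MSRE site above 4% MAF
            counts[i] = [1, 0, 0, 0, 0]
            maf[i] = 0.06

    start = 10_000 + 5_000 * np.arange(n)
    frame = np.where(np.arange(n) % 2 == 0, "NspI", "StyI")
    table = pd.DataFrame({
        "amplicon_id": probeset_ids,
        "snp_id": [f"rs{900000 + i}" for i in range(n)],
        "chrom": "chr1",
        "start": start,
        "end": start + sizes - 1,
        "enzyme_frame": frame,
        "predicted_size": sizes,
        "msre_snp_max_maf": maf,
    })
    for k, enz in enumerate(ENZYMES):
        table[f"n_{enz}"] = counts[:, k]
    return table


def simulate_array_experiment(config: ArraySimConfig) -> ArraySimResult:
    """Simulate probe intensities, reference panel and annotation.

    Reproducible: the same config (including seed) yields byte-identical
    outputs. Separate named substreams drive truth assignment, genotypes,
    study-array noise and the reference panel.
    """
    cfg = config
    cfg.validate()
    seed = cfg.seed

    n_ps = cfg.n_mpr + cfg.n_mnr + cfg.n_excluded
    probeset_ids = np.array(
        [f"MPR{i:06d}" for i in range(cfg.n_mpr)]
        + [f"MNR{i:06d}" for i in range(cfg.n_mnr)]
        + [f"EXC{i:06d}" for i in range(cfg.n_excluded)]
    )
    region_type = np.array(
        ["MPR"] * cfg.n_mpr + ["MNR"] * cfg.n_mnr + ["EXC"] * cfg.n_excluded
    )

    # ---- truth: per-MPR class -------------------------------------------------
    rng_truth = substream(seed, "array.truth")
    u = rng_truth.random(n_ps)
    true_class = np.full(n_ps, CLASS_NONE, dtype=object)
    is_cis = u < cfg.cis_asm_fraction
    is_rand = (u >= cfg.cis_asm_fraction) & (u < cfg.cis_asm_fraction + cfg.random_asm_fraction)
    cis_allele = rng_truth.random(n_ps) < 0.5
    true_class[is_cis & cis_allele] = CLASS_CIS_A
    true_class[is_cis & ~cis_allele] = CLASS_CIS_B
    true_class[is_rand] = CLASS_RANDOM
    # MNRs carry no digestion signal; their truth class is always none
    not_mpr = region_type != "MPR"
    true_class[not_mpr] = CLASS_NONE

    # ---- study samples --------------------------------------------------------
    rng_geno = substream(seed, "array.genotypes")
    g = rng_geno.binomial(2, cfg.maf, size=(n_ps, cfg.n_samples)).astype(np.int8)

    rng_state = substream(seed, "array.states")
    state = _draw_states(cfg, true_class, g, rng_state)
    # MNRs carry no MSRE site, so their methylation state is inert; pin it
    state[np.broadcast_to((region_type == "MNR")[:, None], state.shape)] = _BI_METH

    copies_a, copies_b, meth_a, meth_b = _methylated_copies(g, state)

    # digestion: one digest per sample; unmethylated amplicons at a locus
    # escape together with probability 1 - digestion_efficiency (cutting
    # failure is a property of the reaction at that locus, so the two
    # homologous amplicons in one tube are not independent). MNRs are
    # never digested.
    rng_digest = substream(seed, "array.digestion")
    escaped = rng_digest.random((n_ps, cfg.n_samples)) < (1.0 - cfg.digestion_efficiency)
    retained_a = meth_a + np.where(escaped, copies_a - meth_a, 0)
    retained_b = meth_b + np.where(escaped, copies_b - meth_b, 0)
    mnr_rows = (region_type == "MNR")[:, None]
    retained_a = np.where(mnr_rows, copies_a, retained_a)
    retained_b = np.where(mnr_rows, copies_b, retained_b)

    rng_aff = substream(seed, "array.affinity")
    aff_sigma = cfg.probe_affinity_sd * _LN2
    affinity_a = np.exp(rng_aff.normal(0.0, aff_sigma, n_ps))
    affinity_b = np.exp(rng_aff.normal(0.0, aff_sigma, n_ps))

    rng_probe = substream(seed, "array.probes")
    sample_ids = np.array([f"S{i + 1:03d}" for i in range(cfg.n_samples)])
    frames = []
    # per-array multiplicative distortion (array = sample x replicate)
    scale_sigma = cfg.array_scale_sd * _LN2
    for rep in range(1, cfg.n_replicates + 1):
        scale = np.exp(rng_probe.normal(0.0, scale_sigma, cfg.n_samples))[None, :]
        ia, ib = _intensities(cfg, retained_a, retained_b, rng_probe,
                              affinity_a, affinity_b, scale=scale)
        frames.append(pd.DataFrame({
            "probeset_id": np.repeat(probeset_ids, cfg.n_samples),
            "sample_id": np.tile(sample_ids, n_ps),
            "replicate": rep,
            "digested": 1,
            "intensity_A": ia.ravel(),
            "intensity_B": ib.ravel(),
        }))
    probes = pd.concat(frames, ignore_index=True)
    probes = probes.sort_values(
        ["probeset_id", "sample_id", "replicate"], kind="mergesort"
    ).reset_index(drop=True)

    # ---- reference panel (undigested) ----------------------------------------
    rng_ref = substream(seed, "array.reference")
    g_ref = rng_ref.binomial(2, cfg.maf, size=(n_ps, cfg.n_reference)).astype(np.int8)
    ref_a, ref_b = _intensities(cfg, 2 - g_ref, g_ref, rng_ref,
                                affinity_a, affinity_b)
    ref_sample_ids = np.array([f"R{i + 1:03d}" for i in range(cfg.n_reference)])
    reference_probes = pd.DataFrame({
        "probeset_id": np.repeat(probeset_ids, cfg.n_reference),
        "sample_id": np.tile(ref_sample_ids, n_ps),
        "replicate": 1,
        "digested": 0,
        "intensity_A": ref_a.ravel(),
        "intensity_B": ref_b.ravel(),
    })
    reference_genotypes = pd.DataFrame({
        "probeset_id": np.repeat(probeset_ids, cfg.n_reference),
        "sample_id": np.tile(ref_sample_ids, n_ps),
        "genotype": GENOTYPE_NAMES[g_ref.ravel()],
    })

    from ..calling import build_reference_distribution
    reference_panel = build_reference_distribution(reference_probes,
                                                   reference_genotypes)
    reference_panel.insert(1, "region_type",
                           reference_panel["probeset_id"].map(
                               dict(zip(probeset_ids, region_type))))

    # ---- annotation + truth ---------------------------------------------------
    rng_amp = substream(seed, "array.amplicons")
    amplicons = _amplicon_table(cfg, probeset_ids, region_type, rng_amp)

    truth_regions = pd.DataFrame({
        "probeset_id": probeset_ids,
        "region_type": region_type,
        "true_class": true_class.astype(str),
    })
    truth_samples = pd.DataFrame({
        "probeset_id": np.repeat(probeset_ids, cfg.n_samples),
        "sample_id": np.tile(sample_ids, n_ps),
        "genotype": GENOTYPE_NAMES[g.ravel()],
        "meth_state": STATE_NAMES[state.ravel()],
    })

    return ArraySimResult(probes=probes, reference_probes=reference_probes,
                          reference_genotypes=reference_genotypes,
                          reference_panel=reference_panel,
                          amplicons=amplicons, truth_regions=truth_regions,
                          truth_samples=truth_samples, config=cfg)
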