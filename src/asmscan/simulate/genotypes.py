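"""Block-structured genotype panel for LD pruning and eQTL exercises.

SNPs within a block are generated by a copy-with-mutation scheme: the
first SNP of a block is drawn binomially under HWE; each later SNP copies
the previous SNP's genotype per sample with probability `copy_prob` and
otherwise redraws it independently. Copy probability 1 gives perfect LD
(r-squared 1) inside a block; blocks are mutually independent.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .._rng import substream
from ..errors import ConfigurationError

__all__ = ["simulate_genotype_panel"]


def simulate_genotype_panel(
    n_samples: int,
    n_snps: int,
    ld_blocks: Sequence[int],
    maf: float = 0.3,
    copy_prob: float = 0.9,
    seed: int = 0,
    chrom: str = "chr1",
    spacing: int = 2000,
) -> pd.DataFrame:
    """Return a samples x SNPs dosage DataFrame (values in {0,1,2}).

    Columns are SNP identifiers; a ``attrs['positions']`` Series maps SNP
    to 1-based position on `chrom`. `ld_blocks` must partition `n_snps`.
    """
    if n_samples <= 0 or n_snps <= 0:
        raise ConfigurationError("n_samples and n_snps must be positive counts")
    if sum(ld_blocks) != n_snps:
        raise ConfigurationError(
            f"ld_blocks must partition n_snps: sum {sum(ld_blocks)} != {n_snps}")
    if any(b <= 0 for b in ld_blocks):
        raise ConfigurationError("ld_blocks entries must be positive")
    if not 0.0 < maf < 1.0:
        raise ConfigurationError(f"maf must lie strictly in (0, 1), got {maf}")
    if not 0.0 <= copy_prob <= 1.0:
        raise ConfigurationError("copy_prob must lie in [0, 1]")

    rng = substream(seed, "genotype_panel")
    cols = []
    for size in ld_blocks:
        anchor = rng.binomial(2, maf, size=n_samples)
        block = [anchor]
        for _ in range(size - 1):
            fresh = rng.binomial(2, maf, size=n_samples)
            copy = rng.random(n_samples) < copy_prob
            block.append(np.where(copy, block[-1], fresh))
        cols.extend(block)

    snp_ids = [f"snp{i + 1:05d}" for i in range(n_snps)]
    panel = pd.DataFrame(np.column_stack(cols), columns=snp_ids, dtype=np.int8)
    panel.index = [f"P{i + 1:04d}" for i in range(n_samples)]
    panel.index.name = "sample_id"
    panel.attrs["positions"] = pd.Series(
        np.arange(1, n_snps + 1) * spacing, index=snp_ids, name="pos")
    panel.attrs["chrom"] = chrom
    return panel
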