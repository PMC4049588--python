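"""Documentation-grade plots: allelic-choice matrix and CpG methylation."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["allelic_choice_matrix", "cpg_methylation_profile"]

_CALL_CODES = {"not_het": 0, "filtered_low_intensity": 1, "none": 2,
               "ASM_A": 3, "ASM_B": 4}


def allelic_choice_matrix(calls: pd.DataFrame, mpr_ids=None, ax=None):
    """Samples x MPRs matrix of allelic choice (white: not het, grey:
    biallelic, yellow: ASM on A, blue: ASM on B)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    sub = calls if mpr_ids is None else calls[calls["mpr_id"].isin(mpr_ids)]
    mat = (sub.assign(code=sub["call"].map(_CALL_CODES))
           .pivot_table(index="sample_id", columns="mpr_id", values="code",
                        aggfunc="first"))
    cmap = ListedColormap(["white", "lightgrey", "darkgrey", "gold", "steelblue"])
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, mat.shape[1] * 0.3),
                                      max(3, mat.shape[0] * 0.15)))
    ax.imshow(mat.to_numpy(), aspect="auto", cmap=cmap, vmin=0, vmax=4,
              interpolation="nearest")
    ax.set_xlabel("MPR")
    ax.set_ylabel("sample")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def cpg_methylation_profile(association: pd.DataFrame, amplicon_id: str, ax=None):
    """Per-CpG percent methylation by allele along one amplicon."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = association[association["amplicon_id"] == amplicon_id].sort_values("pos")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(sub["pos"], sub["pct_meth_ref"], "o-", color="goldenrod", label="ref")
    ax.plot(sub["pos"], sub["pct_meth_alt"], "o-", color="grey", label="alt")
    msre = sub[sub["is_msre"].astype(bool)]
    ax.scatter(msre["pos"], np.full(len(msre), -5), marker="^", color="firebrick",
               label="MSRE CpG")
    ax.set_ylim(-10, 105)
    ax.set_xlabel(f"position ({amplicon_id})")
    ax.set_ylabel("% methylated")
    ax.legend(fontsize=8)
    return ax
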