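"""End-to-end pipeline driver: simulate -> QC -> normalize -> call -> classify.

Each stage writes its table to the run directory and appends record
counts to a manifest, so a run reads as a cascade of counts. Reruns with
the same config produce identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .array_qc import classify_amplicons, reference_discrimination_filter
from .calling import build_reference_distribution, call_asm_table
from .errors import AsmscanError
from .io import RunConfig, write_table
from .normalize import normalize_probes
from .population import classify_population, false_positive_assessment
from .simulate import ArraySimConfig, simulate_array_experiment

__all__ = ["run_pipeline", "run_array_stages"]


def run_array_stages(
    sim,
    qc_params: dict | None = None,
    calling_params: dict | None = None,
    population_params: dict | None = None,
) -> dict:
    """Run QC, normalization, calling and classification on one simulation.

    Returns a dict of stage outputs (amplicon classes, normalized probes,
    calls, thresholds, population table, per-sample false-positive
    assessment). This is the in-memory core that `run_pipeline` wraps
    with file IO.
    """
    qc_params = dict(qc_params or {})
    calling_params = dict(calling_params or {})
    population_params = dict(population_params or {})
    k = qc_params.pop("discrimination_k", 2.0)
    classes = classify_amplicons(
        sim.amplicons,
        size_min=qc_params.pop("size_min", 200),
        size_max=qc_params.pop("size_max", 1200),
        msre_snp_maf_max=qc_params.pop("msre_snp_maf", 0.04),
    )
    # discrimination check against the reference panel, MPRs only
    cls_idx = classes.set_index("amplicon_id")["amplicon_class"]
    mpr_panel = sim.reference_panel[
        sim.reference_panel["probeset_id"].map(cls_idx).eq("MPR")]
    disc = reference_discrimination_filter(mpr_panel, k=k)
    failed = set(disc.loc[~disc["passed"], "probeset_id"])
    classes.loc[classes["amplicon_id"].isin(failed), "amplicon_class"] = "excluded"
    classes.loc[classes["amplicon_id"].isin(failed), "reasons"] = \
        classes.loc[classes["amplicon_id"].isin(failed), "amplicon_id"].map(
            disc.set_index("probeset_id")["reasons"])

    # study and reference arrays pass through one joint MNR normalization,
    # so the panel distributions live on the scale the samples are scored on
    mnr_ids = classes.loc[classes["amplicon_class"] == "MNR", "amplicon_id"]
    n_study = len(sim.probes)
    combined = pd.concat([sim.probes, sim.reference_probes], ignore_index=True)
    combined_norm, maps = normalize_probes(combined, mnr_ids)
    probes_norm = combined_norm.iloc[:n_study]
    ref_norm = combined_norm.iloc[n_study:]
    reference = build_reference_distribution(ref_norm, sim.reference_genotypes)

    calls, thresholds = call_asm_table(
        probes_norm, reference, sim.genotypes, classes,
        **calling_params)
    population = classify_population(calls, **population_params)
    fp = false_positive_assessment(calls)
    return {"classes": classes, "probes_norm": probes_norm, "maps": maps,
            "reference": reference, "calls": calls, "thresholds": thresholds,
            "population": population, "false_positive": fp}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the array stages per config and write all artifacts.

    Creates the run directory with probes/reference/amplicon tables, the
    amplicon classification, ASM calls, population classification, the
    per-sample false-positive assessment and a manifest of seeds,
    thresholds and per-stage record counts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed, "stages": []}

    try:
        sim_cfg = ArraySimConfig(seed=config.seed, **config.array)
        sim = simulate_array_experiment(sim_cfg)
    except AsmscanError as err:
        raise AsmscanError(f"stage simulate: {err}") from err
    write_table(sim.probes, outdir / "probes.tsv", "probes")
    write_table(sim.reference_probes, outdir / "reference_probes.tsv", "probes")
    write_table(sim.reference_genotypes, outdir / "reference_genotypes.tsv")
    write_table(sim.reference_panel, outdir / "reference_panel.tsv")
    write_table(sim.amplicons, outdir / "amplicons.tsv", "amplicons")
    write_table(sim.truth_regions, outdir / "truth_regions.tsv", "truth_regions")
    write_table(sim.truth_samples, outdir / "truth_samples.tsv", "truth_samples")
    manifest["stages"].append({"stage": "simulate",
                               "n_probes": len(sim.probes),
                               "n_probesets": sim.amplicons.shape[0]})

    try:
        out = run_array_stages(sim, qc_params=config.qc,
                               calling_params=config.calling,
                               population_params=config.population)
    except AsmscanError as err:
        raise AsmscanError(f"stage analysis: {err}") from err

    write_table(out["classes"], outdir / "amplicon_class.tsv", "amplicon_class")
    write_table(out["calls"], outdir / "asm_calls.tsv", "asm_calls")
    write_table(out["population"], outdir / "population_asm.tsv", "population_asm")
    write_table(out["false_positive"], outdir / "false_positive_assessment.tsv")

    counts = out["classes"]["amplicon_class"].value_counts().to_dict()
    manifest["stages"].append({"stage": "qc_array", **{f"n_{k}": int(v)
                                                       for k, v in counts.items()}})
    manifest["stages"].append({"stage": "call_array", "n_calls": len(out["calls"]),
                               "thresholds": {
                                   s: {"lo": t.mnr_lo, "hi": t.mnr_hi}
                                   for s, t in sorted(out["thresholds"].items())}})
    cls_counts = out["population"]["asm_class"].value_counts().to_dict()
    manifest["stages"].append({"stage": "classify",
                               **{f"n_{k}": int(v) for k, v in cls_counts.items()}})
    manifest["config"] = {"array": config.array, "qc": config.qc,
                          "calling": config.calling,
                          "population": config.population}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
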