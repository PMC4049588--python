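# asmscan

Allele-specific methylation (ASM) screening from methylation-sensitive
restriction enzyme (MSRE) digestion signals on SNP genotyping arrays, with
population-level classification of cis-regulated versus stochastic ASM and
confirmation from allele-resolved bisulfite sequencing reads.

## Who this is for

Epigenomics groups that want to (re)analyse MSRE-digest SNP-array
experiments — or stress-test that analysis before running one — and need
every stage to be verifiable. Because such experiments rarely come with
public raw data, the package ships first-class synthetic-data generators
with known ground truth for the array stage, the bisulfite stage and an
LD-structured genotype panel, so the whole pipeline can be exercised,
calibrated and power-analysed without any external dataset.

## The method

At a heterozygous SNP inside an amplicon carrying ≥ 1 MSRE site (an
*MSRE-positive region*, MPR), digestion ablates the amplicon of an
unmethylated allele. The allele signal is summarised as log2(A/B) probe
intensity, and each sample's post-digest value is z-scored against the
heterozygote log2(A/B) distribution of an undigested reference panel for
that MPR:

    Standard Score = (log2(A/B) − μ_het,panel) / σ_het,panel

Amplicons with no MSRE sites (*MSRE-negative regions*, MNRs) are
digestion-invariant: they provide (i) the invariant set for between-array
quantile normalization (variant probesets are mapped through the per-array
monotone raw→normalized interpolation), and (ii) a per-sample null score
distribution. A sample's MPR is called ASM on the A allele when its
Standard Score exceeds the sample's 97.5th MNR-score percentile (B allele:
below the 2.5th percentile), so by construction a null MPR is called ASM
~5% of the time. Biallelically unmethylated regions — whose allele ratio is
pure background — are removed first by an intensity-ratio filter (sample
total intensity over panel total < 0.2).

Across a population, calls per SNP are aggregated: with ≥ 6 informative
heterozygotes and ≥ 6 ASM events, a two-sided exact binomial test of
allelic choice (p = ½) separates *cis-regulated* ASM (all events on one
allele; 6 unanimous events is the smallest count with p < 0.05) from
*candidate-random* ASM. Candidates are then annotated: greedy LD pruning
(pairwise r² < 0.3 over random scan orders), GWAS-catalog proxy overlap
(r² > 0.8), 2×2 chi-square enrichment, genic context, and a Spearman +
min-p permutation cis-eQTL scan.

Confirmation uses reads that observe the SNP allele and CpG methylation on
the same molecule: after conversion-rate QC (non-CpG cytosines ≥ 95%
converted), a binomial ML genotype caller (depth ≥ 20, GQ ≥ 20), an exact
Hardy-Weinberg filter (Levene/Wigginton, p ≥ 0.01) and a MAF sanity check,
each CpG gets an allele × methylation 2×2 chi-square with uncapped
Bonferroni adjustment and a direction-consistency check against the array
call.

## Worked example

```python
from asmscan.simulate import ArraySimConfig, simulate_array_experiment
from asmscan.pipeline import run_array_stages

cfg = ArraySimConfig(n_samples=42, n_mpr=800, n_mnr=500, seed=1)
sim = simulate_array_experiment(cfg)          # probes, panel, annotation, truth
out = run_array_stages(sim)                   # QC -> normalize -> call -> classify

print(out["population"]["asm_class"].value_counts().to_dict())
print(out["population"].query("asm_class == 'cis_regulated'").head(3))
```

Output:

```
{'some_asm': 427, 'no_asm': 321, 'cis_regulated': 44, 'candidate_random': 8}
   mpr_id     n_het  n_asm_A  n_asm_B  n_filtered  binomial_p     asm_class cis_allele
MPR000019     17       12        0           0    0.000488  cis_regulated          A
MPR000067     12       10        0           0    0.001953  cis_regulated          A
MPR000074     12        0        9           2    0.003906  cis_regulated          B
```

Reading this: of 800 MPRs, 44 are classified cis-regulated — the generator
planted 46 true cis MPRs at these settings (42 samples, 5% cis fraction,
penetrance 0.8), so recovery is near-complete with the misses lacking
enough expressing heterozygotes. `MPR000019` shows 12 of 17 heterozygotes
with ASM, all on the A allele (binomial p = 2·(½)^12 ≈ 5 × 10⁻⁴):
incomplete penetrance with unanimous allelic choice, the cis signature.
The per-sample false-positive table (`out["false_positive"]`) reports each
sample's observed ASM rate against the 5% the MNR cutoffs construct; with
true ASM present the mean rate here is 10.8%, a 2.2-fold excess.

The same flow is available from the shell:

```bash
asmscan run --config demo.yaml          # simulate + full array pipeline
asmscan qc-array --amplicons amplicons.tsv --out classes.tsv
asmscan confirm-bsseq --reads reads.tsv --cpgs cpgs.tsv --out assoc.tsv
```

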