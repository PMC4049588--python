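# Methods

This note documents the models, defaults and numerical choices behind
`asmscan`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The array-stage generative model

The simulator (`asmscan.simulate.array`) inverts the MSRE-digest assay
into a sampling procedure with known truth.

**Truth assignment.** Each MPR independently receives a class: cis-ASM
with probability `cis_asm_fraction` (allele A or B with probability ½
each), stochastic ASM with probability `random_asm_fraction`, otherwise
no ASM. MNRs never carry a digestion-sensitive class.

**Genotypes.** Per probeset × sample, genotypes are drawn under
Hardy-Weinberg equilibrium at the configured MAF (default 0.3). The
heterozygote count per MPR therefore varies binomially, which exercises
the ≥ 6-heterozygote eligibility rule naturally rather than by
construction.

**Methylation states.** Every probeset × sample has one of four states:
biallelic methylated (the default), biallelic unmethylated (probability
`biallelic_unmeth_fraction`, default 0.10 — this produces the
low-total-intensity cloud that the ratio filter exists to remove),
mono_A or mono_B. Monoallelic states occur only at heterozygotes of
ASM-class MPRs, with probability `penetrance` (default 0.8; cis-ASM is
observed with incomplete penetrance in real populations). Stochastic-ASM
heterozygotes choose mono_A vs mono_B by fair coin.

**Digestion.** Methylated allele copies are protected. Unmethylated
copies at a locus escape digestion *together* with probability
1 − `digestion_efficiency` (default efficiency 0.95): cutting failure is
modelled as a property of the digest reaction at that locus, not of the
individual homologous amplicon. This matters for calibration — if the
two homologues escaped independently, a biallelically unmethylated
heterozygote would produce a perfect mock-ASM signal (one allele at full
intensity, one at background, intermediate total intensity that passes
the ratio filter) at rate ≈ 2·e(1−e), and no construction could deliver
the 5% null ASM rate the MNR percentiles are designed to give. MNRs are
never digested.

**Intensities.** Channel intensity is
`baseline × affinity_channel × (retained_copies + background_fraction) × noise`,
with per-probeset, per-channel affinities (lognormal, `probe_affinity_sd`
= 0.7 in log2 units), multiplicative lognormal probe noise (`noise_sd` =
0.15 log2 units, resampled per replicate), an optional per-array scale
distortion (`array_scale_sd` = 0.25 log2 units; this is what
normalization removes), and a background floor (`background_fraction` =
0.02 of baseline) for ablated amplicons. The affinity term is essential,
not cosmetic: it gives each probeset a nonzero heterozygote log2(A/B)
center, which is the entire reason the method standard-scores against a
per-MPR reference distribution, and it gives the MNR intensity
distribution the broad, smooth shape that makes quantile normalization
well-behaved. The assay publishes no quantitative noise model; these
magnitudes are calibration choices fixed once.

**Replicates and reference panel.** Digestion happens once per sample; a
configurable number of arrays (default 2, matching a run-in-duplicate
design) share the digest but draw independent probe noise and array
scale. The reference panel (default 90 undigested samples, the size of a
classic HapMap population panel) is generated from the same affinities
and noise model.

## 2. Normalization

Between-array normalization uses only the invariant (MNR) probesets:
each array's sorted MNR intensities (A and B channels combined into one
pool per array) are replaced by the across-array mean of sorted values;
ties map to the average of their ranks' targets. The resulting raw →
normalized knot pairs define a monotone piecewise-linear map applied to
all probesets of that array; values outside the knot range are
extrapolated linearly from the boundary segment. Extrapolated values
below the lowest knot can be negative; such values only arise from
background-level (biallelically unmethylated) signal that the intensity
ratio filter removes downstream, and logs floor intensities at 10⁻⁶.

A single map serves both channels of an array, preserving within-probeset
A/B ratios up to the map's local slope. Whether the original analysis
normalized channels jointly or separately is not documented; the joint
map minimizes distortion of log2(A/B) and is the package's choice.

**Panel consistency.** Study arrays and reference-panel arrays are
normalized jointly, and the per-MPR reference distributions (heterozygote
log2(A/B) mean/sd, genotype cluster statistics, mean heterozygote total
intensity) are computed on the normalized scale. Scoring normalized
sample values against raw-scale panel statistics injects probeset-level
distortions (the map is locally nonlinear) and measurably inflates the
null call rate.

## 3. ASM calling

Per sample × MPR, replicate log2(A/B) values and totals are averaged
(`replicate_rule="mean"`), z-scored against the panel heterozygote
distribution, and filtered at intensity ratio < 0.2. Cutoffs are the
sample's own MNR Standard-Score percentiles at 2.5/97.5, computed with
linear interpolation between order statistics (the "type 7" convention;
the method's source describes only "percentiles"). Thresholds are open
intervals: a score exactly at a percentile is not ASM (conservative).

`replicate_rule` also supports `both` (call only when every replicate
crosses the same cutoff) and `either`. The default is `mean` because the
method's stated calibration — MNR cutoffs that exclude 95% of MNRs hence
a 5% false-positive rate on null MPRs — only holds when one score per
sample is compared against thresholds built the same way; a
both-replicates concordance rule drives the null rate to ≈ 2·0.025²,
two orders of magnitude below the design value.

**Residual calibration bias.** The empirical-percentile construction has
a small intrinsic exceedance bias for *new* draws: with m MNR scores, the
expected out-of-interval rate is ≈ 5% + O(1/m). At the desk-scale null
simulation (2,000 MNRs → ~840 heterozygous MNR scores per sample) this
contributes roughly +0.2 percentage points; it vanishes as the MNR count
grows toward assay scale (~150,000).

## 4. Population classification

Per SNP: heterozygotes are samples whose call is none/ASM_A/ASM_B
(ratio-filtered samples are counted separately and are not informative).
Classes: `insufficient` (< 6 heterozygotes), `no_asm`, `some_asm`
(1–5 events), and with ≥ 6 events either `cis_regulated` (unanimous
allelic choice) or `candidate_random`. The two-sided exact binomial p
(minimum-likelihood definition, p = 1 for empty data) is always
reported; 6 unanimous events is the smallest count with p < 0.05, which
is where both defaults come from. A `cis_rule="binomial"` variant admits
significant non-unanimous SNPs for users who prefer the test over
unanimity; unanimity is the default because the cis definition in the
method's source is "all events on one allele". Failure to reject the
null for mixed SNPs is not evidence of imprinting and the package draws
no such inference.

The per-sample false-positive assessment compares each sample's observed
ASM count among assessed heterozygous MPRs with the 5% expectation, with
a one-cell-vs-rest chi-square goodness-of-fit p.

## 5. LD, annotation and eQTL scan

r² is the squared Pearson correlation of genotype dosages over
pairwise-complete samples (composite LD; no phasing required — an
EM-based haplotype r² is out of scope). Greedy pruning scans SNPs in a
seeded random permutation and keeps a SNP iff r² < 0.3 against all
already-kept SNPs; repeated prunes with different seeds reproduce the
"ten random pruned sets" design, and every output satisfies the pairwise
bound. Proxy matching to a catalog accepts identity or r² > 0.8.
Enrichment between SNP sets is the uncorrected 2×2 Pearson chi-square
(Yates correction available); a helper restricts supplied GWAS-catalog
tables to stringent entries (p < 10⁻⁷, initial sample size ≥ 500), and an
optional binned-sampling step (10 equal-width MAF bins over (0, 0.5])
draws MAF-matched background SNP sets for the comparison. Gene context is genic iff the position
falls in a 5′UTR/3′UTR/exon/intron interval (1-based inclusive; BED
converted at the boundary), otherwise the distance to the nearest gene
boundary is reported.

The cis-eQTL scan computes Spearman correlations between dosage and
expression for SNPs within 1 Mb of the TSS; the per-gene null is the
minimum nominal p over cis SNPs in each of 10,000 independent expression
permutations, and a SNP is significant iff its nominal p falls *below*
the 5% quantile of that null. The method's textual source says "greater
than the 0.05 tail", which contradicts the standard permutation
procedure it cites; it is read here as a transcription slip.

## 6. Bisulfite confirmation

The read generator draws sample genotypes under HWE at the amplicon SNP
MAF; each read samples one chromosome uniformly, methylates each CpG
with that allele's probability, and applies conversion failure (default
1.3%, i.e. a 98.7% conversion rate) that makes unmethylated cytosines —
CpG and non-CpG alike — read as methylated. Read dropout (default 10%)
removes the SNP observation from a read. Reads are not filtered by their
own conversion rate (that would bias against genuinely methylated reads
via correlated non-CpG methylation); instead whole samples fail QC when
their mean non-CpG conversion is below 95%.

Genotypes come from a symmetric-error binomial likelihood over
{ref_hom, het, alt_hom} with a uniform prior; GQ is −10·log10 of the
non-best posterior mass, capped at 99. QC drops amplicons failing
depth ≥ 20 / GQ ≥ 20 in a majority (> 50%) of samples, then samples
failing in a majority of remaining amplicons, repeats both steps once
(the order is fixed and logged; the source does not specify one), then
drops amplicons with exact HWE p < 0.01 or an observed-vs-expected MAF
relative mean difference > 0.25. The HWE test evaluates the Levene
conditional distribution of heterozygote counts by log-factorials; the
test suite checks it against a recurrence oracle and, for small n, a
brute-force allele-slot enumeration.

Association at each CpG is the uncorrected 2×2 chi-square of allele ×
{M, U} over reads from heterozygous samples only (homozygote reads carry
no allele contrast; they are retained for per-genotype summaries). Reads
missing the allele or that CpG's state are excluded — the assay requires
both on one molecule. A zero row/column margin leaves the statistic
undefined (reported NA). Bonferroni adjustment is uncapped
multiplication by the number of tests (adjusted values above 1 are
reported as-is, keeping ranks comparable), with m defaulting to the
number of CpG tests in the run. Ties in the methylated-allele label go
to ALT — a display convention, not biology. Direction consistency maps
the array's A/B call onto ref/alt via the amplicon metadata and compares
it with the sequencing methylated allele.

## 7. What the simulations do and do not show

The generators reproduce the statistical structure the analysis relies
on: HWE genotypes, four methylation states, digestion ablation with
locus-level escape, multiplicative probe noise with probe-specific
affinity, array-level scale distortion, conversion failure and read
dropout. They do not model raw fluorescence or CEL-level artifacts,
sequence-dependent probe cross-hybridization, PCR amplification bias
beyond uniform dropout, homopolymer indel errors, batch structure, or
relatedness between samples (the real study contained twin pairs).
Passing tests therefore demonstrate the *procedural* correctness and
calibration of the analysis under its own assumptions, not robustness to
every artifact of a physical experiment.

**Problem sizes.** The shipped checks use 40 samples × 3,000 MPRs +
2,000 MNRs (null calibration), 600 MPRs at 30% cis fraction (recovery),
and tens of amplicons × tens of samples (bisulfite); these sizes give
Monte-Carlo standard errors small enough for the stated tolerances while
keeping a full run in tens of seconds, and are the package's chosen
defaults for its own verification.

## 8. Known limitations

- The empirical-percentile exceedance bias (+O(1/m), §3) is visible at
  small MNR counts; users thresholding on rates near 5% should use
  ≥ a few thousand MNRs.
- The genotype caller ignores mapping/base quality (inputs are already
  allele-resolved calls); its GQ is therefore optimistic at high depth.
- `min_samples_for_significance` assumes unanimous events; it is a floor
  for the unanimity rule, not a general power calculation.
- The eQTL permutation scan recomputes the permutation null per gene and
  is O(n_perm × samples × cis-SNPs); it is intended for targeted panels,
  not transcriptome-wide scans.
- Greedy pruning is order-dependent by design; only the pairwise-r²
  postcondition, not the kept set itself, is stable across seeds.
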