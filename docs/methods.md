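# Methods

## The screen

`imprintscreen` implements a computational screen for maternally imprinted
loci built on a single contrast: a **bimaternal** (parthenogenetically
activated, PA) embryo carries two maternal genomes, so a maternal germline
differentially methylated region (gDMR) is ~fully methylated on both
alleles; a **biparental** control (CN) embryo carries one methylated
maternal and one unmethylated paternal allele, so the same region sits
near 50% methylation. The pipeline turns this contrast into four stages:

1. **Promoter methylation ranking** (`profile`). Per-read CpG calls are
   aggregated into per-CpG methylated/unmethylated counts; sites covered
   by fewer than 3 reads are discarded. For each transcript the unweighted
   mean CpG methylation ratio over the promoter window (TSS ± 2 kb) is
   computed per sample, averaged within group, and transcripts are ranked
   by the ratio `(mean_PA + ε) / (mean_CN + ε)` with pseudocount ε = 0.01.
   The list is truncated to the top 100 transcripts with ratio ≥ 1.2 and
   re-sorted by the first PA replicate's promoter mean, so loci with the
   strongest bimaternal methylation surface first. Ties break on
   transcript id, making the ranking invariant to input order.
2. **Promoter DMR calling** (`dmr`). Within the candidates' promoter
   windows, CpGs covered in *every* sample of both groups are segmented
   into runs with inter-CpG gap ≤ 300 bp; runs are split at stretches of
   ≥ 3 consecutive CpGs whose group difference is weak (|Δ| < 0.1) and
   end-trimmed of weak CpGs — together these isolate the differential
   plateau the way recursive binary segmentation would, while staying
   deterministic. Runs with ≥ 10 CpGs are tested with a Wilcoxon
   signed-rank test of the per-CpG paired group-mean differences against
   zero, and retained when the absolute mean difference is ≥ 0.2.
   Benjamini–Hochberg adjustment runs in one batch across all tested runs
   of an invocation; calls require q < 0.05. All four thresholds are
   attainable bounds (gap of exactly 300 bp joins; a difference of exactly
   0.2 passes; 10 CpGs suffice).
3. **Read-level hemi-methylation** (`hemimeth`). Allele-specific
   methylation is detected without SNPs: each read is wholly from one
   allele, so in a biparental sample reads over a gDMR split into a
   near-fully methylated and a near-fully unmethylated class. A *qualified
   read* carries ≥ 3 CpG calls inside the region; reads with a methylated
   fraction ≤ 20% are hypomethylated and ≥ 80% hypermethylated (the 0–20%
   / 80–100% ranges are taken as inclusive, which matters for a 5-CpG read
   with exactly one methylated CpG). A region is judged only with more
   than 30 qualified reads, and is *hemi-methylated* when ≥ 30% of
   qualified reads are hypo- and ≥ 30% hypermethylated; a class holding
   ≥ 80% of reads makes it hyper-/hypo-dominant instead. Fractions are
   computed over all qualified reads, intermediates included. Per-read
   pattern matrices (M/U/not-covered) require ≥ 10 reads each covering ≥ 3
   consecutive region CpGs; the consecutive-CpG rule applies only to
   matrices, not to region classification, since the two serve different
   displays.
4. **Allelic expression** (`ase`). Heterozygous SNPs are called from
   genomic allele counts (depth ≥ 10, minor fraction ≥ 0.25). At each het
   SNP, RNA counts from the same individual are classified: monoallelic
   when the major allele holds ≥ 90% of ≥ 10 reads and an exact two-sided
   binomial test against 0.5 rejects at α = 0.01; biallelic when the minor
   allele holds ≥ 20%. A transcript is an imprinted candidate when every
   informative SNP × tissue call is monoallelic (direction may differ
   between individuals — phase is unknown), and biallelic when biallelic
   calls appear in ≥ 2 tissues. The 0.90/0.20/α = 0.01 rule is this
   package's own conservative default: imprinting surveys of this kind
   typically report raw allele counts and qualitative conclusions, not
   numeric cutoffs.
   Strain-diagnostic homozygous SNPs from reciprocal crosses can be
   supplied as phased markers, in which case allele fractions read
   directly as maternal/paternal.

`expression_stats` supplies the surrounding statistics: TPM
(length-normalized, summing to 10⁶ per sample), Welch's two-sample t-test
with Satterthwaite degrees of freedom, BH FDR, plain fold changes of group
means, and the DEG rule |log2FC| > 1 with FDR < 0.05 (both strict).

## The signed-rank test

The per-run test must be exact for small runs and well-defined when many
per-CpG differences are identical — tied magnitudes are the norm in
promoter windows. The null distribution of the rank sum of positive
differences, conditional on the observed |differences| (midranks for
ties, zeros dropped), is computed by dynamic programming over all 2ⁿ sign
assignments for n ≤ 25; the two-sided p-value is the probability of a rank
sum at least as far from its mean as observed. Above n = 25 a tie-corrected
normal approximation (σ² = Σrᵢ²/4, no continuity correction) takes over.
With n all-same-sign differences the exact two-sided p is 2·(1/2)ⁿ.
Off-the-shelf exact implementations decline ties, which is why this
primitive is authored here; the n = 10 case is verified against exhaustive
enumeration in the tests.

## The simulator

The generator works at methylation-call level: no nucleotide sequences and
no alignment, because the analysis consumes exactly per-read CpG calls. A
diploid methylome is a pair of per-CpG methylation probabilities; each
read picks one allele uniformly (the physical linkage that makes
hemi-methylation detectable), calls each covered CpG from that allele's
probability, and flips the observed state with probability
`conversion_error` — one symmetric parameter standing for bisulfite
non-conversion plus sequencing error. Read starts are uniform over the
locus with the read count chosen so expected per-CpG coverage equals
`depth`. CpG positions have geometric gaps (mean = `cpg_spacing`, floor
2 bp).

Archetype parameters for a maternal gDMR: maternal allele 0.95 methylated
per CpG, paternal 0.05, background 0.05 (CpG-island promoters are
unmethylated outside imprints; gene bodies can be planted at 0.8 where
body-vs-flank contrast is wanted). ASE truth is a maternal read fraction θ
per transcript (1 = maternal-only, 0.5 = balanced); DNA counts are
Binomial(depth, 0.5), RNA counts Binomial(depth, θ or 1−θ).

The default screen dataset plants one maternally imprinted gene among 50
plus-strand genes at 6 kb pitch (gDMR = TSS ± 1 kb), CpG spacing 20 bp,
read length 150 bp, depth 20×, conversion error 0.01, with 2 PA and 2 CN
samples — matching the n = 2-per-group replicate structure and per-CpG
depth scale a desk-size WGBS contrast provides. These sizes keep a full
replicate under ~3 s so recovery rates can be estimated over 50 seeds.

What the simulator does *not* emulate: sequence-dependent coverage bias,
PCR duplicates, bisulfite strand asymmetry at SNPs, partially methylated
domains, or biological variability between replicates beyond binomial
sampling. Passing recovery tests therefore demonstrate the pipeline's
logic and thresholds, not its performance on real tissue WGBS.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere internally; VCF positions
  convert at the I/O boundary. CpG dyads are merged onto the plus-strand C.
- Threshold comparisons that can land exactly on a float boundary (a read
  with 1/5 CpGs methylated; a planted difference of exactly 0.2) carry a
  1e-9..1e-12 epsilon so the inclusive semantics survive rounding.
- Promoter means are unweighted across CpGs (not coverage-weighted);
  windows with no covered CpG are undefined and excluded from ranking.
- Metagene bodies are rescaled into 100 bins with exact integer bin
  arithmetic (mirror-symmetric, so minus-strand orientation flipping is an
  involution); bodies shorter than the bin count contribute by
  nearest-fraction assignment.
- `welch_t` on two zero-variance groups returns t = 0, p = 1 when means
  agree and raises otherwise; groups need n ≥ 2.
- A region with fewer than 31 qualified reads reports
  `insufficient_support` rather than a methylation state; a DMR scan with
  no eligible runs returns an empty result, not an error.
- Fold change with a zero denominator is NaN (flagged, not raised), since
  it appears inside bulk tables.

## Open design points, resolved

- Replicate promoter means are averaged within group *before* the PA/CN
  ratio (not ratios of per-replicate pairs).
- The ortholog-intersection step of the original candidate list is
  replaced by an optional user-supplied keep-list; no ortholog database is
  bundled.
- The hemi stage of `run_screen` evaluates each called DMR over its
  *partially methylated subregion* — the span of CpGs whose CN-group mean
  is in [0.25, 0.75] — because DMR boundaries can carry flanking
  unmethylated CpGs that dilute the read-class fractions; this mirrors how
  partial methylation defines the regions fed to read-level analysis.
- The 30%+30% hemi rule counts intermediate reads in the denominator.
- Welch's t is exposed and labeled as such for expression comparisons;
  no negative-binomial/DESeq2-style model is reproduced.

## Problem sizes

Default test and acceptance runs use: 50-gene loci (≈ 15,000 CpGs, ≈ 130k
reads across 4 samples) × 50 replicates for screen recovery; 200
replicates for ASE recovery and for the hemi sensitivity property;
exhaustive 2¹⁰ enumeration for the signed-rank oracle. A full planted
screen replicate takes ≈ 2–3 s on one core.
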