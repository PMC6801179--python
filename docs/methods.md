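# Methods

This note documents the models, parameter choices and numerical
conventions behind `probioqc`, and what the synthetic-data tests do and
do not demonstrate about real data.

## The synthetic study

The generators emulate a commercial 8-strain blend analysed end to
end. Defaults are the study conditions; they are set once and all
tests and the acceptance script run against them.

**Genomes.** Eight 20-kb random nucleotide sequences, one per strain,
with 900-bp ORFs tiled on alternating strands every 1200 bp (75%
coding density, comfortably above the >50% contract). The
*B. animalis* subsp. *lactis* pair (BI04/BL03) is constructed, not
drawn independently: BL03 is a copy of BI04 with one substitution at
each of four diagnostic SNP positions (spread through the genome,
inside ORFs, clear of the indel) and one 54-bp codon-aligned deletion
in the middle of an ORF. One additional locus carries an allele shared
by the whole panel, so the tally logic is exercised on uninformative
positions. A 20-kb genome keeps every alignment desk-scale while
leaving the discriminating fraction of pair reads realistically small
(~3% of pair reads cover a diagnostic position at 150-bp reads).

**Reads.** Single-end 150-mers; the strain of origin is drawn from the
blend abundance vector (63.4, 12.7, 4.55, 9.9, 7.2, 1.7, 0.4, 0.2)% —
normalized to sum exactly to 1 — the start position uniformly, and
substitution errors independently per base (default rate 0.001,
roughly post-filter short-read quality; the error model is
substitution-only so identity arithmetic stays exact). Paired-end
merging is upstream of this package and not modelled.

**Cytometry.** Each subpopulation is a log-normal cluster per channel
(instruments collect these as logarithmic signals): live cells
SYTO24-bright/PI-dim (log₁₀ FL1 = 4.5, FL3 = 1.5), damaged bright/bright
(4.5, 3.5), dead dim/bright (2.0, 3.5), all with sd 0.15 — inter-cluster
separations of ≥ 2.5 log₁₀ on the discriminating axis, comfortably
above the 1.5 log₁₀ the gating-recovery property requires. Fractions
default to 82/9/9% (dead cells in the high single digits, as in a
well-made freeze-dried product). Counting beads form a separate
FL2-bright cluster; the bead count is exact by construction.

**cFSE / urease.** A single log-normal fluorescence population
(log₁₀ mean 4.0, sd 0.05) in which a 52.1% subpopulation is
urease-positive; after urea its linear fluorescence is multiplied by
1.6 (a 60% shift). The CCCP and flurofamide control tables redraw the
pre-urea distribution, i.e. the shift is fully inhibited. The overall
percent-increase statistic therefore has expectation
0.521 × 60% ≈ 31.3%.

**Kinetics.** OD₄₂₀(t) = intercept + slope·t + N(0, σ²), 60 readings at
30-s intervals; default slope 8.8 mOD min⁻¹ and σ = 0.5 mOD. The noise
models plate-reader read noise only, not between-replicate biological
variation, so replicate sds are much smaller than those of a real
assay; the estimator checks (exactness, unbiasedness) are unaffected.

**qPCR.** Ct = 38.0 − 3.32·log₁₀(cells) + N(0, 0.2²), triplicates per
sample; the −3.32 slope corresponds to ~100% amplification efficiency
(10^(−1/slope) − 1).

**LFQ.** 207 proteins per strain (1656 total, near the ~1650 a deep
lot characterization identifies); base log₁₀ intensity uniform on
[5, 10]; replicate noise sd 0.05 (Pearson r between replicates ≈ 0.96);
3.2% of proteins receive a ±1.2 log₁₀ lot effect; 1% of cells are set
to zero (missing). Missing values are encoded as literal zero
intensity, matching the upstream convention.

All generators draw from one `numpy` Generator seeded per operation,
record the seed on their output, and are byte-identical across reruns.

## Read assignment and abundance

Assignment scores a read against every panel genome in both
orientations. Exact substring matches short-circuit (identity 1);
otherwise the best semi-global (infix) placement is found with edlib,
capped at 10% edit distance so sub-threshold identities near the
cutoff are still reported, and identity is matched columns over
alignment columns. A read is unassigned when shorter than 80 bp, when
the best identity is ≤ 0.98, or when the alignment spans less than 90%
of the read — the span rule substitutes for E-value screening, which
is database-size-dependent and meaningless on a toy panel. Ties across
orientations break toward forward; the primary winner among tied
strains follows panel order, deterministically.

Abundance counts a read for a strain when its alignment midpoint (on
that strain's own coordinates) lies inside an annotated ORF; the
midpoint rule makes ORF-boundary behaviour deterministic. Ties —
essentially all reads from the near-identical pair — are split
equally, which preserves the pair's total abundance but not its
internal ratio; `apportion_pair` then re-splits the pair total by the
diagnostic-SNP percentage. An alternative reading of "ORF count"
(number of distinct ORFs detected per genome) is available behind
`count_mode="distinct_orfs"`; reads-hitting-ORFs is the default.

## Pair deconvolution

Allele calling matches a ±7-bp haplotype window per allele (the
reference context with the allele substituted, or with the base
removed for single-base deletion alleles) against the read by edit
distance; the best window must be unique and within distance 1, reads
must cover the position with ≥5 bp of flank on both sides (avoiding
end-of-read gap artifacts), and anything matching no listed allele
lands in an explicit other-bucket. Window matching sidesteps the
mismatch-vs-gap ambiguity of unit-cost alignment at deletion alleles.

Both aggregations of the strain percentage are exposed because they
genuinely differ on the published worked example: per-position
ratios averaged give 73.6%/26.4% on counts (43 vs 17) and (37 vs 12),
while pooling the counts first gives 80/109 = 73.4%. The per-position
mean is the default; the package treats the choice as a documented
ambiguity rather than resolving it.

## Gating and absolute counts

Gates are rectangles in (log₁₀ FL1, log₁₀ FL3) applied after an FSC
threshold (default 5000) and after bead identification on log₁₀ FL2;
disjointness is validated at construction and asserted per event.
`GateSpec.from_cluster_means` places boundaries at midpoints between
cluster means — a synthetic-data convenience, not a substitute for
operator gating on a real instrument. Damaged cells are excluded from
viable totals. Bead stock concentration is a required input
(vendor-lot-specific); the pipeline default (1.16 × 10⁸ beads/ml at
1:100 dilution, 0.1 g/ml suspension) is sized so the default
simulation reads ~3.8 × 10¹¹ live cells per gram — a well-formulated
product several-fold above a 10¹¹ label claim.

Lot comparisons use Student's equal-variance unpaired t-test by
default (Welch behind a flag), two-sided, α = 0.05; with zero variance
in both groups p is 1 for equal means and 0 otherwise by convention.

## Enzyme statistics

The urease percent increase is computed on linear fluorescence (the
statistic is scale-invariant; log display is presentation only).
The optional shift boundary — placed at the geometric midpoint of the
unshifted and shifted means — estimates the urease-positive fraction;
with the default 0.05 log₁₀ within-population sd, misclassification on
the two sides of the boundary nearly cancels at fractions near 50%,
so the estimate is within binomial error of truth. Control checks pass
when the urea shift exceeds, and both control shifts stay below, a 20%
tolerance reflecting the analytical imprecision of the assay. The
P1/P2 subpopulation split is handled as user-supplied gates; no
bimodality detection is attempted.

β-galactosidase AU is the OLS slope over the full 30-min window by
default; whether a linear-phase subwindow was selected upstream is not
specified, so a `window_min` option allows restriction. Time is
converted to minutes once, so AU is per minute despite 30-s sampling.

## Proteomics

The filter keeps proteins with ≥2 peptides, ≥1 unique, ≥1 unmodified;
decoys are deleted; contaminants are kept but flagged and excluded
from the headline differential count (they class separately in the
volcano output). "log" is base 10 throughout: housekeeping-table
values around 9.5 match log₁₀ of typical LFQ intensities (~10⁹), and
the factor-10 rule reads |log₁₀ ratio| > 1. The 4.3 imputation floor
is also applied as a lower clip to measured values so the transformed
matrix never dips below it. The headline call applies no
multiple-testing correction, mirroring the raw p < 0.01 + fold-change
rule; BH q-values are emitted as an extra column. The housekeeping
table reports plain log₁₀ LFQ per replicate (any size correction
upstream is opaque at this layer), sorted by descending row mean, with
absent proteins rendered as constant 4.30 rows.

Under the null, the dual rule is far stricter than p < 0.01 alone: a
|log₁₀ ratio| > 1 between 3-replicate means with sd 0.05 essentially
never occurs, so the null call rate is ~0 while the t-test alone
rejects at its nominal 1%.

## qPCR

Calibration is OLS of Ct on log₁₀(cells) over ≥3 distinct standards;
amplification efficiency is reported as 10^(−1/slope) − 1. Replicates
are back-transformed individually and then averaged — the reported sd
is in cell space, matching the ± format of a product-quantification
table — and back-transform-then-average deliberately differs from
average-then-back-transform (the former carries a small lognormal
bias, ~+1% at 0.2 Ct noise, tested explicitly). Quantification more
than 2 cycles outside the calibrated range warns of extrapolation.
Loads are in flow-cytometry fluorescence-unit (FU) equivalents, since
standards are counted cytometrically.

## Problem sizes

The default test and acceptance runs use 20-kb genomes, 50 000 reads
for abundance recovery, 20 000 cytometry/cFSE events, 10 000 proteins
for null calibration, and 100 seeds for estimator-bias checks; these
sizes put binomial/regression sampling error well inside the asserted
tolerances while keeping any single check in the seconds-to-a-minute
range.

## Limitations

Synthetic genomes are i.i.d. random sequence: no repeats, no shared
gene families, no conserved operons — so cross-strain mapping ambiguity
is limited to the constructed near-identical pair, and real
metagenomes will show more ties and lower assignment rates. The error
model has no indels or quality-dependent structure; the cytometry
model has no spectral spillover, doublets or debris; the LFQ model
has no peptide-level structure, intensity-dependent missingness, or
shared peptides. Passing recovery tests therefore demonstrates the
correctness of the estimators under their stated models, not
instrument-grade performance. The resistome screen compares against
whatever reference FASTA the user supplies; it ships with no
resistance-gene database.
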