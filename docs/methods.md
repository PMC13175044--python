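# Methods

This note records the models, parameter choices and numerical decisions
behind each module, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Synthetic data

The generators exist so that every downstream analysis can be validated
against planted truth. They emulate the *signal structure* of pooled
resequencing and whole-genome-alignment output, not the reads
themselves: there is no read-level simulation, no alignment and no
variant calling.

**Genome and sex architecture.** Chromosome sequences are uniform
i.i.d. A/C/G/T. A `GenomePlan` plants 0-based half-open intervals of
two kinds on a diploid, male-heterogametic (XY) background:
Y-hemizygous intervals (copy number 1 in males, 0 in females) and
X-differentiated intervals (1 in males, 2 in females). Intervals must
be non-overlapping; a ZW system is obtained by swapping sex labels.

**Pooled depth.** Per-base depth is negative binomial with mean
`mean_depth × copies/2` and size parameter `dispersion` (Poisson in the
infinite-dispersion limit). Defaults `mean_depth = 40`, `dispersion =
5` represent a deeply sequenced Illumina pool with realistic
overdispersion (variance ≈ m + m²/5). A `contamination` rate (default
0) adds Poisson stray reads where copy number is zero, to probe the
strictness of the zero-female-depth rule; index hopping and mapping
noise are otherwise not modelled, which is why the strict zero default
is viable here and configurable for real data. Depth is drawn
independently per base; real depth is autocorrelated, so the simulated
tracks understate the run-length variance of real pools — recovery
results should be read as upper bounds on real-data performance.

**Pooled SNPs.** SNPs are placed uniformly at `snp_density` (default
1/kb). Sex-specific SNPs follow a Y-gametolog model: the alternate
allele sits at frequency 0.5 in every male pool (one Y copy against one
X copy) and 0 in every female pool. The allele-frequency structure of
real sex-specific SNPs is not observable from the source data, so this
idealisation is an assumption of the generator, with a background
sex-specific fraction (default 0.005) multiplied by `sexsnp_enrichment`
inside X-differentiated intervals. Read counts per pool are Poisson at
the copy-number-scaled mean with binomial allele sampling.

**Fragmented SVs.** True events are split into k (default 3–8)
reference- and query-consecutive sub-blocks of the same type and
orientation, each > 5 kb, mimicking annotators that report one long
rearrangement as many tandem blocks; decoy blocks ≤ 5 kb are added and
fall below the length filter. Placement enforces one identifiability
property: within a (ref chrom, qry chrom, type, orientation) group,
consecutive events receive query intervals running against the
orientation's direction. Two same-type events that were ref-adjacent
*and* query-colinear would, by definition of the merge rule, constitute
a single event; the generator therefore never plants that
configuration, and round-trip recovery (fragment → filter → merge) is
exact for all seeds.

**Redundant repeat libraries.** Each family consensus (≥ 100 b;
fixtures use 1.2 kb) is tiled into fragments whose adjacent pairs share
at least `overlap` bases, then mutated at `mutation_rate` substitutions
per base. Fixtures use 0.005: fragments of one family in a combined
library derive from consensus building over the same genomes, so
sub-percent divergence is realistic, and it keeps expected pairwise
overlap identity ~99 %, well clear of the 95 % join threshold. This
margin matters: overlaps whose realised identity falls below the
threshold are *correctly* left unjoined (a tested property), so a
high-divergence library reaches a fixpoint with more sequences than
families.

**Pairing counts.** Paired cells per (chromosome, individual) cell are
Binomial(n, p) from a truth grid; no cell-level covariates or
overdispersion, matching the plain-GLM analysis model.

All generators are deterministic given a seed; per-purpose RNG streams
are derived from the root seed so that, e.g., the male and female depth
tracks are independent but individually reproducible.

## Sex-chromosome scan

Windows are anchored at position 0, tile at `step` (50 kb) while
`start + window ≤ length`, and a terminal window ending at the
chromosome end is added if bases remain uncovered; a chromosome shorter
than the window becomes a single window. The depth ratio uses a
pseudocount c = 0.5 in both numerator and denominator so Y windows
(female sum 0) remain finite; with 200 kb windows at 40× the
pseudocount shifts autosomal ratios by < 1e-6.

Y-region detection is per-base: female depth ≤ `female_max_depth`
(default 0, read literally; configurable because real pools contain
index-hopping noise) and male depth ≥ 30 % of the male track's own
genome-wide mean (the natural referent for a male-pool threshold).
Passing runs separated by fewer than 100 failing bases are joined —
under NB dispersion 5 about a fifth of bases inside a true Y region
individually fail the male-depth test, but failing runs are short, so
gap-joining reassembles the region while the 1 kb minimum length
discards the isolated zero-female-depth bases that occur at rate
~1.7e-5 on autosomes (this is what keeps autosomal false calls at
exactly zero at 40×). X-region detection is evaluated on 1 kb bins
because a per-base exact-ratio test essentially never fires under count
noise; the "twice the depth" rule carries a ±20 % ratio band and a
±20 % band around the female genome average, both configurable.

Sex-specific SNP calling uses presence ≥ 0.2 alt frequency in every
pool of one sex, ≤ 0 alt reads in every pool of the other, and ≥ 10×
depth in all pools. These three thresholds are this package's own
choices; the presence threshold is deliberately below the 0.5
Y-gametolog expectation to tolerate sampling noise, and the depth floor
keeps frequency estimates meaningful.

Primer strategy is a pure length rule: a region at least as long as the
intended product (default 500 b) takes both primers inside the region
(boundary counts as inside); shorter regions anchor one primer inside
and one in flanking sequence.

## SV merging

Records follow the 12-column alignment-annotator dialect, 1-based
inclusive; query intervals reported end-before-start are normalised to
start ≤ end with inversion carried by the type code. Only top-level
annotation records are kept by default. The length filter is strict
(reference span > 5,000) and applied on the reference genome — the
dialect does not say which genome or whether the bound is inclusive, so
both choices are pinned here and configurable.

"Neighbouring" is formalised as three conditions on a type- and
orientation-homogeneous, reference-sorted run: (a) non-overlapping
reference intervals with gap ≤ `max_gap` (default unlimited); (b) no
record of a *different* rearrangement type starts strictly between the
two blocks — syntenic and unaligned records never block, since
annotators interleave them freely; (c) query coordinates progress
monotonically in the direction implied by the orientation (forward
types ascending, inverted types descending). Merging is idempotent:
collapsing each event to a single record and re-merging reproduces the
same events, because every blocking record is itself an event in the
output and every monotonicity break survives collapsing.

Spacer maps (default 1 kb spacers) support analyses that require equal
chromosome counts by concatenation; lift-back splits spacer-spanning
records at the spacer (artificial sequence, so splitting is preferred
over erroring) and drops records wholly inside it with a warning.

The rate arithmetic divides divergence time in generations by the SV
count, with a 1-year default generation time and no doubling for the
two lineages — the convention consistent with the published per-28 and
per-250 figures this mirrors.

## Repeat-library deduplication

The aligner is seeded by exact shared words (default 20) and extended
ungapped with +1/−1 scoring and an X-drop of 20; hits must reach 50
aligned bases at ≥ 95 % identity (matches / aligned columns), on either
strand. The 50 b overlap floor suppresses spurious 20-mer-seeded
micro-hits. Because extension is ungapped, a qualifying overlap
containing an indel is not found; repeat-consensus redundancy is
overwhelmingly substitution-level, and on substitution-only instances
the aligner's hits contain those of an exhaustive DP local aligner at
the same thresholds (tested).

Overlap resolution: a dovetail (alignment reaching within 10 bases of
one sequence's end and the other's start, forward strand) joins the two
into one consensus — prefix + per-column merge of the shared segment +
suffix — reconstructing a fragmented family, which is the stated intent
of joining; any other geometry (containment, internal overlap, reverse
strand) shortens the *shorter* sequence by removing its aligned
segment, keeping only the longest remaining piece and dropping pieces
under 50 b. Length ties break lexicographically on id. Iteration
resolves the longest qualifying alignment first (deterministic given
ids) and terminates because every action strictly removes bases; a
guard aborts with a diagnostic if total bases ever fail to decrease.
The final family *count* is invariant to input order on the synthetic
fixtures; exact sequence content is not, since join order affects which
copy donates mismatched columns.

Genomic refinement counts, per library base, the qualifying alignments
to the supplied genome and excises maximal segments with fewer than 2
hits ("portions" that are not repetitive), applied per supplied genome;
pooling hits across several genomes is possible by concatenating them
into one genome dict. Masking lower-cases genome bases covered by any
qualifying library alignment and reports per-family coverage.

## Pairing GLM

Grouped binomial logistic regression with treatment coding (reference
levels: alphabetically first chromosome and individual), fitted by IRLS
to tolerance 1e-10. Cells with zero scored spermatocytes are dropped
before fitting; rank-deficient designs raise an error naming the
aliased columns. Headline inference is by likelihood-ratio tests
(deviance differences against the χ² distribution): with
near-separation — a chromosome paired in a handful of hundreds of
cells — Wald standard errors explode while the deviance remains well
behaved. Pairwise chromosome contrasts are estimated marginal log-odds
averaged over individuals with equal weights, with Wald standard errors
from the fitted covariance and Bonferroni adjustment
`min(1, C(k,2) · p)`. Calibration on the synthetic grids: type-I error
of the chromosome LRT at nominal 0.05 sits in [0.03, 0.07] over 1,000
null simulations, and per-coefficient log-odds are recovered within
±0.2 in ≥ 95 % of replicates at 500 cells per grid cell (per
coefficient, whose standard error ≈ 0.09 at that size, is the reading
under which the tolerance and sample size are mutually consistent).

## Problem sizes

The test suite and acceptance script use a 10 Mb, five-chromosome
genome for the sex scan (three planted Y regions of 40/15/10 kb, one
1 Mb X region), 50 planted rearrangements fragmented into 3–8 blocks
with 500 decoys, 10 repeat families × 6 fragments (1.2 kb consensus,
200 b overlaps), and pairing grids of 4 chromosomes × 2 individuals at
100–500 cells per cell. These sizes give the recovery statistics
comfortable margins (per-base Y-region Jaccard ≥ 0.999 in practice)
while keeping full runs to seconds.

## Limitations

Simulated depth is positionally independent and GC-unaware; SNP tables
assume equimolar pools with no library-size normalisation (matching the
equal-pool design the scan defaults assume); the fragmenter emits only
INV/TRANS/INVTR/DUP/INVDP blocks and does not simulate fusions or
fissions as alignment artefacts; the seeded aligner is ungapped; the
pairing model has no cell-level random effects (deliberately — the
analysis it implements is a plain GLM). Passing recovery tests on these
generators demonstrates correctness of the computations, not
performance on real pools with mapping artefacts, collapsed repeats or
reference bias.
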