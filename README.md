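# cobitools

Downstream comparative-genomics analyses for loach-like fishes
(*Cobitis* and relatives): Pool-Seq sex-chromosome discovery,
parsimonious merging of whole-genome-alignment structural variants,
iterative repeat-library redundancy removal, and chromosome-specific
meiotic pairing statistics. Every analysis can be exercised end-to-end
on synthetic data with planted ground truth, so the pipeline is fully
testable without any sequencing downloads.

## What it computes

**Sex-chromosome scan** (`cobitools.sexscan`). From pooled male and
female per-base depth tracks, sliding windows (default 200 kb, 50 kb
step) report log2((ΣF + c)/(ΣM + c)), the female/male depth ratio. In a
male-heterogametic (XY) system this is ≈ 0 on autosomes, ≈ +1 over
X-differentiated regions and strongly negative over Y-hemizygous
sequence. Candidate Y regions are maximal base runs with female depth
≤ 0 and male depth ≥ 30 % of the male genome-wide mean; candidate X
regions are kilobase-bin runs with F ≈ 2M within ±20 % and F within
±20 % of the female mean. Sex-specific SNPs (alt allele present in
every pool of one sex, absent from every pool of the other) are counted
per window and normalised by total SNPs.

**SV merging** (`cobitools.svmerge`). Whole-genome-alignment annotators
report one rearrangement as many short tandem blocks. After dropping
blocks with reference span ≤ 5 kb, runs of neighbouring blocks of the
same type and orientation — uninterrupted by a different rearrangement
type and with monotonically progressing query coordinates — are merged
into single events, giving a more parsimonious set of structural
changes. Includes spacer-concatenation maps with coordinate lift-back,
large-event (> 1 Mb) counting, type × length summaries, gene-span
counts and indel∩repeat base fractions, plus the SV-rate arithmetic
(generations per SV = divergence years / generation time / SV count).

**Repeat-library dedup** (`cobitools.repeatlib`). A combined repeat
library is compared against itself with a seeded ungapped local aligner
(word size 20, ≥ 95 % identity, ≥ 50 b overlap, both strands).
Dovetail overlaps are joined into a new consensus; containments and
internal overlaps shorten the shorter sequence; this repeats until no
qualifying overlap remains (total bases strictly decrease every round).
A genomic refinement then excises library segments aligning to the
genome fewer than twice, and a soft-masking step reports per-family
genome coverage.

**Pairing statistics** (`cobitools.pairing`). Bivalent-vs-univalent
counts per chromosome × individual are fitted with a grouped-binomial
logistic GLM (treatment coding, IRLS). Effects are tested by
likelihood-ratio tests — robust when a chromosome pairs in almost no
cells — and all pairwise chromosome contrasts on the log-odds scale,
averaged over individuals, are Bonferroni-adjusted.

**Synthetic data** (`cobitools.simulate`). Deterministic generators for
all of the above: genomes with planted X/Y architecture,
negative-binomial pooled depth with copy-number-scaled means, pooled
SNP tables under a Y-gametolog allele model (alt frequency 0.5 in male
pools, 0 in female pools), fragmented SV records with decoys, redundant
tiled repeat libraries, repeat-planted genomes, and binomial pairing
counts.

## Worked example

One SV per how many generations? With ~35,633 SVs between two genomes
that diverged ~1 Mya (1-year generation time):

```pycon
>>> from cobitools.svmerge import generations_per_sv
>>> generations_per_sv(35_633, 1e6)
28.06387337580333
>>> generations_per_sv(41_228, 10e6)   # older pair, ~10 My divergence
242.55360434656058
```

i.e. roughly one SV per 28 generations for the recently diverged pair,
versus one per ~240–250 for the older pair — a nearly tenfold higher
short-term rate.

The end-to-end demo chains every stage on a 2 Mb synthetic genome and
checks recovery against the planted truth:

```sh
cobitools demo --seed 0 --out-dir demo_out
```

```json
{
  "seed": 0,
  "y_region_jaccard": 1.0,
  "y_recovery_pass": true,
  "sv_events_recovered": 8,
  "sv_events_planted": 8,
  "sv_recovery_pass": true,
  "repeat_fixpoint_size": 4,
  "repeat_families_planted": 4,
  "repeat_recovery_pass": true,
  "pairing_chromosome_lrt_p": 4.412975087716907e-74,
  "pairing_effect_pass": true
}
```

The planted Y interval is recovered base-exactly (Jaccard 1.0), all 8
fragmented rearrangements merge back to single events, the 16-fragment
repeat library collapses to its 4 true families, and the planted
chromosome effect on pairing is detected at p ≪ 0.0001.

Other subcommands: `cobitools simulate|sexscan|svmerge|repeatlib|pairing`
(see `--help` for each).

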