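# Methods

## Problem and model

A mobile-element insertion into one (heterozygous) or both (homozygous)
alleles of a resequenced genome leaves three read-pair signatures against a
reference that lacks the insertion: pairs bridging genome and element
(cross), reads split across a junction (clipped), and — from the
non-insertion allele — ordinary pairs spanning the site (background).
`teseek` detects insertions from the first two and types zygosity from the
ratio of the first two to the third.

The insertion model is the standard LTR-retrotransposition geometry: at a
1-based target position *p* with TSD length *t*, the mutant chromosome is
`ref[1..p+t−1] + element + ref[p..]`, i.e. the *t* bases starting at *p* are
duplicated on both flanks. All internal coordinates are 0-based half-open;
every user-facing coordinate is 1-based inclusive. A call's `position` is
the TSD start *p*.

## Classification

A pair is informative when ≥ `min_te_overlap` (default 20 bp) of its
sequence derives from the element, established in order of reliability:
a mate whose primary alignment is on the element; a supplementary alignment
on the element; or a terminal soft clip whose sequence matches either
element terminus, in either orientation, with mismatch fraction
≤ `max_mismatch_frac` (default 0.1). The 20-bp floor matches the aligner
contract (`bwa mem -T 20`: at least 20 bp of a read properly aligned before
a record is emitted). Dual clipped-read detection (terminus matching plus
supplementary records) keeps junction reads usable when the aligner
declines to emit a split alignment; terminus matching also pins down the
matched element end and strand, which identical LTR termini would otherwise
leave ambiguous through position alone.

Side convention: evidence whose genome-side alignment points rightward
supports the insertion's left junction; leftward-pointing evidence the
right junction. For clipped reads the side follows from which reference
edge of the alignment is clipped, independent of read strand. A cross
pair's genome mate must be "completely" aligned; up to 5 bp of incidental
clipping is tolerated. Pairs with both mates inside the element carry no
genome anchor and are uninformative.

## Clustering, filters, breakpoints

Evidence anchors (clip coordinates for clipped pairs, inner alignment edges
for cross pairs) are single-linkage clustered per sequence with
`cluster_window` = insert mean + 3 sd (650 bp at the default 500 ± 50
library). Filters on each cluster, all at their published defaults:
mean MAPQ of informative pairs ≥ 1, mean read depth over ± insert-mean
around the cluster midpoint within [2, 300], ≥ 3 supporting pairs, and both
junctions supported. "Both ends" is interpreted as both genome flanks
(left and right junction evidence), not both element termini. Depth is
computed from all genome-mapped reads, informative included. Rejected
candidates are written with their failure reasons.

Breakpoint refinement uses the modal clip coordinate per side (ties broken
toward the smaller coordinate, keeping output deterministic): *L* from
left-junction clips, *R* from right-junction clips, TSD length
`L − R + 1` bounded by `max_tsd` = 20 (an implausible value flags probable
junction mis-pairing and suppresses the TSD). One-sided clips still give an
exact coordinate with no TSD; clusters without clips fall back to the
midpoint between the innermost left and right anchors, flagged `interval`.
Orientation is an 80:20 majority vote: a clipped read votes the strand its
clip matched a terminus on; a cross pair votes forward when its element
mate's strand opposes the genome mate's pointing direction (FR geometry).
Both rules are insensitive to identical LTR ends.

## Zygosity

At a heterozygous site the insertion allele feeds two junctions while the
other allele feeds one spanning locus, giving the idealized 2:1
supportive:background expectation, hence a background proportion of 1/3.
With *s* supportive and *b* background pairs (background counted as pairs
whose outer insert interval strictly contains the position — pairs, not
reads, symmetric with the supportive count), the one-sided exact binomial
lower tail `P(X ≤ b)`, `X ~ Binomial(s+b, 1/3)`, is evaluated with the
exact CDF; `p < alpha` (default 0.05) calls homozygous. Background excess
beyond the heterozygous expectation is still reported heterozygous;
mosaicism and allele-frequency estimation are out of scope, and no
multiple-testing correction is applied across loci. Note the 2:1 figure
ignores the 20-bp overlap requirement, which trims the informative window
per junction; under the default library geometry the realized ratio sits
near 1.8, comfortably inside the test's discrimination range.

## Synthetic data

The generator reproduces the benchmark conditions: i.i.d. random genomes at
42% GC, optionally with exact interspersed repeat copies
(`repeat_fraction`) to reproduce the repeat-region failure mode; a
synthetic element with Tnt1 geometry (5334 bp, identical 610-bp LTRs,
random sequence — a labelled synthetic stand-in, since the benchmark's real
element sequence is not bundled); insertions with a 5-bp TSD placed
uniformly with a minimum spacing; and paired-end reads at the study
parameters — 100-bp reads, insert 500 ± 50 truncated at twice the read
length, per-base substitution rate 0.001, no indel errors, no GC bias,
constant Q30 qualities (the caller never reads qualities). Heterozygous
samples mix equal coverage of mutant- and reference-derived reads in a
seeded random interleave. Everything is deterministic given its seed.

Read names encode their origin, so a truth-projected SAM can be emitted:
each read is written with the alignment it must have were mapping perfect,
junction reads soft-clipped at the known splice point. A junction read
stays genome-aligned whenever ≥ 20 bp of it lies on the genome (mirroring
the aligner's minimum-anchor contract); otherwise the larger block wins.
This oracle removes aligner behaviour from tests of breakpoint arithmetic.
What the simulator does **not** emulate: sequence divergence between the
resequenced line and the reference, indels, coverage biases, chimeric
fragments, and quality-dependent errors — so passing benchmarks bound the
method's behaviour under clean data, not its robustness to
cross-genotype mapping noise.

Benchmark scoring matches calls to truth greedily by distance, each truth
record used at most once, with disjoint bins: exact (0 bp), within 100 bp,
within 500 bp; calls beyond 500 bp of any remaining truth are false
positives. Recall counts all matches within 500 bp.

Benchmarks in the test suite are scaled to a few megabases and tens of
insertions (e.g. 5 Mb / 25 insertions for the 5X recall benchmark; 100 loci
at 30X for zygosity accuracy), sizes chosen so each run completes in
seconds to a couple of minutes while keeping per-locus evidence counts at
their full-scale expectations.

## Annotation

GFF3 genes and exons are indexed as interval trees; a position is exon if
inside any exon, intron if inside a gene but no exon, else intergenic
(half-open arithmetic, so a 1-based position equal to an exon's end is
still exonic). Genic enrichment is a permutation test — each round drops as
many uniform random positions as there are calls and counts genic hits —
with the add-one estimator `(1 + #{perm ≥ obs}) / (n_perm + 1)` to avoid
zero p-values. A permutation test was chosen over a contingency-table
exact test as primary because it is self-contained and assumption-free;
with 10,000 permutations its resolution floor is ~1e-4.

## Design choices and limitations

* The aligner is invoked as `bwa mem` (the `-T` option exists only in
  `mem`); the aligner is isolated behind one function and the rest of the
  pipeline runs from any SAM/BAM.
* Pair joining accepts name- or coordinate-sorted input; a pair is flushed
  as soon as both primaries are seen and no supplementary record is
  advertised (SA tag), bounding memory on sorted input.
* Secondary alignments are dropped; supplementaries kept (clipped-read
  detection). CRAM and single-end/long-read input are unsupported.
* With a real aligner, micro-homology between the element terminus and the
  sequence beyond a junction can extend alignments a few bases past the
  true splice point, shifting breakpoints by up to the homology length;
  positions from clipped reads are exact on idealized alignments and
  typically within a few bases otherwise.
* Absence calling (detecting reference TE copies missing from the sample),
  multi-sample joint calling, and genotype-likelihood models beyond the
  binomial test are non-goals.
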