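# teseek

Locate transposable-element (TE) insertion sites — and their zygosity — from
paired-end whole-genome resequencing data.

Insertional mutagenesis with mobile elements such as the tobacco LTR
retrotransposon Tnt1 scatters dozens of new copies through a genome; forward
genetics then needs every insertion point recovered from a resequenced
mutant line. `teseek` takes a reference genome, the element sequence and
paired-end reads (or a pre-aligned BAM/SAM), and produces a filtered table
of insertion sites with exact breakpoints, the target-site duplication
(TSD), the element orientation, and a heterozygous/homozygous call for each
site. A built-in simulator generates benchmark genomes, reads and truth
tables, so the entire pipeline is testable without any external data.

## Method

Reads are mapped with `bwa mem -T 20` against the reference genome plus the
element appended as one extra sequence, so pairs bridging an insertion are
directly visible. Every pair is then classified:

* **background** — both mates on the genome, no element evidence; carries
  the non-insertion allele;
* **cross** — one mate entirely on the genome, the other on the element;
* **clipped** — a read crosses the junction itself: its soft-clipped tail
  (≥ 20 bp, ≤ 10% mismatches) matches an element terminus;
* anything else is uninformative. A pair is informative only when ≥ 20 bp
  of it derives from the element.

Informative pairs are single-linkage clustered along the genome
(window = insert mean + 3 sd). A cluster is reported as an insertion when it
passes four filters: mean mapping quality ≥ 1 (repeat guard), local depth in
[2, 300], ≥ 3 supporting pairs, and at least one pair on each side of the
insertion. Clipped reads fix the breakpoint exactly: with modal clip
coordinates *L* (last reference base before the element, from the left) and
*R* (first reference base after it, from the right), the TSD is
`ref[R..L]` of length `L − R + 1` and the call sits at *R*.

Zygosity follows from the 2:1 expectation at a heterozygous site
(two junctions feed informative pairs, one allele feeds background): with
*s* supportive and *b* background pairs, the one-sided exact binomial tail
`p = P(X ≤ b)`, `X ~ Binomial(s + b, 1/3)`, is computed and the site called
homozygous when `p < 0.05`.

Optionally, calls are classified against a GFF3 annotation
(exon/intron/intergenic) and genic enrichment is tested by permutation.

## Quick start

```bash
teseek simulate --outdir demo --seq-len 500000 --n-insertions 5 --coverage 10 --seed 1
teseek call --genome demo/genome.fa --te demo/te.fa \
            --fastq1 demo/reads_1.fq --fastq2 demo/reads_2.fq --outdir demo/out
teseek evaluate --calls demo/out/calls.tsv --truth demo/truth.tsv
```

or from Python — `examples/01_simulate_and_call.py` builds a 300-kb genome
with five heterozygous full-length insertions at 10X and prints:

```
     pos    tsd strand support left/right clipped zygosity
   55114  TAGTC      +      18    9/9           4 heterozygous
  100334             -      25   16/9           4 heterozygous
  130204  CCAAA      +      20   14/6           3 heterozygous
  175690  TGTTT      -      25   16/9           3 heterozygous
  199232  TTGAC      +      23   14/9           7 heterozygous
```

Each row is one called insertion: the 1-based start of the duplicated
target site, the recovered 5-bp TSD (empty when only one junction had
clipped reads, as at 100334), the element orientation, the supporting-pair
counts split by junction, and the zygosity call. The other examples sweep
recall against coverage, contrast het/hom typing, and run the annotation
enrichment test.

## Outputs

`calls.tsv` (1-based positions; one row per passing call with evidence
counts, mean MAPQ, depth, TSD, zygosity fields), `calls.bed` (BED6,
0-based half-open), `rejected.tsv` (candidates with the filters they
failed), and optionally `enrichment.json`.

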