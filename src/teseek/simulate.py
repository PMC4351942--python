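"""Synthetic data generation and benchmarking.

Everything needed to exercise the caller without external data: random
genomes (optionally with exact interspersed repeats to reproduce the
repeat-region failure mode), a synthetic LTR retrotransposon with Tnt1
geometry (5334 bp, identical 610-bp terminal repeats, 5-bp target-site
duplication on insertion), a paired-end read simulator matching the study
conditions (100-bp reads, 500 +/- 50 insert, 0.001 per-base substitution
error, no indels, no GC bias, constant Q30 qualities), heterozygous read
mixing, a truth-projected SAM writer for aligner-free testing, small
hand-built SAM fixtures for threshold sweeps, and the benchmark evaluator.

All operations are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .io_sam import ReferenceSet, write_fasta
from .util import revcomp

log = logging.getLogger(__name__)

# Tnt1-characteristic geometry: element length, LTR length, TSD length
TE_LENGTH = 5334
LTR_LENGTH = 610
TSD_LENGTH = 5

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    arr = rng.choice(_BASES, size=length, p=_base_probs(gc))
    return arr.tobytes().decode("ascii")


def random_te(length: int = TE_LENGTH, ltr_len: int = LTR_LENGTH,
              gc: float = 0.42, seed: int = 0, name: str = "synthTE") -> tuple[str, str]:
    """A synthetic LTR retrotransposon: identical terminal repeats flanking a
    random internal region.  A stand-in with the length and LTR structure of
    Tnt1; the sequence itself is random.  Returns ``(name, sequence)``."""
    if length <= 2 * ltr_len:
        raise ValueError("element length must exceed twice the LTR length")
    rng = np.random.default_rng(seed)
    ltr = random_sequence(ltr_len, gc, rng)
    internal = random_sequence(length - 2 * ltr_len, gc, rng)
    return name, ltr + internal + ltr


def generate_genome(n_seq: int = 2, seq_len: int = 1_000_000, gc: float = 0.42,
                    repeat_fraction: float = 0.0, repeat_unit_len: int = 500,
                    seed: int = 0) -> dict[str, str]:
    """Random genome of ``n_seq`` sequences named chr1..chrN.

    ``repeat_fraction`` of each sequence is overwritten with exact copies of
    one shared ``repeat_unit_len``-bp unit at random non-overlapping
    positions: reads from those stretches map ambiguously, which is the
    failure mode that hides insertions from the caller.
    """
    if not (0 <= repeat_fraction < 1):
        raise ValueError("repeat_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    unit = None
    if repeat_fraction > 0:
        unit = np.frombuffer(random_sequence(repeat_unit_len, gc, rng).encode(),
                             dtype=np.uint8)
    genome: dict[str, str] = {}
    for i in range(n_seq):
        arr = rng.choice(_BASES, size=seq_len, p=_base_probs(gc))
        if unit is not None:
            n_copies = int(repeat_fraction * seq_len / repeat_unit_len)
            placed: list[int] = []
            tries = 0
            while len(placed) < n_copies and tries < 50 * n_copies:
                tries += 1
                s = int(rng.integers(0, seq_len - repeat_unit_len + 1))
                if all(abs(s - p) >= repeat_unit_len for p in placed):
                    placed.append(s)
            for s in placed:
                arr[s: s + repeat_unit_len] = unit
        genome[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    return genome


# ---------------------------------------------------------------------------
# In-silico mutagenesis


@dataclass
class TruthRecord:
    """One simulated insertion (ground truth for benchmarking).

    ``position`` is the 1-based start of the target-site duplication in
    reference coordinates — the same convention the caller reports.
    """

    genome_ref: str
    position: int
    tsd_len: int = TSD_LENGTH
    te_strand: str = "+"
    zygosity: str = "het"


def apply_truth(genome: Mapping[str, str], te_seq: str,
                truth: Iterable[TruthRecord]) -> dict[str, str]:
    """Splice the element into the genome at each truth record.

    At 1-based TSD start ``p`` with TSD length ``t`` the mutant sequence is
    ``ref[:p-1+t] + TE + ref[p-1:]`` — the ``t`` reference bases starting at
    ``p`` end up duplicated on both sides of the element ('-' records insert
    the reverse complement).
    """
    by_ref: dict[str, list[TruthRecord]] = {}
    for t in truth:
        by_ref.setdefault(t.genome_ref, []).append(t)
    mutant = {}
    for ref, seq in genome.items():
        recs = sorted(by_ref.get(ref, []), key=lambda t: t.position)
        parts = []
        prev = 0
        for t in recs:
            cut = t.position - 1 + t.tsd_len
            parts.append(seq[prev:cut])
            parts.append(te_seq if t.te_strand == "+" else revcomp(te_seq))
            prev = t.position - 1
        parts.append(seq[prev:])
        mutant[ref] = "".join(parts)
    return mutant


def insert_te(genome: Mapping[str, str], te_seq: str, n_insertions: int,
              tsd_len: int = TSD_LENGTH, min_gap: int = 10_000,
              orientation_mix: float = 0.5, seed: int = 0,
              zygosity: str = "het",
              edge_margin: int = 2_000) -> tuple[dict[str, str], list[TruthRecord]]:
    """Randomly insert ``n_insertions`` element copies with a TSD.

    Positions are sampled uniformly (sequences weighted by length), at least
    ``min_gap`` apart and ``edge_margin`` from sequence ends;
    ``orientation_mix`` is the probability of a reverse-orientation copy.
    Returns the mutant genome and the truth table.
    """
    total = sum(len(s) for s in genome.values())
    if n_insertions * (len(te_seq) + min_gap) >= total:
        raise ValueError(
            "cannot place insertions: genome too small for the requested "
            "count at this min_gap; reduce n_insertions or min_gap"
        )
    rng = np.random.default_rng(seed)
    names = list(genome)
    weights = np.array([len(genome[n]) for n in names], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[int]] = {n: [] for n in names}
    truth: list[TruthRecord] = []
    tries = 0
    while len(truth) < n_insertions:
        tries += 1
        if tries > 100 * n_insertions:
            raise ValueError("cannot place insertions with the requested "
                             "min_gap; try fewer insertions")
        ref = names[int(rng.choice(len(names), p=weights))]
        L = len(genome[ref])
        if L < 2 * edge_margin + tsd_len + 1:
            continue
        pos = int(rng.integers(edge_margin, L - edge_margin - tsd_len)) + 1
        if any(abs(pos - q) < min_gap for q in placed[ref]):
            continue
        placed[ref].append(pos)
        strand = "-" if rng.random() < orientation_mix else "+"
        truth.append(TruthRecord(genome_ref=ref, position=pos,
                                 tsd_len=tsd_len, te_strand=strand,
                                 zygosity=zygosity))
    truth.sort(key=lambda t: (t.genome_ref, t.position))
    return apply_truth(genome, te_seq, truth), truth


def write_truth(truth: Iterable[TruthRecord], path) -> Path:
    path = Path(path)
    pd.DataFrame([vars(t) for t in truth]).to_csv(path, sep="\t", index=False)
    return path


def read_truth(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [TruthRecord(genome_ref=str(r.genome_ref), position=int(r.position),
                        tsd_len=int(r.tsd_len), te_strand=str(r.te_strand),
                        zygosity=str(r.zygosity))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class SimParams:
    """Paired-end simulation parameters (defaults are the study conditions)."""

    read_len: int = 100
    insert_mean: int = 500
    insert_sd: int = 50
    error_rate: float = 0.001
    coverage: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.insert_mean <= 2 * self.read_len:
            raise ValueError("insert_mean must exceed twice the read length")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")


def _mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    arr = bytearray(seq.encode())
    pos = rng.choice(len(arr), size=k, replace=False)
    for p in pos:
        cur = arr[p]
        choices = [b for b in b"ACGT" if b != cur]
        arr[p] = choices[int(rng.integers(3))]
    return arr.decode()


def simulate_reads(seqs: Mapping[str, str], params: SimParams, fastq1, fastq2,
                   label: str = "hap") -> int:
    """Simulate paired-end reads over ``seqs`` into two FASTQ files.

    Fragment starts are uniform, fragment lengths normal
    (``insert_mean`` +/- ``insert_sd``) truncated at twice the read length,
    the inner mate is reverse-complemented, and substitution errors are
    applied at ``error_rate`` per base (no indels).  Read names encode the
    origin — ``sr|{label}|{sequence}|{fragment_start}|{fragment_len}|{serial}``
    — so truth-projected alignments can be reconstructed.  Returns the
    number of pairs written.
    """
    rng = np.random.default_rng(params.seed)
    rl = params.read_len
    total = sum(len(s) for s in seqs.values())
    n_pairs = int(round(params.coverage * total / (2 * rl)))
    names = [n for n in seqs if len(seqs[n]) >= 2 * rl]
    for n in seqs:
        if n not in names:
            log.warning("sequence %s shorter than a fragment; skipped", n)
    lens = np.array([len(seqs[n]) for n in names], dtype=float)
    counts = rng.multinomial(n_pairs, lens / lens.sum())
    serial = 0
    written = 0
    with open(fastq1, "w") as f1, open(fastq2, "w") as f2:
        for name, count in zip(names, counts):
            seq = seqs[name]
            L = len(seq)
            if count == 0:
                continue
            flens = np.rint(rng.normal(params.insert_mean, params.insert_sd,
                                       size=count)).astype(int)
            np.clip(flens, 2 * rl, L, out=flens)
            starts = rng.integers(0, L - flens + 1)
            n_err1 = rng.binomial(rl, params.error_rate, size=count)
            n_err2 = rng.binomial(rl, params.error_rate, size=count)
            buf1, buf2 = [], []
            qual = "?" * rl  # constant Q30; qualities are never used downstream
            for s, fl, k1, k2 in zip(starts, flens, n_err1, n_err2):
                r1 = seq[s: s + rl]
                r2 = revcomp(seq[s + fl - rl: s + fl])
                if k1:
                    r1 = _mutate(r1, int(k1), rng)
                if k2:
                    r2 = _mutate(r2, int(k2), rng)
                rname = f"sr|{label}|{name}|{s}|{fl}|{serial}"
                serial += 1
                buf1.append(f"@{rname}\n{r1}\n+\n{qual}\n")
                buf2.append(f"@{rname}\n{r2}\n+\n{qual}\n")
            f1.write("".join(buf1))
            f2.write("".join(buf2))
            written += count
    return int(written)


def mix_heterozygous(fq1_a, fq2_a, fq1_b, fq2_b, out1, out2,
                     seed: int = 0) -> int:
    """Interleave two read sets (e.g. mutant and reference haplotypes) in a
    random but seed-deterministic order, preserving pair integrity."""
    def _load(path):
        recs = []
        with pysam.FastxFile(str(path)) as fh:
            for r in fh:
                recs.append((r.name, r.sequence, r.quality))
        return recs

    a1, a2, b1, b2 = _load(fq1_a), _load(fq2_a), _load(fq1_b), _load(fq2_b)
    if len(a1) != len(a2) or len(b1) != len(b2):
        raise ValueError("mate FASTQ files disagree in record count")
    if min(len(a1), len(b1)) and abs(len(a1) - len(b1)) / max(len(a1), len(b1)) > 0.01:
        log.warning("haplotype read sets differ by more than 1%% "
                    "(%d vs %d pairs)", len(a1), len(b1))
    r1 = a1 + b1
    r2 = a2 + b2
    order = np.random.default_rng(seed).permutation(len(r1))
    with open(out1, "w") as f1, open(out2, "w") as f2:
        for i in order:
            n, s, q = r1[i]
            f1.write(f"@{n}\n{s}\n+\n{q}\n")
            n, s, q = r2[i]
            f2.write(f"@{n}\n{s}\n+\n{q}\n")
    return len(r1)


# ---------------------------------------------------------------------------
# Truth-projected alignments (aligner-free oracle)


def _segments(ref_len: int, truth: list[TruthRecord], te_len: int):
    """Mutant-coordinate segment list: (start, end, kind, payload).

    kind 'G': payload = reference offset of the segment start;
    kind 'T': payload = element strand.
    """
    segs = []
    mut = 0
    prev = 0
    for t in sorted(truth, key=lambda t: t.position):
        cut = t.position - 1 + t.tsd_len
        if cut > prev:
            segs.append((mut, mut + (cut - prev), "G", prev))
            mut += cut - prev
        segs.append((mut, mut + te_len, "T", t.te_strand))
        mut += te_len
        prev = t.position - 1
    segs.append((mut, mut + (ref_len - prev), "G", prev))
    return segs


def _project_read(segs, s: int, e: int, te_len: int, min_anchor: int = 20):
    """Project mutant interval [s, e) onto the combined reference.

    Returns ``(kind, payload, ref_pos, pre_clip, aligned, post_clip, te_rev)``.
    The primary block is the genome segment with the most overlapped bases
    when that anchor reaches ``min_anchor`` (a junction read stays
    genome-aligned with the element portion soft-clipped, mirroring an
    aligner that requires at least 20 properly mapped bases); otherwise the
    segment with the most bases wins.
    """
    over = []
    for seg in segs:
        if seg[1] > s and seg[0] < e:
            over.append(seg)
        elif seg[0] >= e:
            break

    def ov(seg):
        return min(e, seg[1]) - max(s, seg[0])

    genomic = [seg for seg in over if seg[2] == "G"]
    best_g = max(genomic, key=ov, default=None)
    if best_g is not None and ov(best_g) >= min_anchor:
        best = best_g
    else:
        best = max(over, key=ov)
    seg_s, seg_e, kind, payload = best
    pre = max(0, seg_s - s)
    post = max(0, e - seg_e)
    aligned = (e - s) - pre - post
    offset = max(s, seg_s) - seg_s
    te_rev = False
    if kind == "G":
        ref_pos = payload + offset
    elif payload == "+":
        ref_pos = offset
    else:
        ref_pos = te_len - (offset + aligned)
        te_rev = True
    return kind, payload, ref_pos, pre, aligned, post, te_rev


def parse_read_name(name: str):
    """Decode a simulator read name into (label, sequence, start, frag_len)."""
    core = name.split("/")[0]
    fields = core.split("|")
    if len(fields) != 6 or fields[0] != "sr":
        raise ValueError(f"read name {name!r} does not encode a simulated origin")
    return fields[1], fields[2], int(fields[3]), int(fields[4])


def project_truth_alignments(fastq1, fastq2, refset: ReferenceSet,
                             truths: Mapping[str, list[TruthRecord]],
                             out_sam) -> Path:
    """Write the alignments each simulated read MUST have were mapping perfect.

    ``truths`` maps the haplotype label embedded in read names to that
    haplotype's truth table (an empty list for a reference haplotype).  Reads
    wholly inside the element are emitted on the TE reference; junction
    straddlers as genome records soft-clipped at the splice point, with the
    CIGAR computed from the known splice geometry.
    """
    te_len = len(refset.te_sequence)
    seg_cache: dict[tuple[str, str], list] = {}

    def segs_for(label, chrom):
        key = (label, chrom)
        if key not in seg_cache:
            if label not in truths:
                raise ValueError(f"unknown haplotype label {label!r} in read names")
            chrom_truth = [t for t in truths[label] if t.genome_ref == chrom]
            seg_cache[key] = _segments(len(refset.genome[chrom]), chrom_truth,
                                       te_len)
        return seg_cache[key]

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": n, "LN": l} for n, l in refset.lengths().items()]}
    out_sam = Path(out_sam)
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out, \
            pysam.FastxFile(str(fastq1)) as fh1, pysam.FastxFile(str(fastq2)) as fh2:
        for r1, r2 in zip(fh1, fh2):
            label, chrom, start, flen = parse_read_name(r1.name)
            rl1, rl2 = len(r1.sequence), len(r2.sequence)
            segs = segs_for(label, chrom)
            mates = []
            for mate_idx, (rec, s, e, mut_fwd) in enumerate((
                    (r1, start, start + rl1, r1.sequence),
                    (r2, start + flen - rl2, start + flen,
                     revcomp(r2.sequence)))):
                kind, payload, ref_pos, pre, aligned, post, te_rev = \
                    _project_read(segs, s, e, te_len)
                rname = chrom if kind == "G" else refset.te_name
                is_rev = (mate_idx == 1) != te_rev
                seq = mut_fwd if not te_rev else revcomp(mut_fwd)
                if te_rev:
                    pre, post = post, pre
                cig = ""
                if pre:
                    cig += f"{pre}S"
                cig += f"{aligned}M"
                if post:
                    cig += f"{post}S"
                mates.append((rec.name.split("/")[0], rname, ref_pos, is_rev,
                              cig, seq))
            for i, (qname, rname, pos, rev, cig, seq) in enumerate(mates):
                o_rname, o_pos, o_rev = mates[1 - i][1], mates[1 - i][2], mates[1 - i][3]
                a = pysam.AlignedSegment(out.header)
                a.query_name = qname
                a.flag = (0x1 | 0x2 | (0x10 if rev else 0)
                          | (0x20 if o_rev else 0)
                          | (0x40 if i == 0 else 0x80))
                a.reference_name = rname
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigarstring = cig
                a.query_sequence = seq
                a.next_reference_name = o_rname
                a.next_reference_start = o_pos
                out.write(a)
    return out_sam


# ---------------------------------------------------------------------------
# Hand-built SAM fixtures (threshold sweeps, unit tests)


def write_sam(path, refset: ReferenceSet, records: Iterable[dict]) -> Path:
    """Write plain dict records as an unsorted SAM over the combined reference.

    Each record: name, ref, pos0, strand, cigar, seq, mapq, read1 (bool),
    mate_ref, mate_pos0, mate_strand.
    """
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": n, "LN": l} for n, l in refset.lengths().items()]}
    path = Path(path)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r["name"]
            a.flag = (0x1 | 0x2
                      | (0x10 if r["strand"] == "-" else 0)
                      | (0x20 if r["mate_strand"] == "-" else 0)
                      | (0x40 if r["read1"] else 0x80))
            a.reference_name = r["ref"]
            a.reference_start = r["pos0"]
            a.mapping_quality = r.get("mapq", 60)
            a.cigarstring = r["cigar"]
            a.query_sequence = r["seq"]
            a.next_reference_name = r["mate_ref"]
            a.next_reference_start = r["mate_pos0"]
            out.write(a)
    return path


def junction_evidence_pair(refset: ReferenceSet, chrom: str, junction: int,
                           side: str, overlap: int, name: str,
                           kind: str = "clipped", read_len: int = 100,
                           frag_offset: int = 250, mapq: int = 60) -> list[dict]:
    """One synthetic informative pair at a forward-element junction.

    ``junction`` is 1-based: the last genomic base before the element for
    ``side='left'``, the first genomic base after it for ``side='right'``.
    ``overlap`` is the TE-derived portion of the informative read.
    """
    ref = refset.genome[chrom]
    te = refset.te_sequence
    g = read_len - overlap
    if kind == "clipped":
        if side == "left":
            pos0 = junction - g
            clipped = dict(name=name, ref=chrom, pos0=pos0, strand="-",
                           cigar=f"{g}M{overlap}S",
                           seq=ref[pos0:junction] + te[:overlap],
                           mapq=mapq, read1=False)
            mate_pos0 = pos0 - frag_offset
            mate = dict(name=name, ref=chrom, pos0=mate_pos0, strand="+",
                        cigar=f"{read_len}M",
                        seq=ref[mate_pos0: mate_pos0 + read_len],
                        mapq=mapq, read1=True)
        else:
            pos0 = junction - 1
            clipped = dict(name=name, ref=chrom, pos0=pos0, strand="+",
                           cigar=f"{overlap}S{g}M",
                           seq=te[-overlap:] + ref[pos0: pos0 + g],
                           mapq=mapq, read1=True)
            mate_pos0 = pos0 + frag_offset
            mate = dict(name=name, ref=chrom, pos0=mate_pos0, strand="-",
                        cigar=f"{read_len}M",
                        seq=ref[mate_pos0: mate_pos0 + read_len],
                        mapq=mapq, read1=False)
        clipped["mate_ref"], clipped["mate_pos0"], clipped["mate_strand"] = \
            mate["ref"], mate["pos0"], mate["strand"]
        mate["mate_ref"], mate["mate_pos0"], mate["mate_strand"] = \
            clipped["ref"], clipped["pos0"], clipped["strand"]
        return [clipped, mate]
    # cross pair
    pad = read_len - overlap
    if side == "left":
        gpos0 = junction - read_len
        gmate = dict(name=name, ref=chrom, pos0=gpos0, strand="+",
                     cigar=f"{read_len}M", seq=ref[gpos0:junction],
                     mapq=mapq, read1=True)
        cig = f"{overlap}M{pad}S" if pad else f"{read_len}M"
        tmate = dict(name=name, ref=refset.te_name, pos0=0, strand="-",
                     cigar=cig, seq=te[:overlap] + "A" * pad,
                     mapq=mapq, read1=False)
    else:
        gpos0 = junction - 1
        gmate = dict(name=name, ref=chrom, pos0=gpos0, strand="-",
                     cigar=f"{read_len}M", seq=ref[gpos0: gpos0 + read_len],
                     mapq=mapq, read1=False)
        cig = f"{pad}S{overlap}M" if pad else f"{read_len}M"
        tmate = dict(name=name, ref=refset.te_name, pos0=len(te) - overlap,
                     strand="+", cigar=cig, seq="A" * pad + te[-overlap:],
                     mapq=mapq, read1=True)
    gmate["mate_ref"], gmate["mate_pos0"], gmate["mate_strand"] = \
        tmate["ref"], tmate["pos0"], tmate["strand"]
    tmate["mate_ref"], tmate["mate_pos0"], tmate["mate_strand"] = \
        gmate["ref"], gmate["pos0"], gmate["strand"]
    return [gmate, tmate]


def background_pairs(refset: ReferenceSet, chrom: str, start0: int, n: int,
                     name_prefix: str, read_len: int = 100, insert: int = 500,
                     step: int = 60, mapq: int = 60) -> list[dict]:
    """``n`` fully genome-mapped pairs tiled from ``start0`` (0-based)."""
    ref = refset.genome[chrom]
    out = []
    for i in range(n):
        p1 = start0 + i * step
        p2 = p1 + insert - read_len
        name = f"{name_prefix}_{i}"
        r1 = dict(name=name, ref=chrom, pos0=p1, strand="+",
                  cigar=f"{read_len}M", seq=ref[p1: p1 + read_len],
                  mapq=mapq, read1=True, mate_ref=chrom, mate_pos0=p2,
                  mate_strand="-")
        r2 = dict(name=name, ref=chrom, pos0=p2, strand="-",
                  cigar=f"{read_len}M", seq=ref[p2: p2 + read_len],
                  mapq=mapq, read1=False, mate_ref=chrom, mate_pos0=p1,
                  mate_strand="+")
        out.extend([r1, r2])
    return out


# ---------------------------------------------------------------------------
# Synthetic annotation (for the enrichment analysis)


def random_annotation(genome_lengths: Mapping[str, int], path,
                      genic_fraction: float = 0.3, gene_len: int = 3_000,
                      exon_len: int = 500, seed: int = 0) -> Path:
    """Write a synthetic GFF3: non-overlapping genes covering about
    ``genic_fraction`` of the genome, each an alternation of exons and
    introns starting and ending with an exon."""
    rng = np.random.default_rng(seed)
    path = Path(path)
    mean_gap = gene_len * (1 - genic_fraction) / max(genic_fraction, 1e-9)
    gid = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, L in genome_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {L}\n")
        for chrom, L in genome_lengths.items():
            pos = 0
            while True:
                gap = int(rng.exponential(mean_gap)) + 1
                start = pos + gap               # 0-based gene start
                glen = max(3 * exon_len, int(rng.normal(gene_len, gene_len / 5)))
                end = start + glen
                if end >= L:
                    break
                gid += 1
                strand = "+" if rng.random() < 0.5 else "-"
                fh.write(f"{chrom}\tteseek\tgene\t{start + 1}\t{end}\t.\t"
                         f"{strand}\t.\tID=gene{gid}\n")
                fh.write(f"{chrom}\tteseek\tmRNA\t{start + 1}\t{end}\t.\t"
                         f"{strand}\t.\tID=mRNA{gid};Parent=gene{gid}\n")
                # alternate exon/intron, exon first and last
                cursor = start
                eid = 0
                while cursor < end:
                    e_end = min(cursor + exon_len, end)
                    eid += 1
                    fh.write(f"{chrom}\tteseek\texon\t{cursor + 1}\t{e_end}\t.\t"
                             f"{strand}\t.\tID=exon{gid}.{eid};Parent=mRNA{gid}\n")
                    cursor = e_end + exon_len   # intron of the same length
                pos = end
    return path


# ---------------------------------------------------------------------------
# Benchmark evaluation


@dataclass
class BenchmarkResult:
    """Scoring of calls against a truth table.

    Bins are disjoint: ``n_exact`` (distance 0), ``n_within100`` (1-100 bp),
    ``n_within500`` (101-500 bp); beyond 500 bp — or with no truth record
    left to match — a call is a false positive.
    """

    n_truth: int
    n_calls: int
    n_exact: int = 0
    n_within100: int = 0
    n_within500: int = 0
    n_false_positive: int = 0
    n_missed: int = 0
    recall: float = 0.0
    fp_rate: float = 0.0

    def as_dict(self) -> dict:
        return dict(vars(self))


def _call_pos(call):
    if hasattr(call, "genome_ref"):
        return call.genome_ref, call.position
    return call[0], call[1]


def evaluate_calls(calls, truth: Iterable[TruthRecord], exact_tol: int = 0,
                   near_tol: int = 100, fp_dist: int = 500) -> BenchmarkResult:
    """Greedy nearest-match assignment of calls to truth records.

    Each truth record is matched at most once; distance is the absolute
    difference of 1-based positions on the same sequence.  ``calls`` may be
    :class:`~teseek.caller.InsertionCall` objects or ``(chrom, pos)`` pairs.
    """
    truth = list(truth)
    positions = [_call_pos(c) for c in calls]
    cand = []
    for ci, (chrom, pos) in enumerate(positions):
        for ti, t in enumerate(truth):
            if t.genome_ref != chrom:
                continue
            d = abs(pos - t.position)
            if d <= fp_dist:
                cand.append((d, ci, ti))
    cand.sort()
    res = BenchmarkResult(n_truth=len(truth), n_calls=len(positions))
    used_c: set[int] = set()
    used_t: set[int] = set()
    for d, ci, ti in cand:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        if d <= exact_tol:
            res.n_exact += 1
        elif d <= near_tol:
            res.n_within100 += 1
        else:
            res.n_within500 += 1
    res.n_false_positive = len(positions) - len(used_c)
    res.n_missed = len(truth) - len(used_t)
    matched = res.n_exact + res.n_within100 + res.n_within500
    res.recall = matched / len(truth) if truth else 0.0
    res.fp_rate = res.n_false_positive / len(positions) if positions else 0.0
    return res
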