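"""Sequence and alignment I/O.

Reads the standard formats the pipeline touches (FASTA, SAM/BAM), builds the
combined genome + transposable-element mapping reference, optionally drives
the external ``bwa``/``samtools`` binaries, and streams alignment records as
mate-joined read pairs.

Coordinates are 0-based half-open internally; anything user-facing is 1-based
inclusive.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

# CIGAR operation groups (pysam numeric codes)
_QUERY_OPS = frozenset((0, 1, 4, 7, 8))   # consume query: M I S = X
_REF_OPS = frozenset((0, 2, 3, 7, 8))     # consume reference: M D N = X
_ALIGN_OPS = frozenset((0, 7, 8))         # aligned bases: M = X
SOFT_CLIP = 4
HARD_CLIP = 5


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase-sequence map.

    Names are the first whitespace-delimited token of each header. A file
    with leading non-header content raises a ``ValueError`` naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA, line {lineno} precedes any '>' header"
                )
            break
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA record name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        log.warning("FASTA file %s contains no records", path)
    return seqs


def write_fasta(path, seqs: dict[str, str], width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Reference handling


@dataclass
class ReferenceSet:
    """The genome sequences plus the single mobile-element sequence.

    The element is carried as one extra reference sequence so that read pairs
    bridging an insertion show up directly as inter-reference pairs after
    alignment.
    """

    genome: dict[str, str]
    te_name: str
    te_sequence: str

    def __post_init__(self):
        if self.te_name in self.genome:
            raise ValueError(
                f"TE name {self.te_name!r} collides with a genome sequence name"
            )

    @property
    def names(self) -> list[str]:
        return list(self.genome) + [self.te_name]

    def lengths(self) -> dict[str, int]:
        out = {n: len(s) for n, s in self.genome.items()}
        out[self.te_name] = len(self.te_sequence)
        return out

    def sequence(self, name: str) -> str:
        if name == self.te_name:
            return self.te_sequence
        return self.genome[name]


def build_combined_reference(genome_fasta, te_fasta, out_path) -> ReferenceSet:
    """Concatenate genome records and the single TE record into one FASTA.

    Returns the in-memory :class:`ReferenceSet`; the combined FASTA written
    to ``out_path`` is the mapping reference handed to the aligner.
    """
    genome = read_fasta(genome_fasta)
    te = read_fasta(te_fasta)
    if len(te) != 1:
        raise ValueError(f"{te_fasta}: TE FASTA must contain exactly one record, found {len(te)}")
    (te_name, te_seq), = te.items()
    refset = ReferenceSet(genome=genome, te_name=te_name, te_sequence=te_seq)
    combined = dict(genome)
    combined[te_name] = te_seq
    write_fasta(out_path, combined)
    return refset


def align_reads(fastq1, fastq2, combined_ref, out_bam, threads: int = 1,
                min_score: int = 20) -> Path:
    """Map paired reads to the combined reference with ``bwa mem -T <min_score>``.

    The minimum output alignment score of 20 ensures at least 20 bp of each
    read is properly aligned before a record is emitted, matching the
    informative-pair overlap threshold downstream.  Produces a
    coordinate-sorted, indexed BAM.
    """
    for tool in ("bwa", "samtools"):
        if shutil.which(tool) is None:
            raise RuntimeError(
                f"external tool {tool!r} not found on PATH; either install it or "
                "run the caller on a pre-aligned, name- or coordinate-sorted BAM/SAM"
            )
    combined_ref = Path(combined_ref)
    out_bam = Path(out_bam)
    if not Path(str(combined_ref) + ".bwt").exists():
        subprocess.run(["bwa", "index", str(combined_ref)], check=True,
                       capture_output=True)
    mem = subprocess.Popen(
        ["bwa", "mem", "-T", str(min_score), "-t", str(threads),
         str(combined_ref), str(fastq1), str(fastq2)],
        stdout=subprocess.PIPE, stderr=subprocess.DEVNULL,
    )
    sort = subprocess.run(
        ["samtools", "sort", "-@", str(threads), "-o", str(out_bam), "-"],
        stdin=mem.stdout, check=True, capture_output=True,
    )
    mem.stdout.close()
    if mem.wait() != 0:
        raise RuntimeError("bwa mem failed")
    del sort
    subprocess.run(["samtools", "index", str(out_bam)], check=True,
                   capture_output=True)
    with pysam.AlignmentFile(str(out_bam)) as fh:
        n = fh.mapped + fh.unmapped
    if n == 0:
        log.warning("alignment produced an empty BAM (%s)", out_bam)
    return out_bam


# ---------------------------------------------------------------------------
# Alignment records and pair streaming


@dataclass(frozen=True)
class AlignmentRecord:
    """One SAM alignment record, reference-forward oriented."""

    query_name: str
    reference_name: str
    pos: int                      # 0-based leftmost
    strand: str                   # '+' or '-'
    cigar: tuple                  # ((op, length), ...) pysam op codes
    mapq: int
    sequence: str                 # SEQ field (reference-forward)
    is_supplementary: bool = False
    is_read1: bool = True

    @property
    def reference_end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.pos + sum(l for op, l in self.cigar if op in _REF_OPS)

    @property
    def aligned_query_length(self) -> int:
        return sum(l for op, l in self.cigar if op in _ALIGN_OPS)

    def _edge_ops(self, edge: str):
        ops = list(self.cigar)
        if edge == "right":
            ops = ops[::-1]
        # hard clips carry no sequence; skip them when measuring soft clips
        for op, length in ops:
            if op == HARD_CLIP:
                continue
            return op, length
        return None, 0

    def soft_clip(self, edge: str) -> int:
        """Length of the soft clip at the 'left' or 'right' reference edge."""
        op, length = self._edge_ops(edge)
        return length if op == SOFT_CLIP else 0

    def soft_clip_seq(self, edge: str) -> str:
        n = self.soft_clip(edge)
        if n == 0 or not self.sequence:
            return ""
        return self.sequence[:n] if edge == "left" else self.sequence[-n:]

    @property
    def total_soft_clip(self) -> int:
        return self.soft_clip("left") + self.soft_clip("right")


@dataclass
class AlignedPair:
    """One read pair: both primary records plus any supplementary records."""

    name: str
    mate1: AlignmentRecord | None
    mate2: AlignmentRecord | None
    supplementary: list = field(default_factory=list)

    @property
    def mates(self) -> list[AlignmentRecord]:
        return [m for m in (self.mate1, self.mate2) if m is not None]


def _to_record(aln: pysam.AlignedSegment) -> AlignmentRecord:
    return AlignmentRecord(
        query_name=aln.query_name,
        reference_name=aln.reference_name,
        pos=aln.reference_start,
        strand="-" if aln.is_reverse else "+",
        cigar=tuple(aln.cigartuples or ()),
        mapq=aln.mapping_quality,
        sequence=aln.query_sequence or "",
        is_supplementary=aln.is_supplementary,
        is_read1=aln.is_read1 if aln.is_paired else True,
    )


class _PairBuilder:
    __slots__ = ("name", "recs", "seen", "supplementary", "expect_supp")

    def __init__(self, name):
        self.name = name
        self.recs = [None, None]
        self.seen = [False, False]
        self.supplementary = []
        self.expect_supp = False

    @property
    def complete(self):
        return self.seen[0] and self.seen[1]

    def pair(self) -> AlignedPair:
        return AlignedPair(self.name, self.recs[0], self.recs[1],
                           self.supplementary)


def stream_pairs(path, buffer_warn: int = 2_000_000) -> Iterator[AlignedPair]:
    """Stream a SAM/BAM (name- or coordinate-sorted) as mate-joined pairs.

    Secondary alignments are dropped; supplementary alignments are attached
    to their pair.  A pair is flushed as soon as both primaries are in hand
    and neither advertises a supplementary record (SA tag); anything else is
    held to end-of-file, with a warning above ``buffer_warn`` buffered reads.
    Orphan mates are yielded with the missing side set to ``None``.
    """
    buf: dict[str, _PairBuilder] = {}
    done: set[str] = set()
    orphans = 0
    verbosity = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for aln in fh:
                if aln.is_secondary or aln.query_name is None:
                    continue
                entry = buf.get(aln.query_name)
                if entry is None:
                    if aln.query_name in done:
                        raise ValueError(
                            f"read name {aln.query_name!r} seen again after its "
                            "pair was complete; duplicate names across libraries?"
                        )
                    entry = buf[aln.query_name] = _PairBuilder(aln.query_name)
                    if len(buf) > buffer_warn:
                        log.warning("mate buffer exceeds %d entries; input may "
                                    "be unsorted or mate-less", buffer_warn)
                if aln.is_supplementary:
                    entry.supplementary.append(_to_record(aln))
                else:
                    slot = 0 if (not aln.is_paired or aln.is_read1) else 1
                    if entry.seen[slot]:
                        raise ValueError(
                            f"duplicate primary alignment for read {aln.query_name!r} "
                            "(mate {})".format(slot + 1)
                        )
                    entry.seen[slot] = True
                    if not aln.is_unmapped:
                        entry.recs[slot] = _to_record(aln)
                    if aln.has_tag("SA"):
                        entry.expect_supp = True
                if entry.complete and not entry.expect_supp:
                    del buf[aln.query_name]
                    done.add(aln.query_name)
                    yield entry.pair()
    finally:
        pysam.set_verbosity(verbosity)
    for entry in buf.values():
        if not entry.complete:
            orphans += 1
        yield entry.pair()
    if orphans:
        log.info("%d read pairs had a missing mate record", orphans)
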