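"""Shared fixtures: small synthetic references and in-memory pair builders."""

import re

import pytest

from teseek import ReferenceSet
from teseek.io_sam import AlignedPair, AlignmentRecord
from teseek import simulate as sim

_OPS = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}


def parse_cigar(cig: str) -> tuple:
    return tuple((_OPS[m[1]], int(m[0]))
                 for m in re.findall(r"(\d+)([MIDNSHP=X])", cig))


def make_record(name, ref, pos, strand="+", cigar="100M", seq="", mapq=60,
                read1=True, supplementary=False) -> AlignmentRecord:
    return AlignmentRecord(query_name=name, reference_name=ref, pos=pos,
                           strand=strand, cigar=parse_cigar(cigar), mapq=mapq,
                           sequence=seq, is_supplementary=supplementary,
                           is_read1=read1)


def make_pair(mate1, mate2, supplementary=()) -> AlignedPair:
    some = mate1 or mate2
    name = some.query_name if some is not None else "unmapped"
    return AlignedPair(name=name, mate1=mate1, mate2=mate2,
                       supplementary=list(supplementary))


@pytest.fixture(scope="session")
def small_refset() -> ReferenceSet:
    """50-kb single-chromosome genome plus a 1-kb LTR element."""
    genome = sim.generate_genome(n_seq=1, seq_len=50_000, seed=11)
    te_name, te_seq = sim.random_te(length=1_000, ltr_len=150, seed=12)
    return ReferenceSet(genome=genome, te_name=te_name, te_sequence=te_seq)


@pytest.fixture(scope="session")
def tnt1_refset() -> ReferenceSet:
    """100-kb genome plus a full-length (5334 bp) synthetic element."""
    genome = sim.generate_genome(n_seq=1, seq_len=100_000, seed=21)
    te_name, te_seq = sim.random_te(seed=22)
    return ReferenceSet(genome=genome, te_name=te_name, te_sequence=te_seq)
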