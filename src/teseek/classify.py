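"""Read-pair classification.

Every pair streamed from the alignment is assigned exactly one category:

* ``background`` — both mates mapped to the genome, no TE evidence; these
  pairs carry the non-insertion allele and are counted later for zygosity.
* ``cross`` — one mate completely on the genome, the other on the TE; they
  localise an insertion to within roughly one insert size.
* ``clipped`` — at least one read covers both genome and TE across the
  junction; the soft-clip boundary pins the insertion to the base.
* ``uninformative`` — everything else (unmapped, TE-only, sub-threshold
  overlap).

A pair is informative only when its TE overlap is at least
``min_te_overlap`` (default 20 bp), the same bound the aligner's minimum
output score enforces per read.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io_sam import AlignedPair, AlignmentRecord, ReferenceSet
from .util import hamming, revcomp

log = logging.getLogger(__name__)

CATEGORIES = ("background", "cross", "clipped", "uninformative")


@dataclass
class ClassifyParams:
    min_te_overlap: int = 20      # bp of TE sequence required on some read
    max_mismatch_frac: float = 0.1  # tolerated mismatch fraction in clip matching
    max_genome_clip: int = 5      # incidental clipping allowed on a "complete" genome mate


@dataclass
class Evidence:
    """One informative pair, annotated with which junction it supports.

    ``side`` follows the pointing convention: evidence whose genome-side
    alignment points rightward (towards increasing coordinates) supports the
    LEFT junction of the insertion; leftward-pointing evidence supports the
    RIGHT junction.  ``genome_pos`` is the 1-based genome-side anchor (the
    clip point for clipped evidence, the inner alignment edge for cross
    evidence).
    """

    name: str
    category: str                 # 'cross' | 'clipped'
    genome_ref: str
    genome_pos: int               # 1-based anchor
    side: str                     # 'left' | 'right'
    te_overlap_bp: int
    mapq: int
    clip_coord: int | None = None  # 1-based, clipped evidence only
    te_end: str | None = None      # 'start' | 'end'
    te_strand: str | None = None   # '+' | '-'


def _terminus_match(clip_seq: str, te_seq: str, edge: str,
                    max_mismatch_frac: float):
    """Match a terminal soft-clip against the TE termini.

    A clip at the *right* edge of a genome alignment continues into the
    element, so it must look like the TE 5' start (forward insertion) or the
    reverse complement of the TE 3' end (reverse insertion); a left-edge clip
    is the mirror case.  Returns ``(te_end, te_strand)`` or ``None``.
    """
    k = len(clip_seq)
    if k == 0 or k > len(te_seq):
        return None
    if edge == "right":
        cands = ((te_seq[:k], "start", "+"), (revcomp(te_seq[-k:]), "end", "-"))
    else:
        cands = ((te_seq[-k:], "end", "+"), (revcomp(te_seq[:k]), "start", "-"))
    allow = int(max_mismatch_frac * k)
    clip_seq = clip_seq.upper()
    best = None
    for cand, end, strand in cands:
        d = hamming(clip_seq, cand)
        if d <= allow and (best is None or d < best[0]):
            best = (d, end, strand)
    return (best[1], best[2]) if best else None


def _te_supplementary(pair: AlignedPair, mate: AlignmentRecord, te_name: str):
    for s in pair.supplementary:
        if s.reference_name == te_name and s.is_read1 == mate.is_read1:
            return s
    return None


def te_overlap_length(pair: AlignedPair, te_name: str, te_sequence: str,
                      max_mismatch_frac: float = 0.1) -> tuple[int, str]:
    """Number of query bases of this pair attributable to the TE.

    Checked in order: a mate whose primary alignment is on the TE, a
    supplementary alignment on the TE, then the longest terminal soft-clip
    whose sequence matches either TE terminus (in either orientation) within
    ``max_mismatch_frac``.  Returns ``(bp, how)`` with ``how`` one of
    ``mapped_to_te``, ``supplementary_to_te``, ``clip_matches_te_terminus``,
    ``none``.
    """
    on_te = [m for m in pair.mates if m.reference_name == te_name]
    if on_te:
        return max(m.aligned_query_length for m in on_te), "mapped_to_te"
    supp = [s for s in pair.supplementary if s.reference_name == te_name]
    if supp:
        return max(s.aligned_query_length for s in supp), "supplementary_to_te"
    best = 0
    for m in pair.mates:
        for edge in ("left", "right"):
            clip = m.soft_clip_seq(edge)
            if len(clip) <= best:
                continue
            if _terminus_match(clip, te_sequence, edge, max_mismatch_frac):
                best = len(clip)
    if best:
        return best, "clip_matches_te_terminus"
    return 0, "none"


def _clipped_evidence(pair: AlignedPair, genome_mates, refset: ReferenceSet,
                      params: ClassifyParams) -> Evidence | None:
    candidates = []
    for m in genome_mates:
        for edge in ("left", "right"):
            clip_len = m.soft_clip(edge)
            if clip_len < params.min_te_overlap:
                continue
            hit = _terminus_match(m.soft_clip_seq(edge), refset.te_sequence,
                                  edge, params.max_mismatch_frac)
            overlap = clip_len
            if hit is None:
                supp = _te_supplementary(pair, m, refset.te_name)
                if supp is None or supp.aligned_query_length < params.min_te_overlap:
                    continue
                overlap = supp.aligned_query_length
                te_len = len(refset.te_sequence)
                mid = (supp.pos + supp.reference_end) / 2
                hit = ("start" if mid < te_len / 2 else "end",
                       "+" if supp.strand == m.strand else "-")
            te_end, te_strand = hit
            if edge == "right":
                side, coord = "left", m.reference_end       # 1-based last aligned base
            else:
                side, coord = "right", m.pos + 1            # 1-based first aligned base
            candidates.append((overlap, -coord, Evidence(
                name=pair.name, category="clipped",
                genome_ref=m.reference_name, genome_pos=coord, side=side,
                te_overlap_bp=overlap, mapq=m.mapq, clip_coord=coord,
                te_end=te_end, te_strand=te_strand,
            )))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], -c[1]))
    return candidates[0][2]


def classify_pair(pair: AlignedPair, refset: ReferenceSet,
                  params: ClassifyParams | None = None):
    """Assign one category to a pair.

    Returns ``(category, evidence, background_interval)`` where ``evidence``
    is set only for informative categories and ``background_interval`` is the
    0-based half-open outer insert interval ``(ref, start, end)`` for
    background pairs with both mates on the same sequence.  Clipped takes
    precedence over cross: a clipped pair also fixes the exact junction.
    """
    if params is None:
        params = ClassifyParams()
    mates = pair.mates
    if not mates:
        return "uninformative", None, None
    te_name = refset.te_name
    genome_mates = [m for m in mates if m.reference_name != te_name]
    te_mates = [m for m in mates if m.reference_name == te_name]

    ev = _clipped_evidence(pair, genome_mates, refset, params)
    if ev is not None:
        return "clipped", ev, None

    if genome_mates and te_mates:
        g, t = genome_mates[0], te_mates[0]
        if (g.total_soft_clip <= params.max_genome_clip
                and t.aligned_query_length >= params.min_te_overlap):
            side = "left" if g.strand == "+" else "right"
            anchor = g.reference_end if side == "left" else g.pos + 1
            te_len = len(refset.te_sequence)
            mid = (t.pos + t.reference_end) / 2
            ev = Evidence(
                name=pair.name, category="cross", genome_ref=g.reference_name,
                genome_pos=anchor, side=side,
                te_overlap_bp=t.aligned_query_length, mapq=g.mapq,
                te_end="start" if mid < te_len / 2 else "end",
                te_strand=t.strand,
            )
            return "cross", ev, None
        return "uninformative", None, None

    if te_mates and not genome_mates:
        return "uninformative", None, None

    if len(genome_mates) == 2:
        m1, m2 = genome_mates
        bg = None
        if m1.reference_name == m2.reference_name:
            bg = (m1.reference_name, min(m1.pos, m2.pos),
                  max(m1.reference_end, m2.reference_end))
        return "background", None, bg

    return "uninformative", None, None


class BackgroundIndex:
    """Outer insert intervals of background pairs, queryable by position."""

    def __init__(self, sequence_names: Iterable[str] = ()):
        self._acc: dict[str, list] = defaultdict(list)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._names = set(sequence_names)
        self._final = False

    def add(self, ref: str, start: int, end: int):
        self._acc[ref].append((start, end))
        self._names.add(ref)

    def finalize(self):
        for ref, ivs in self._acc.items():
            arr = np.asarray(ivs, dtype=np.int64).reshape(-1, 2)
            self._starts[ref] = arr[:, 0]
            self._ends[ref] = arr[:, 1]
        self._acc.clear()
        self._final = True
        return self

    def count_spanning(self, ref: str, position: int) -> int:
        """Pairs whose outer interval strictly contains 1-based ``position``."""
        if not self._final:
            self.finalize()
        if ref not in self._names:
            raise KeyError(f"sequence {ref!r} not present in the background index")
        if ref not in self._starts:
            return 0
        s, e = self._starts[ref], self._ends[ref]
        return int(np.count_nonzero((s < position - 1) & (e > position)))


class DepthIndex:
    """Per-base coverage from every genome-mapped read, for the depth filter."""

    def __init__(self):
        self._acc: dict[str, list] = defaultdict(list)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._final = False

    def add(self, ref: str, start: int, end: int):
        self._acc[ref].append((start, end))

    def finalize(self):
        for ref, ivs in self._acc.items():
            arr = np.asarray(ivs, dtype=np.int64).reshape(-1, 2)
            order = np.argsort(arr[:, 0], kind="stable")
            self._starts[ref] = arr[order, 0]
            self._ends[ref] = arr[order, 1]
        self._acc.clear()
        self._final = True
        return self

    def mean_depth(self, ref: str, wstart: int, wend: int) -> float:
        """Mean per-base coverage over the 0-based half-open window."""
        if not self._final:
            self.finalize()
        if wend <= wstart:
            return 0.0
        if ref not in self._starts:
            return 0.0
        s, e = self._starts[ref], self._ends[ref]
        hi = np.searchsorted(s, wend, side="left")  # reads starting past the window
        s, e = s[:hi], e[:hi]
        ov = np.minimum(e, wend) - np.maximum(s, wstart)
        ov = ov[ov > 0]
        return float(ov.sum()) / (wend - wstart)


@dataclass
class ClassifyResult:
    evidence: list            # sorted by (genome_ref, genome_pos)
    background: BackgroundIndex
    depth: DepthIndex
    stats: dict[str, int] = field(default_factory=dict)


def classify_all(pairs: Iterable[AlignedPair], refset: ReferenceSet,
                 params: ClassifyParams | None = None) -> ClassifyResult:
    """Classify every pair; collect evidence, background index and coverage."""
    if params is None:
        params = ClassifyParams()
    evidence: list[Evidence] = []
    background = BackgroundIndex(refset.genome.keys())
    depth = DepthIndex()
    stats = {c: 0 for c in CATEGORIES}
    te_name = refset.te_name
    for pair in pairs:
        cat, ev, bg = classify_pair(pair, refset, params)
        stats[cat] += 1
        if ev is not None:
            evidence.append(ev)
        if bg is not None:
            background.add(*bg)
        for m in pair.mates:
            if m.reference_name != te_name:
                depth.add(m.reference_name, m.pos, m.reference_end)
    evidence.sort(key=lambda e: (e.genome_ref, e.genome_pos, e.name))
    background.finalize()
    depth.finalize()
    return ClassifyResult(evidence, background, depth, stats)


def evidence_table(evidence: Iterable[Evidence]) -> pd.DataFrame:
    """BED-like debug dump of the evidence list (1-based positions)."""
    rows = [dict(chrom=e.genome_ref, pos=e.genome_pos, side=e.side,
                 category=e.category, te_overlap_bp=e.te_overlap_bp,
                 te_end=e.te_end, te_strand=e.te_strand, mapq=e.mapq,
                 name=e.name)
            for e in evidence]
    return pd.DataFrame(rows, columns=["chrom", "pos", "side", "category",
                                       "te_overlap_bp", "te_end", "te_strand",
                                       "mapq", "name"])
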