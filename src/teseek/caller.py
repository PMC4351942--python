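"""Candidate clustering, filtering and breakpoint refinement.

Evidence pairs are single-linkage clustered along the genome; each cluster is
a candidate insertion.  Four filters discard likely artefacts: average
mapping quality of the informative pairs at least 1 (repetitive-region
guard), mean sequencing depth around the insertion between 2 and 300, at
least 3 supporting pairs, and at least one supporting pair on each side of
the insertion.  Clipped reads then refine the exact breakpoint and the
target-site duplication (TSD); the TE orientation is a majority vote over
the evidence.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .classify import DepthIndex, Evidence

log = logging.getLogger(__name__)


@dataclass
class CallerParams:
    min_avg_mapq: float = 1.0
    depth_min: float = 2.0
    depth_max: float = 300.0
    min_support: int = 3
    require_both_ends: bool = True
    # evidence anchors for one insertion spread over at most about one insert
    # size per junction: mean + 3 sd of the library insert distribution
    cluster_window: int = 650
    max_tsd: int = 20
    insert_mean: int = 500


@dataclass
class CandidateCluster:
    genome_ref: str
    left_evidence: list
    right_evidence: list

    @property
    def evidence(self) -> list:
        return self.left_evidence + self.right_evidence

    @property
    def n_support(self) -> int:
        return len(self.left_evidence) + len(self.right_evidence)

    @property
    def n_clipped(self) -> int:
        return sum(1 for e in self.evidence if e.category == "clipped")

    @property
    def span(self) -> tuple[int, int]:
        pos = [e.genome_pos for e in self.evidence]
        return min(pos), max(pos)

    @property
    def avg_mapq(self) -> float:
        ev = self.evidence
        return sum(e.mapq for e in ev) / len(ev)


@dataclass
class InsertionCall:
    genome_ref: str
    position: int                    # 1-based start of the TSD (or best estimate)
    precision: str                   # 'exact' | 'interval'
    interval: tuple[int, int] | None
    tsd_sequence: str
    tsd_len: int
    te_strand: str                   # '+', '-', 'unknown'
    n_support: int
    n_left: int
    n_right: int
    n_clipped: int
    avg_mapq: float
    depth: float
    filters_failed: tuple = ()
    tsd_warning: bool = False
    n_background: int | None = None
    p_value: float | None = None
    zygosity: str | None = None
    region: str | None = None        # filled by the annotation step


def cluster_evidence(evidence: Iterable[Evidence],
                     cluster_window: int = 650) -> list[CandidateCluster]:
    """Single-linkage clustering of position-sorted evidence.

    Consecutive evidence on the same sequence within ``cluster_window`` bp
    joins one cluster; members are split into left-/right-junction lists.
    """
    clusters: list[CandidateCluster] = []
    cur: list[Evidence] = []

    def _flush():
        if cur:
            clusters.append(CandidateCluster(
                genome_ref=cur[0].genome_ref,
                left_evidence=[e for e in cur if e.side == "left"],
                right_evidence=[e for e in cur if e.side == "right"],
            ))

    prev = None
    for e in sorted(evidence, key=lambda e: (e.genome_ref, e.genome_pos, e.name)):
        if prev is not None and (e.genome_ref != prev.genome_ref
                                 or e.genome_pos - prev.genome_pos > cluster_window):
            _flush()
            cur = []
        cur.append(e)
        prev = e
    _flush()
    return clusters


def apply_filters(cluster: CandidateCluster, depth: float,
                  params: CallerParams | None = None) -> list[str]:
    """Return the (possibly empty) list of failed filter names."""
    if params is None:
        params = CallerParams()
    fails = []
    if cluster.avg_mapq < params.min_avg_mapq:
        fails.append("min_avg_mapq")
    if not (params.depth_min <= depth <= params.depth_max):
        fails.append("depth_range")
    if cluster.n_support < params.min_support:
        fails.append("min_support")
    if params.require_both_ends and (not cluster.left_evidence
                                     or not cluster.right_evidence):
        fails.append("both_ends")
    return fails


def _modal(values: Iterable[int]) -> int:
    """Most frequent value; ties broken towards the smallest (deterministic)."""
    counts = Counter(values)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def refine_breakpoint(cluster: CandidateCluster, genome: dict[str, str],
                      max_tsd: int = 20):
    """Infer the insertion position and TSD from clipped evidence.

    ``L`` is the modal clip coordinate of left-junction clipped reads (the
    last reference base before the element, i.e. the end of the duplicated
    target site); ``R`` the modal clip coordinate of right-junction clipped
    reads (the first reference base after the element, i.e. the TSD start).
    With both junctions clipped, ``tsd_len = L - R + 1`` and the call sits at
    ``R``.  One-sided clips still give an exact coordinate but no TSD; with
    no clipped reads the call is the midpoint between the innermost anchors,
    flagged ``interval``.

    Returns ``(position, tsd_sequence, precision, tsd_warning)``.
    """
    left_clips = [e.clip_coord for e in cluster.left_evidence
                  if e.category == "clipped"]
    right_clips = [e.clip_coord for e in cluster.right_evidence
                   if e.category == "clipped"]
    if left_clips and right_clips:
        L, R = _modal(left_clips), _modal(right_clips)
        tsd_len = L - R + 1
        if 0 <= tsd_len <= max_tsd:
            seq = genome[cluster.genome_ref][R - 1: R - 1 + tsd_len]
            return R, seq, "exact", False
        log.warning("implausible TSD of %d bp at %s:%d; junctions may be "
                    "mis-paired", tsd_len, cluster.genome_ref, R)
        return R, "", "exact", True
    if left_clips:
        return _modal(left_clips), "", "exact", False
    if right_clips:
        return _modal(right_clips), "", "exact", False
    left_anchor = max((e.genome_pos for e in cluster.left_evidence), default=None)
    right_anchor = min((e.genome_pos for e in cluster.right_evidence), default=None)
    if left_anchor is None:
        return right_anchor, "", "interval", False
    if right_anchor is None:
        return left_anchor, "", "interval", False
    return (left_anchor + right_anchor) // 2, "", "interval", False


def call_orientation(cluster: CandidateCluster) -> str:
    """Majority vote on the element orientation.

    A clipped read votes the strand its clip matched a TE terminus on.  A
    cross pair votes forward when its TE mate's strand is opposite to the
    direction the genome mate points (the FR library geometry); both rules
    are insensitive to identical LTR termini.  A verdict needs an 80:20
    majority, otherwise ``unknown``.
    """
    votes = []
    for e in cluster.evidence:
        if e.te_strand is None:
            continue
        if e.category == "clipped":
            votes.append(e.te_strand)
        else:
            fwd = (e.side == "left") == (e.te_strand == "-")
            votes.append("+" if fwd else "-")
    if not votes:
        return "unknown"
    frac_fwd = votes.count("+") / len(votes)
    if frac_fwd >= 0.8:
        return "+"
    if frac_fwd <= 0.2:
        return "-"
    return "unknown"


def call_insertions(evidence: Iterable[Evidence], depth_index: DepthIndex,
                    genome: dict[str, str],
                    params: CallerParams | None = None):
    """Cluster, filter and refine; returns ``(calls, rejected)``.

    Rejected candidates keep their failure reasons — essential for debugging
    and for post-hoc inspection of repeat-region artefacts.
    """
    if params is None:
        params = CallerParams()
    calls: list[InsertionCall] = []
    rejected: list[InsertionCall] = []
    for cluster in cluster_evidence(evidence, params.cluster_window):
        ref_len = len(genome[cluster.genome_ref])
        lo, hi = cluster.span
        mid = (lo + hi) // 2
        depth = depth_index.mean_depth(
            cluster.genome_ref,
            max(0, mid - params.insert_mean),
            min(ref_len, mid + params.insert_mean),
        )
        fails = apply_filters(cluster, depth, params)
        pos, tsd, precision, warn = refine_breakpoint(cluster, genome,
                                                      params.max_tsd)
        call = InsertionCall(
            genome_ref=cluster.genome_ref, position=pos, precision=precision,
            interval=(lo, hi) if precision == "interval" else None,
            tsd_sequence=tsd, tsd_len=len(tsd),
            te_strand=call_orientation(cluster),
            n_support=cluster.n_support, n_left=len(cluster.left_evidence),
            n_right=len(cluster.right_evidence), n_clipped=cluster.n_clipped,
            avg_mapq=cluster.avg_mapq, depth=depth,
            filters_failed=tuple(fails), tsd_warning=warn,
        )
        (calls if not fails else rejected).append(call)
    key = lambda c: (c.genome_ref, c.position)
    calls.sort(key=key)
    rejected.sort(key=key)
    return calls, rejected


# ---------------------------------------------------------------------------
# Tabular output

_COLUMNS = ["chrom", "pos", "precision", "interval_start", "interval_end",
            "tsd", "tsd_len", "strand", "n_support", "n_left", "n_right",
            "n_clipped", "avg_mapq", "depth", "filters", "n_background",
            "p_value", "zygosity", "region"]


def calls_to_dataframe(calls: Iterable[InsertionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(dict(
            chrom=c.genome_ref, pos=c.position, precision=c.precision,
            interval_start=c.interval[0] if c.interval else ".",
            interval_end=c.interval[1] if c.interval else ".",
            tsd=c.tsd_sequence or ".", tsd_len=c.tsd_len, strand=c.te_strand,
            n_support=c.n_support, n_left=c.n_left, n_right=c.n_right,
            n_clipped=c.n_clipped, avg_mapq=f"{c.avg_mapq:.2f}",
            depth=f"{c.depth:.2f}",
            filters=",".join(c.filters_failed) if c.filters_failed else "PASS",
            n_background=c.n_background if c.n_background is not None else ".",
            p_value=f"{c.p_value:.4e}" if c.p_value is not None else ".",
            zygosity=c.zygosity or ".", region=c.region or ".",
        ))
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_calls_tsv(calls: Iterable[InsertionCall], path) -> Path:
    path = Path(path)
    calls_to_dataframe(calls).to_csv(path, sep="\t", index=False)
    return path


def write_calls_bed(calls: Iterable[InsertionCall], path, te_name: str) -> Path:
    """BED6: 0-based half-open TSD footprint, score = supporting pairs."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in calls:
            start = c.position - 1
            end = start + max(c.tsd_len, 1)
            strand = c.te_strand if c.te_strand in "+-" else "."
            fh.write(f"{c.genome_ref}\t{start}\t{end}\t{te_name}\t"
                     f"{c.n_support}\t{strand}\n")
    return path
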