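"""Genomic-context annotation of calls and genic-enrichment testing.

Calls are classified against a GFF3 annotation as exon, intron (inside a
gene but outside every exon) or intergenic, and the observed number of genic
insertions is compared to the null of uniform random placement by a
permutation test (the add-one estimator avoids zero p-values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import gffutils
import numpy as np
from intervaltree import IntervalTree

log = logging.getLogger(__name__)


@dataclass
class FeatureIndex:
    """Per-sequence interval trees for gene and exon spans (0-based half-open)."""

    genes: dict[str, IntervalTree]
    exons: dict[str, IntervalTree]
    genome_lengths: dict[str, int]


def build_feature_index(gff3_path, genome_lengths: Mapping[str, int]) -> FeatureIndex:
    """Load genes and exons from a GFF3 file into interval trees."""
    db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: dict[str, IntervalTree] = {}
    exons: dict[str, IntervalTree] = {}
    for ftype, trees in (("gene", genes), ("exon", exons)):
        for feat in db.features_of_type(ftype):
            trees.setdefault(feat.seqid, IntervalTree()).addi(
                feat.start - 1, feat.end)  # GFF3 is 1-based inclusive
    return FeatureIndex(genes=genes, exons=exons,
                        genome_lengths=dict(genome_lengths))


def classify_position(index: FeatureIndex, genome_ref: str,
                      position: int) -> str:
    """Classify a 1-based position as 'exon', 'intron' or 'intergenic'."""
    if genome_ref not in index.genome_lengths:
        raise KeyError(f"unknown sequence name {genome_ref!r}")
    point = position - 1
    tree = index.exons.get(genome_ref)
    if tree is not None and tree.overlaps(point):
        return "exon"
    tree = index.genes.get(genome_ref)
    if tree is not None and tree.overlaps(point):
        return "intron"
    return "intergenic"


def annotate_calls(index: FeatureIndex, calls: Iterable) -> None:
    """Fill the ``region`` field of each call in place."""
    for call in calls:
        call.region = classify_position(index, call.genome_ref, call.position)


def enrichment_test(index: FeatureIndex, calls: Iterable,
                    genome_lengths: Mapping[str, int] | None = None,
                    n_perm: int = 10_000, seed: int = 0) -> dict:
    """Permutation test for genic enrichment of the called insertions.

    Each permutation drops as many uniform random positions on the genome as
    there are calls and counts genic (exon or intron) hits;
    ``perm_p = (1 + #{permutations >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if genome_lengths is None:
        genome_lengths = index.genome_lengths
    positions = [(c.genome_ref, c.position) if hasattr(c, "genome_ref") else c
                 for c in calls]
    observed = sum(
        classify_position(index, chrom, pos) != "intergenic"
        for chrom, pos in positions
    )
    k = len(positions)
    rng = np.random.default_rng(seed)
    names = list(genome_lengths)
    lens = np.array([genome_lengths[n] for n in names], dtype=float)
    probs = lens / lens.sum()
    chrom_idx = rng.choice(len(names), size=(n_perm, k), p=probs)
    unif = rng.random(size=(n_perm, k))
    perm_counts = np.zeros(n_perm, dtype=int)
    gene_trees = {n: index.genes.get(n) for n in names}
    for i in range(n_perm):
        hits = 0
        for j in range(k):
            chrom = names[chrom_idx[i, j]]
            pos = int(unif[i, j] * genome_lengths[chrom])
            tree = gene_trees[chrom]
            if tree is not None and tree.overlaps(pos):
                hits += 1
        perm_counts[i] = hits
    perm_p = (1 + int(np.count_nonzero(perm_counts >= observed))) / (n_perm + 1)
    return {
        "n_calls": k,
        "observed_genic": int(observed),
        "expected_genic_mean": float(perm_counts.mean()),
        "perm_p": float(perm_p),
        "n_perm": n_perm,
    }
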