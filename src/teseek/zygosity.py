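"""Heterozygous / homozygous typing of called insertions.

At a heterozygous insertion the allele carrying the element contributes
informative pairs at both junctions while the other allele contributes
background pairs spanning the site, giving an expected supportive:background
ratio of 2:1 — i.e. a background fraction of 1/3.  A homozygous insertion
leaves (almost) no background.  The one-sided exact binomial lower tail on
the background count under p = 1/3 therefore separates the two states: a
significant *deficit* of background pairs means homozygous.

An excess of background beyond the heterozygous expectation is still called
heterozygous (mosaicism is out of scope).  No multiple-testing correction is
applied across loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy.stats import binom

from .caller import InsertionCall
from .classify import BackgroundIndex

P_BACKGROUND = 1.0 / 3.0
ALPHA = 0.05


@dataclass
class ZygosityResult:
    n_support: int
    n_background: int
    p_value: float
    call: str  # 'homozygous' | 'heterozygous'


def count_background(background_index: BackgroundIndex, genome_ref: str,
                     position: int) -> int:
    """Background pairs whose outer insert interval strictly contains the
    1-based insertion position."""
    return background_index.count_spanning(genome_ref, position)


def zygosity_test(n_support: int, n_background: int,
                  p_bg: float = P_BACKGROUND,
                  alpha: float = ALPHA) -> ZygosityResult:
    """Exact one-sided binomial lower-tail test on the background count.

    ``p_value = P(X <= n_background)`` for
    ``X ~ Binomial(n_support + n_background, p_bg)``; the locus is called
    homozygous iff ``p_value < alpha``.
    """
    n = n_support + n_background
    if n < 1:
        raise ValueError("zygosity test needs at least one observed pair")
    p_value = float(binom.cdf(n_background, n, p_bg))
    call = "homozygous" if p_value < alpha else "heterozygous"
    return ZygosityResult(n_support, n_background, p_value, call)


def annotate_zygosity(calls: Iterable[InsertionCall],
                      background_index: BackgroundIndex,
                      p_bg: float = P_BACKGROUND,
                      alpha: float = ALPHA) -> None:
    """Fill the zygosity fields of each call in place."""
    for call in calls:
        nb = count_background(background_index, call.genome_ref, call.position)
        res = zygosity_test(call.n_support, nb, p_bg=p_bg, alpha=alpha)
        call.n_background = res.n_background
        call.p_value = res.p_value
        call.zygosity = res.call
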