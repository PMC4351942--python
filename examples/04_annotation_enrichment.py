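"""Genomic context of insertions and genic-enrichment testing.

Builds a synthetic annotation in which ~30% of a 400-kb genome is genic,
places 20 insertion calls deliberately inside genes, classifies each call as
exon / intron / intergenic, and runs the permutation enrichment test: 10,000
rounds of 20 uniform random positions give the null distribution of genic
hits, and the add-one permutation p-value measures how unusual the observed
genic count is.  Elements that prefer genic regions (as insertional
mutagens do) show p-values near the 1/(n_perm+1) floor.
"""

import tempfile
from collections import Counter
from pathlib import Path

import numpy as np

from teseek import annotate as ann
from teseek import simulate as sim

tmp = Path(tempfile.mkdtemp(prefix="teseek_ex4_"))
lengths = {"chr1": 400_000}
gff = sim.random_annotation(lengths, tmp / "genes.gff3", genic_fraction=0.3,
                            seed=31)
index = ann.build_feature_index(gff, lengths)

# 20 calls dropped inside genes (a genic-preferring element)
gene_ivs = sorted(index.genes["chr1"])[:20]
calls = [("chr1", iv.begin + (iv.end - iv.begin) // 2 + 1) for iv in gene_ivs]
regions = Counter(ann.classify_position(index, c, p) for c, p in calls)
print("regions of the 20 calls:", dict(regions))

enr = ann.enrichment_test(index, calls, n_perm=10_000, seed=32)
print(f"observed genic: {enr['observed_genic']}/{enr['n_calls']}")
print(f"expected genic under uniform placement: "
      f"{enr['expected_genic_mean']:.2f}")
print(f"permutation p-value: {enr['perm_p']:.2e}")

# contrast: uniformly random calls are not enriched
rng = np.random.default_rng(33)
random_calls = [("chr1", int(p) + 1) for p in rng.integers(0, 400_000, 20)]
enr0 = ann.enrichment_test(index, random_calls, n_perm=10_000, seed=34)
print(f"\nuniform random calls: observed {enr0['observed_genic']} genic, "
      f"p = {enr0['perm_p']:.2f}")
print("A p-value near 1e-4 (the add-one floor at 10,000 permutations) "
      "indicates strong genic preference; random calls stay orders of "
      "magnitude away from that floor.")
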