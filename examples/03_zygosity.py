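"""Heterozygous versus homozygous typing of called insertions.

Simulates one genome carrying two insertions — one on a single allele (het),
one on both alleles (hom) — at 30X, and shows how the binomial test
separates them.  At a het locus the non-insertion allele contributes
read pairs that span the site without touching the element ("background"),
expected at 1/3 of the total; at a hom locus background all but vanishes,
and the one-sided binomial lower tail on the background count drops below
alpha = 0.05.
"""

import tempfile
from pathlib import Path

import teseek as ts
from teseek import simulate as sim

tmp = Path(tempfile.mkdtemp(prefix="teseek_ex3_"))

genome = sim.generate_genome(n_seq=1, seq_len=200_000, seed=21)
te_name, te_seq = sim.random_te(length=2_000, ltr_len=300, seed=22)
refset = ts.ReferenceSet(genome=genome, te_name=te_name, te_sequence=te_seq)

# haplotype A carries both insertions, haplotype B only the homozygous one
_, truth = sim.insert_te(genome, te_seq, 2, min_gap=60_000, seed=23)
truth[0].zygosity, truth[1].zygosity = "het", "hom"
hap_a = sim.apply_truth(genome, te_seq, truth)
hap_b = sim.apply_truth(genome, te_seq, [truth[1]])

sim.simulate_reads(hap_a, sim.SimParams(coverage=15, seed=24),
                   tmp / "a1.fq", tmp / "a2.fq", label="hapA")
sim.simulate_reads(hap_b, sim.SimParams(coverage=15, seed=25),
                   tmp / "b1.fq", tmp / "b2.fq", label="hapB")
sim.mix_heterozygous(tmp / "a1.fq", tmp / "a2.fq", tmp / "b1.fq",
                     tmp / "b2.fq", tmp / "x1.fq", tmp / "x2.fq", seed=26)
sam = sim.project_truth_alignments(
    tmp / "x1.fq", tmp / "x2.fq", refset,
    {"hapA": truth, "hapB": [truth[1]]}, tmp / "p.sam")

res = ts.classify_all(ts.stream_pairs(sam), refset)
calls, _ = ts.call_insertions(res.evidence, res.depth, genome)
ts.annotate_zygosity(calls, res.background)

truth_by_pos = {t.position: t.zygosity for t in truth}
print(f"{'pos':>8} {'support':>8} {'background':>10} {'p-value':>10} "
      f"{'call':>14} truth")
for c in calls:
    print(f"{c.position:>8} {c.n_support:>8} {c.n_background:>10} "
          f"{c.p_value:>10.3g} {c.zygosity:>14} {truth_by_pos[c.position]}")
print("\nThe p-value is P(X <= background) for X ~ Binomial(support + "
      "background, 1/3); below 0.05 the locus is called homozygous.")
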