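"""Synthetic-data generation: genomes, mutagenesis, reads, projection, scoring."""

import numpy as np
import pysam
import pytest

from teseek import ReferenceSet
from teseek import simulate as sim
from teseek.util import revcomp


# ---------------------------------------------------------------------------
# Genome generation


def test_genome_deterministic_given_seed():
    a = sim.generate_genome(n_seq=2, seq_len=20_000, seed=7)
    b = sim.generate_genome(n_seq=2, seq_len=20_000, seed=7)
    assert a == b
    c = sim.generate_genome(n_seq=2, seq_len=20_000, seed=8)
    assert a != c


def test_repeat_free_genome_has_unique_100mers():
    genome = sim.generate_genome(n_seq=1, seq_len=200_000,
                                 repeat_fraction=0.0, seed=1)
    seq = genome["chr1"]
    kmers = {seq[i:i + 100] for i in range(0, len(seq) - 100, 1)}
    assert len(kmers) == len(seq) - 100


def test_repeat_fraction_duplicates_kmers():
    genome = sim.generate_genome(n_seq=1, seq_len=200_000,
                                 repeat_fraction=0.2, repeat_unit_len=500,
                                 seed=1)
    seq = genome["chr1"]
    kmers = [seq[i:i + 100] for i in range(0, len(seq) - 100)]
    dup_frac = 1 - len(set(kmers)) / len(kmers)
    assert dup_frac >= 0.15


# ---------------------------------------------------------------------------
# Mutagenesis


def test_insert_te_length_bookkeeping():
    genome = sim.generate_genome(n_seq=1, seq_len=10_000, seed=2)
    te = "ACGT" * 250  # 1000 bp
    mutant, truth = sim.insert_te(genome, te, 1, tsd_len=5, min_gap=100,
                                  edge_margin=2_000, seed=3)
    assert len(mutant["chr1"]) == 10_000 + 1_000 + 5
    mutant0, _ = sim.insert_te(genome, te, 1, tsd_len=0, min_gap=100,
                               edge_margin=2_000, seed=3)
    assert len(mutant0["chr1"]) == 10_000 + 1_000


@pytest.mark.parametrize("strand", ["+", "-"])
def test_splice_oracle_at_each_site(strand):
    """Independent string-splice check: the mutant locally equals
    TSD + element + TSD-anchored flank at the recorded position."""
    genome = sim.generate_genome(n_seq=1, seq_len=30_000, seed=4)
    _, te = sim.random_te(length=800, ltr_len=100, seed=5)
    mutant, truth = sim.insert_te(genome, te, 2, tsd_len=5, min_gap=8_000,
                                  orientation_mix=1.0 if strand == "-" else 0.0,
                                  seed=6)
    ref = genome["chr1"]
    ins = te if strand == "+" else revcomp(te)
    for t in truth:
        p = t.position
        expected = (ref[:p - 1] + ref[p - 1:p + 4] + ins + ref[p - 1:p + 4])
        assert mutant["chr1"].startswith(expected[:p + 4 + len(te) + 5])
        break  # first site suffices: later sites shift coordinates


def test_insert_te_refuses_overcrowded_genome():
    genome = {"chr1": "ACGT" * 2_500}
    with pytest.raises(ValueError, match="fewer insertions|too small"):
        sim.insert_te(genome, "A" * 1_000, 50, min_gap=1_000)


def test_truth_table_roundtrip(tmp_path):
    genome = sim.generate_genome(n_seq=2, seq_len=30_000, seed=9)
    _, te = sim.random_te(length=600, ltr_len=80, seed=9)
    _, truth = sim.insert_te(genome, te, 4, min_gap=5_000, seed=10)
    sim.write_truth(truth, tmp_path / "truth.tsv")
    assert sim.read_truth(tmp_path / "truth.tsv") == truth


# ---------------------------------------------------------------------------
# Read simulation


def test_pair_count_matches_coverage(tmp_path):
    genome = sim.generate_genome(n_seq=1, seq_len=100_000, seed=11)
    params = sim.SimParams(coverage=10, seed=12)
    n = sim.simulate_reads(genome, params, tmp_path / "a1.fq",
                           tmp_path / "a2.fq")
    assert n == 5_000  # coverage * length / (2 * read_len)


def test_error_free_reads_are_exact_substrings(tmp_path):
    genome = sim.generate_genome(n_seq=1, seq_len=50_000, seed=13)
    params = sim.SimParams(coverage=2, error_rate=0.0, seed=14)
    sim.simulate_reads(genome, params, tmp_path / "b1.fq", tmp_path / "b2.fq")
    seq = genome["chr1"]
    with pysam.FastxFile(str(tmp_path / "b1.fq")) as f1, \
            pysam.FastxFile(str(tmp_path / "b2.fq")) as f2:
        for r1, r2 in zip(f1, f2):
            _, chrom, start, flen = sim.parse_read_name(r1.name)
            assert r1.sequence == seq[start:start + 100]
            assert r2.sequence == revcomp(seq[start + flen - 100:start + flen])


def test_empirical_error_rate(tmp_path):
    """Substitution rate over >= 1 Mb of simulated bases within 3 SE of the
    requested 0.001."""
    genome = sim.generate_genome(n_seq=1, seq_len=600_000, seed=15)
    params = sim.SimParams(coverage=4, error_rate=0.001, seed=16)
    sim.simulate_reads(genome, params, tmp_path / "c1.fq", tmp_path / "c2.fq")
    seq = genome["chr1"]
    mism = bases = 0
    with pysam.FastxFile(str(tmp_path / "c1.fq")) as f1:
        for r in f1:
            _, chrom, start, flen = sim.parse_read_name(r.name)
            src = seq[start:start + 100]
            mism += sum(a != b for a, b in zip(r.sequence, src))
            bases += 100
    assert bases >= 1_000_000
    se = (0.001 * 0.999 / bases) ** 0.5
    assert abs(mism / bases - 0.001) <= 3 * se


def test_simulation_deterministic(tmp_path):
    genome = sim.generate_genome(n_seq=1, seq_len=20_000, seed=17)
    for tag in ("x", "y"):
        params = sim.SimParams(coverage=3, seed=18)
        sim.simulate_reads(genome, params, tmp_path / f"{tag}1.fq",
                           tmp_path / f"{tag}2.fq")
    assert (tmp_path / "x1.fq").read_bytes() == (tmp_path / "y1.fq").read_bytes()
    assert (tmp_path / "x2.fq").read_bytes() == (tmp_path / "y2.fq").read_bytes()


def test_heterozygous_mixing(tmp_path):
    genome = sim.generate_genome(n_seq=1, seq_len=40_000, seed=19)
    for label, seed in (("mut", 20), ("ref", 21)):
        params = sim.SimParams(coverage=5, seed=seed)
        sim.simulate_reads(genome, params, tmp_path / f"{label}1.fq",
                           tmp_path / f"{label}2.fq", label=label)
    n = sim.mix_heterozygous(tmp_path / "mut1.fq", tmp_path / "mut2.fq",
                             tmp_path / "ref1.fq", tmp_path / "ref2.fq",
                             tmp_path / "mix1.fq", tmp_path / "mix2.fq",
                             seed=22)
    names1, names2 = [], []
    with pysam.FastxFile(str(tmp_path / "mix1.fq")) as fh:
        names1 = [r.name for r in fh]
    with pysam.FastxFile(str(tmp_path / "mix2.fq")) as fh:
        names2 = [r.name for r in fh]
    assert names1 == names2  # pair integrity preserved
    assert len(names1) == n == 2_000
    mut_frac = sum(n_.split("|")[1] == "mut" for n_ in names1) / len(names1)
    assert abs(mut_frac - 0.5) <= 0.02
    # same seed reproduces the order
    sim.mix_heterozygous(tmp_path / "mut1.fq", tmp_path / "mut2.fq",
                         tmp_path / "ref1.fq", tmp_path / "ref2.fq",
                         tmp_path / "mix1b.fq", tmp_path / "mix2b.fq", seed=22)
    assert (tmp_path / "mix1.fq").read_bytes() == (tmp_path / "mix1b.fq").read_bytes()


# ---------------------------------------------------------------------------
# Truth projection


def _write_fastq(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'?' * len(seq)}\n")


def test_projection_geometry(small_refset, tmp_path):
    """A read inside the element lands on the TE reference; a junction
    straddler becomes a genome record soft-clipped at the splice point."""
    genome = small_refset.genome
    te = small_refset.te_sequence
    truth = [sim.TruthRecord("chr1", 10_001, tsd_len=5, te_strand="+")]
    mutant = sim.apply_truth(genome, te, truth)["chr1"]
    # fragment fully inside the element: mutant coords of TE = [10005, 11005)
    frag_a = (10_100, 300)
    # fragment straddling the left junction by 30 bp: read1 = 70 genome + 30 TE
    frag_b = (10_005 - 70, 300)
    _write_fastq(tmp_path / "p1.fq", [
        (f"sr|mut|chr1|{frag_a[0]}|{frag_a[1]}|0",
         mutant[frag_a[0]:frag_a[0] + 100]),
        (f"sr|mut|chr1|{frag_b[0]}|{frag_b[1]}|1",
         mutant[frag_b[0]:frag_b[0] + 100]),
    ])
    _write_fastq(tmp_path / "p2.fq", [
        (f"sr|mut|chr1|{frag_a[0]}|{frag_a[1]}|0",
         revcomp(mutant[frag_a[0] + 200:frag_a[0] + 300])),
        (f"sr|mut|chr1|{frag_b[0]}|{frag_b[1]}|1",
         revcomp(mutant[frag_b[0] + 200:frag_b[0] + 300])),
    ])
    sam = sim.project_truth_alignments(tmp_path / "p1.fq", tmp_path / "p2.fq",
                                       small_refset, {"mut": truth},
                                       tmp_path / "p.sam")
    with pysam.AlignmentFile(str(sam)) as fh:
        recs = {(r.query_name, r.is_read1): r for r in fh}
    inside = recs[(f"sr|mut|chr1|{frag_a[0]}|{frag_a[1]}|0", True)]
    assert inside.reference_name == small_refset.te_name
    assert inside.reference_start == 10_100 - 10_005
    straddle = recs[(f"sr|mut|chr1|{frag_b[0]}|{frag_b[1]}|1", True)]
    assert straddle.reference_name == "chr1"
    assert straddle.cigarstring == "70M30S"
    # 70M ends at the last reference base before the element (TSD end)
    assert straddle.reference_end == 10_005
    # the clipped 30 bp are exactly the element start
    assert straddle.query_sequence[70:] == te[:30]


def test_projection_rejects_foreign_read_names(small_refset, tmp_path):
    _write_fastq(tmp_path / "q1.fq", [("not_a_sim_read", "A" * 100)])
    _write_fastq(tmp_path / "q2.fq", [("not_a_sim_read", "T" * 100)])
    with pytest.raises(ValueError, match="not encode"):
        sim.project_truth_alignments(tmp_path / "q1.fq", tmp_path / "q2.fq",
                                     small_refset, {"mut": []},
                                     tmp_path / "q.sam")


# ---------------------------------------------------------------------------
# Benchmark evaluation


def _truth(*positions, chrom="chr1"):
    return [sim.TruthRecord(chrom, p) for p in positions]


def test_evaluator_distance_bins():
    truth = _truth(10_000, 50_000, 90_000)
    calls = [("chr1", 10_000), ("chr1", 50_080), ("chr1", 90_600)]
    res = sim.evaluate_calls(calls, truth)
    assert res.n_exact == 1
    assert res.n_within100 == 1
    assert res.n_within500 == 0
    assert res.n_false_positive == 1  # 600 bp away exceeds the 500-bp bound
    assert res.n_missed == 1
    assert res.recall == pytest.approx(2 / 3)


def test_evaluator_greedy_matches_truth_once():
    truth = _truth(10_000)
    calls = [("chr1", 10_000), ("chr1", 10_050)]
    res = sim.evaluate_calls(calls, truth)
    assert res.n_exact == 1 and res.n_false_positive == 1


def test_evaluator_conservation_property():
    """Bins always partition the calls; matches + missed always cover truth."""
    rng = np.random.default_rng(0)
    for _ in range(25):
        truth = _truth(*rng.choice(200_000, size=8, replace=False))
        calls = [("chr1", int(p)) for p in rng.choice(200_000, size=10)]
        res = sim.evaluate_calls(calls, truth)
        assert (res.n_exact + res.n_within100 + res.n_within500
                + res.n_false_positive) == res.n_calls
        assert (res.n_exact + res.n_within100 + res.n_within500
                + res.n_missed) == res.n_truth
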