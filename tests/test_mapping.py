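"""Seed-and-verify mapping, coverage profiles, SAM interchange."""
import numpy as np
import pytest

import venomtx as v
from oracles import interval_stabbing_depth, revcomp
from venomtx.mapping import AlignmentSet, Placement, coverage_profile, map_reads
from venomtx.records import Contig, Read, ReadSet


def _reads(seqs, sample="s"):
    return ReadSet(sample, [Read(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)])


def exhaustive_best(read, contigs, max_mm):
    """Scan every offset on every contig and strand for the fewest mismatches."""
    best = None
    for ci, contig in enumerate(contigs):
        seq = contig.sequence
        for oriented, strand in ((read, "+"), (revcomp(read), "-")):
            for start in range(len(seq) - len(read) + 1):
                mm = sum(a != b for a, b in zip(oriented, seq[start : start + len(read)]))
                if mm <= max_mm and (best is None or mm < best[0]):
                    best = (mm, ci, start, strand)
    return best


def test_exact_substring_maps_with_zero_mismatches():
    rng = np.random.default_rng(0)
    contig = Contig("c1", "".join(rng.choice(list("ACGT"), size=120)))
    read = contig.sequence[10:40]
    aln = map_reads(_reads([read]), [contig], seed_length=10)
    (p,) = aln.placements
    assert (p.contig_id, p.start, p.end, p.mismatches) == ("c1", 10, 40, 0)


def test_foreign_read_is_unmapped():
    contig = Contig("c1", "A" * 200)
    aln = map_reads(_reads(["CGCGCGCGCGCGCGCGCGCGCG"]), [contig], seed_length=10)
    assert aln.unmapped == ["r0"]
    assert aln.placements == []


def test_empty_contig_set_leaves_all_unmapped():
    aln = map_reads(_reads(["ACGT" * 10]), [], seed_length=10)
    assert aln.unmapped == ["r0"]


def test_reads_with_planted_mismatches_match_exhaustive_oracle():
    rng = np.random.default_rng(11)
    contigs = [
        Contig(f"c{i}", "".join(rng.choice(list("ACGT"), size=1000))) for i in range(3)
    ]
    for trial in range(40):
        ci = int(rng.integers(3))
        start = int(rng.integers(0, 1000 - 80))
        read = list(contigs[ci].sequence[start : start + 80])
        n_mm = int(rng.integers(0, 3))
        for pos in rng.choice(80, size=n_mm, replace=False):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        if rng.random() < 0.5:
            read = list(revcomp("".join(read)))
        read = "".join(read)
        aln = map_reads(_reads([read]), contigs, seed_length=15, max_mismatches=4)
        oracle = exhaustive_best(read, contigs, 4)
        (p,) = aln.placements
        assert p.mismatches == oracle[0]
        assert (p.start, p.contig_id) == (oracle[2], contigs[oracle[1]].contig_id)


def test_fractional_weights_conserve_read_mass():
    contig_a = Contig("a", "ACGT" * 30)
    contig_b = Contig("b", "ACGT" * 30)  # identical: every read ties
    reads = _reads([contig_a.sequence[0:40], contig_a.sequence[20:60]])
    aln = map_reads(reads, [contig_a, contig_b], seed_length=10)
    total = sum(p.weight for p in aln.placements)
    assert total == pytest.approx(len(reads.reads))
    counts = aln.counts()
    assert counts["a"] + counts["b"] == pytest.approx(2.0)


def test_primary_policy_assigns_whole_reads():
    contig_a = Contig("a", "ACGT" * 30)
    contig_b = Contig("b", "ACGT" * 30)
    reads = _reads([contig_a.sequence[0:40]])
    aln = map_reads(reads, [contig_a, contig_b], seed_length=10, policy="primary")
    assert len(aln.placements) == 1
    assert aln.placements[0].weight == 1.0


def test_coverage_profile_single_read_interval():
    contig = Contig("c", "A" * 20)
    aln = AlignmentSet(placements=[Placement("r0", "c", 0, 10, "+", 0)])
    profile = coverage_profile(aln, contig)
    assert list(profile.depth) == [1] * 10 + [0] * 10


def test_coverage_profile_no_reads_is_zero():
    profile = coverage_profile(AlignmentSet(), Contig("c", "A" * 15))
    assert list(profile.depth) == [0] * 15


def test_coverage_matches_interval_stabbing_oracle():
    rng = np.random.default_rng(12)
    length = 200
    intervals = []
    placements = []
    for i in range(100):
        s = int(rng.integers(0, length - 10))
        e = s + int(rng.integers(1, 10))
        intervals.append((s, e))
        placements.append(Placement(f"r{i}", "c", s, e, "+", 0))
    profile = coverage_profile(AlignmentSet(placements=placements), Contig("c", "A" * length))
    assert list(profile.depth) == interval_stabbing_depth(intervals, length)


def test_sam_roundtrip(tmp_path, small_transcriptome):
    reads = v.simulate_reads(small_transcriptome, 100, 100, 0.0, seed=3)
    contigs = [
        Contig(t.transcript_id, t.sequence) for t in small_transcriptome.transcripts
    ]
    aln = map_reads(reads, contigs, seed_length=20)
    path = tmp_path / "aln.sam"
    v.write_sam(aln, contigs, reads, str(path))
    loaded = v.read_sam(str(path))
    original = sorted((p.read_id, p.contig_id, p.start, p.end, p.strand, p.mismatches)
                      for p in aln.placements)
    roundtrip = sorted((p.read_id, p.contig_id, p.start, p.end, p.strand, p.mismatches)
                       for p in loaded.placements)
    assert roundtrip == original
    assert sorted(loaded.unmapped) == sorted(aln.unmapped)
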