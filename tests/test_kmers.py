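"""Canonical k-mer counting, cross-sample flagging, and read filtering."""
import random

import pytest

from oracles import brute_force_kmer_counts
from venomtx.kmers import (
    FlaggedKmerSet,
    KmerSpectrum,
    canonical_kmer,
    count_kmers,
    decode_kmer,
    encode_kmer,
    filter_reads,
    flag_kmers,
)
from venomtx.records import Read, ReadSet


def _reads(seqs, sample="s"):
    return ReadSet(sample, [Read(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)])


def test_single_window_is_canonicalized():
    spectrum = count_kmers(_reads(["ACGTACG"]), 7)
    assert spectrum.as_strings() == {"ACGTACG": 1}
    assert canonical_kmer("CGTACGT") == "ACGTACG"


def test_read_shorter_than_k_contributes_nothing():
    assert count_kmers(_reads(["ACGT"]), 7).counts == {}


def test_windows_with_ambiguous_bases_are_skipped():
    spectrum = count_kmers(_reads(["ACGNACGT"]), 4)
    assert spectrum.as_strings() == {"ACGT": 1}


def test_encode_decode_roundtrip():
    for kmer in ["A", "ACGT", "TTTGACA", "GTACGTACGTACG"]:
        assert decode_kmer(encode_kmer(kmer), len(kmer)) == kmer


@pytest.mark.parametrize("k", [5, 9, 31])
def test_counting_matches_brute_force_enumeration(k):
    random.seed(k)
    seqs = [
        "".join(random.choice("ACGTN" if i % 7 == 0 else "ACGT")
                for _ in range(random.randint(3, 80)))
        for i in range(100)
    ]
    spectrum = count_kmers(_reads(seqs), k)
    assert spectrum.as_strings() == brute_force_kmer_counts(seqs, k)


def _spectrum(counts, sample="s", k=4):
    return KmerSpectrum(sample, k, {encode_kmer(km): c for km, c in counts.items()})


def test_identical_spectra_flag_nothing_at_high_fold():
    sp = _spectrum({"ACGT": 5, "AAAA": 2})
    assert len(flag_kmers(sp, sp, 1000.0)) == 0


def test_fold_ratio_boundary_is_inclusive():
    focal = _spectrum({"AAAA": 1}, "f")
    other = _spectrum({"AAAA": 1000}, "o")
    assert len(flag_kmers(focal, other, 1000.0)) == 1  # ratio exactly 1000

    focal = _spectrum({"AAAA": 2}, "f")
    other = _spectrum({"AAAA": 1999}, "o")
    assert len(flag_kmers(focal, other, 1000.0)) == 0  # ratio 999.5


def test_kmers_absent_from_focal_are_never_flagged():
    focal = _spectrum({"AAAA": 1}, "f")
    other = _spectrum({"AAAA": 2000, "CCCC": 99999}, "o")
    flagged = flag_kmers(focal, other, 1000.0)
    assert flagged.kmers == {encode_kmer("AAAA")}


def test_mismatched_k_raises():
    with pytest.raises(ValueError, match="k mismatch"):
        flag_kmers(_spectrum({}, k=4), _spectrum({}, k=5), 10)


def test_flagging_is_antisymmetric_at_fold_above_one():
    random.seed(3)
    kmers = ["AAAA", "ACGT", "GGCC", "TTTA", "CAGT"]
    a = _spectrum({km: random.randint(1, 5000) for km in kmers}, "a")
    b = _spectrum({km: random.randint(1, 5000) for km in kmers}, "b")
    ab = flag_kmers(a, b, 1000.0).kmers
    ba = flag_kmers(b, a, 1000.0).kmers
    assert not (ab & ba)


def _flagged(kmers, k, sample="s", other="o"):
    return FlaggedKmerSet(sample, other, 1000.0, k, {encode_kmer(km) for km in kmers})


def test_no_flagged_kmers_keeps_all_long_reads():
    reads = _reads(["ACGT" * 30, "TTTT" * 30])
    kept, report = filter_reads(reads, [], min_length=75)
    assert len(kept) == 2
    assert report.n_removed == 0


def test_flagged_coverage_fraction_rule():
    # one flagged 57-mer occurrence covers 57/150 = 0.38 >= 0.25 of the read
    random.seed(5)
    read_seq = "".join(random.choice("ACGT") for _ in range(150))
    flagged_kmer = canonical_kmer(read_seq[40 : 40 + 57])
    reads = _reads([read_seq])
    kept, report = filter_reads(reads, [_flagged([flagged_kmer], 57)], 0.25, 75)
    assert len(kept) == 0
    (decision,) = report.decisions
    assert decision[3] == "contamination"
    assert decision[1] == pytest.approx(57 / 150)


def test_minimum_length_rule_removes_short_reads():
    reads = _reads(["A" * 74, "A" * 75])
    kept, report = filter_reads(reads, [], min_length=75)
    assert [r.read_id for r in kept] == ["r1"]
    assert report.removed_by_reason() == {"too_short": 1}


def test_filter_is_invariant_to_read_order():
    random.seed(9)
    seqs = ["".join(random.choice("ACGT") for _ in range(80)) for _ in range(30)]
    flagged = [_flagged([canonical_kmer(seqs[0][10:31])], 21)]
    fwd = ReadSet("s", [Read(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)])
    rev = ReadSet("s", list(reversed(fwd.reads)))
    _, rep1 = filter_reads(fwd, flagged, 0.25, 75)
    _, rep2 = filter_reads(rev, flagged, 0.25, 75)
    assert sorted(rep1.decisions) == sorted(rep2.decisions)


def test_flagged_sets_with_differing_k_raise():
    reads = _reads(["ACGT" * 30])
    with pytest.raises(ValueError, match="disagree on k"):
        filter_reads(reads, [_flagged(["AAAA"], 4), _flagged(["AAAAA"], 5)])
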