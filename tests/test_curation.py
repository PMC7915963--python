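"""Chimera screening, species assignment, isoform clustering."""
import numpy as np
import pytest

import venomtx as v
from venomtx.curation import assign_species, cluster_isoforms, detect_chimera
from venomtx.mapping import CoverageProfile
from venomtx.orfs import Hit, OrfRecord, ToxinAnnotation
from venomtx.records import Contig


def _profile(depths, cid="c"):
    return CoverageProfile(cid, np.asarray(depths))


def test_uniform_coverage_is_clean():
    call = detect_chimera(_profile([50] * 400))
    assert call.verdict == "clean"
    assert call.breakpoints == []


def test_sharp_step_is_called_at_the_boundary():
    call = detect_chimera(_profile([100] * 250 + [2] * 250), 10, 25, 10)
    assert call.verdict == "chimeric"
    assert len(call.breakpoints) == 1
    pos, fold = call.breakpoints[0]
    assert pos == 250
    assert fold == pytest.approx(50.0)


def test_step_detection_is_translation_invariant():
    base = [80] * 300 + [4] * 200
    pos0 = detect_chimera(_profile(base), 10, 25, 10).breakpoints[0][0]
    shifted = [80] * 350 + [4] * 150
    pos1 = detect_chimera(_profile(shifted), 10, 25, 10).breakpoints[0][0]
    assert pos1 - pos0 == 50


def test_contig_shorter_than_two_windows_is_indeterminate():
    call = detect_chimera(_profile([10] * 30), window=25)
    assert call.verdict == "indeterminate"


def test_low_depth_steps_are_not_called():
    call = detect_chimera(_profile([8] * 250 + [0] * 250), 10, 25, 10)
    assert call.verdict == "clean"


def _annotation(taxon):
    orf = OrfRecord("c", "+", 0, 0, 6, "ATGTGA", "M")
    hit = Hit("ref", "3FTx", taxon, 100.0, 95.0)
    return ToxinAnnotation(orf, "3FTx", "ref", 100.0, 95.0, [hit])


def test_single_species_reads_give_unanimous_assignment():
    contig = Contig("c", "A" * 100)
    assignment = assign_species(
        contig,
        {"spA": 5000.0, "spB": 0.0},
        _annotation("spA"),
        {"spA": _profile(np.full(100, 50)), "spB": _profile(np.zeros(100))},
    )
    assert assignment.assigned_species == "spA"
    assert assignment.confidence == "3/3"


def test_fold_rule_with_agreeing_indicators():
    contig = Contig("c", "A" * 100)
    depth_b = np.zeros(100)
    depth_b[:30] = 3  # sparse partial coverage
    assignment = assign_species(
        contig,
        {"spA": 1000.0, "spB": 5.0},
        _annotation("spA"),
        {"spA": _profile(np.full(100, 40)), "spB": _profile(depth_b)},
        expression_fold=5.0,
    )
    assert assignment.assigned_species == "spA"
    assert assignment.expression_vote == "spA"
    assert assignment.similarity_vote == "spA"
    assert assignment.coverage_vote == "spA"
    assert assignment.confidence == "3/3"


def test_split_votes_are_ambiguous():
    contig = Contig("c", "A" * 100)
    # expression equivocal (below fold), similarity says A, coverage says B
    assignment = assign_species(
        contig,
        {"spA": 100.0, "spB": 80.0},
        _annotation("spA"),
        {"spA": _profile(np.zeros(100)), "spB": _profile(np.full(100, 30))},
        expression_fold=5.0,
    )
    assert assignment.expression_vote == "equivocal"
    assert assignment.assigned_species == "ambiguous"
    assert assignment.confidence == "ambiguous"


def test_zero_expression_species_never_wins():
    contig = Contig("c", "A" * 100)
    assignment = assign_species(
        contig,
        {"spA": 0.0, "spB": 0.0},
        _annotation("spA"),
        {"spA": _profile(np.zeros(100)), "spB": _profile(np.zeros(100))},
    )
    assert assignment.assigned_species == "ambiguous"


def test_identical_sequences_form_one_cluster():
    seq = "ACGTTGCA" * 30
    clusters = cluster_isoforms([Contig("a", seq), Contig("b", seq)], 0.99)
    assert len(clusters) == 1
    assert sorted(clusters[0].member_ids) == ["a", "b"]


def test_dissimilar_sequences_stay_apart():
    rng = np.random.default_rng(5)
    a = "".join(rng.choice(list("ACGT"), size=200))
    b = "".join(rng.choice(list("ACGT"), size=200))
    clusters = cluster_isoforms([Contig("a", a), Contig("b", b)], 0.99)
    assert len(clusters) == 2


def test_centroid_is_longest_member_and_partition_holds():
    rng = np.random.default_rng(6)
    base = "".join(rng.choice(list("ACGT"), size=400))
    variant = list(base)
    variant[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[variant[50]]
    contigs = [
        Contig("short", base[:380]),
        Contig("long", base),
        Contig("var", "".join(variant)),
    ]
    clusters = cluster_isoforms(contigs, 0.99)
    assert len(clusters) == 1
    assert clusters[0].centroid_id == "long"
    assert sum(len(c) for c in clusters) == len(contigs)


def test_clusters_sorted_by_member_count():
    rng = np.random.default_rng(7)
    fam1 = "".join(rng.choice(list("ACGT"), size=300))
    fam2 = "".join(rng.choice(list("ACGT"), size=300))
    contigs = [Contig("a1", fam1), Contig("a2", fam1), Contig("a3", fam1),
               Contig("b1", fam2)]
    clusters = cluster_isoforms(contigs, 0.99)
    assert [len(c) for c in clusters] == [3, 1]
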