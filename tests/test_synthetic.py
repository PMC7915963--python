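"""Ground-truth properties of the synthetic-data generator."""
import math

import numpy as np
import pytest

import venomtx as v
from venomtx.io import read_fastq, write_fastq
from venomtx.orfs import find_orfs, translate
from venomtx.records import Contig, reverse_complement


def test_single_transcript_single_family_has_complete_orf():
    ts = v.generate_transcriptome(1, {"3FTx": 1.0}, seed=0)
    (t,) = ts.transcripts
    assert t.family == "3FTx"
    cds = t.sequence[t.orf_start : t.orf_end]
    assert cds.startswith("ATG")
    assert cds[-3:] in ("TAA", "TAG", "TGA")
    assert "*" not in translate(cds)
    found = find_orfs(Contig(t.transcript_id, t.sequence), 50)
    assert (t.orf_start, t.orf_end) in {(o.start, o.end) for o in found}


def test_generator_is_deterministic_for_fixed_seed():
    a = v.generate_transcriptome(8, seed=5)
    b = v.generate_transcriptome(8, seed=5)
    assert [(t.transcript_id, t.sequence, t.family, t.weight) for t in a.transcripts] \
        == [(t.transcript_id, t.sequence, t.family, t.weight) for t in b.transcripts]
    ra = v.simulate_reads(a, 200, 100, 0.01, seed=6)
    rb = v.simulate_reads(b, 200, 100, 0.01, seed=6)
    assert [(r.read_id, r.sequence) for r in ra] == [(r.read_id, r.sequence) for r in rb]


def test_family_frequencies_converge_to_profile():
    n = 10000
    ts = v.generate_transcriptome(
        n, {"3FTx": 0.7, "PLA2": 0.3}, mean_length=300, seed=2
    )
    n_3ftx = sum(1 for t in ts.transcripts if t.family == "3FTx")
    sigma = math.sqrt(n * 0.7 * 0.3)
    assert abs(n_3ftx - 0.7 * n) <= 3 * sigma


def test_family_expression_shares_match_profile():
    ts = v.generate_transcriptome(50, {"3FTx": 0.6, "kunitz": 0.4}, seed=3)
    total = sum(t.weight for t in ts.transcripts)
    share = sum(t.weight for t in ts.transcripts if t.family == "3FTx") / total
    assert share == pytest.approx(0.6)


def test_empty_family_profile_rejected():
    with pytest.raises(ValueError):
        v.generate_transcriptome(5, {}, seed=0)


def test_error_free_reads_are_exact_substrings(small_transcriptome):
    reads = v.simulate_reads(small_transcriptome, 300, 120, 0.0, seed=4)
    seqs = {t.transcript_id: t.sequence for t in small_transcriptome.transcripts}
    for r in reads:
        tid, start, strand = r.source_span
        window = seqs[tid][start : start + 120]
        expected = window if strand == "+" else reverse_complement(window)
        assert r.sequence == expected


def test_substitution_error_rate_matches_binomial_expectation(small_transcriptome):
    n, length, rate = 10000, 150, 0.01
    reads = v.simulate_reads(small_transcriptome, n, length, rate, seed=8)
    seqs = {t.transcript_id: t.sequence for t in small_transcriptome.transcripts}
    total_mm = 0
    for r in reads:
        tid, start, strand = r.source_span
        window = seqs[tid][start : start + length]
        if strand == "-":
            window = reverse_complement(window)
        total_mm += sum(a != b for a, b in zip(r.sequence, window))
    trials = n * length
    sigma = math.sqrt(trials * rate * (1 - rate))
    assert abs(total_mm - trials * rate) <= 3 * sigma


def test_zero_reads_is_empty_not_error(small_transcriptome):
    assert len(v.simulate_reads(small_transcriptome, 0, 100, 0.01, seed=1)) == 0


def test_read_length_longer_than_all_transcripts_rejected(small_transcriptome):
    with pytest.raises(ValueError, match="read_length"):
        v.simulate_reads(small_transcriptome, 10, 10**6, 0.0, seed=1)


def test_spike_rate_zero_is_identity(small_batch):
    tsets, _ = small_batch
    rsets = [v.simulate_reads(ts, 500, 100, 0.0, seed=50 + i) for i, ts in enumerate(tsets)]
    batch = v.spike_contamination(rsets, 0.0, seed=1)
    for orig, spiked in zip(rsets, batch.read_sets):
        assert [r.read_id for r in orig] == [r.read_id for r in spiked]


def test_spike_counts_match_binomial_expectation():
    ts = [v.generate_transcriptome(5, seed=60 + i, species_id=f"s{i}") for i in range(2)]
    rsets = [v.simulate_reads(t, 10000, 100, 0.0, seed=70 + i) for i, t in enumerate(ts)]
    batch = v.spike_contamination(rsets, 0.01, seed=80)
    for rs in batch.read_sets:
        n_cont = sum(1 for r in rs if r.true_source.startswith("contaminant:"))
        p = 0.01 / 0.99
        sigma = math.sqrt(10000 * p * (1 - p))
        assert abs(n_cont - 10000 * p) <= 3 * sigma


def test_spiked_reads_are_verbatim_copies(small_batch):
    _, batch = small_batch
    by_sample = {rs.sample_id: {r.sequence for r in rs} for rs in batch.read_sets}
    for rs in batch.read_sets:
        for r in rs:
            if r.true_source.startswith("contaminant:"):
                origin = r.true_source.split(":", 1)[1]
                assert r.sequence in by_sample[origin]


def test_spike_requires_two_samples():
    ts = v.generate_transcriptome(2, seed=1)
    rs = v.simulate_reads(ts, 10, 100, 0.0, seed=1)
    with pytest.raises(ValueError, match="2 samples"):
        v.spike_contamination([rs], 0.01)


def test_chimera_degenerate_join_equals_first_parent():
    a = Contig("a", "ACGT" * 25)
    b = Contig("b", "TTTT" * 25)
    chim = v.make_chimera(a, b, len(a.sequence), suffix_start=len(b.sequence))
    assert chim.contig.sequence == a.sequence


def test_chimera_construction_and_breakpoint_record():
    a = Contig("a", "A" * 100)
    b = Contig("b", "C" * 100)
    chim = v.make_chimera(a, b, 50)
    assert len(chim.contig.sequence) == 100
    assert chim.contig.sequence[:50] == "A" * 50
    assert chim.contig.sequence[50:] == "C" * 50
    assert chim.breakpoint == 50


def test_chimera_breakpoint_out_of_range():
    a = Contig("a", "A" * 10)
    with pytest.raises(ValueError, match="breakpoint"):
        v.make_chimera(a, a, 0)
    with pytest.raises(ValueError, match="breakpoint"):
        v.make_chimera(a, a, 11)


def test_zero_branch_length_leaves_ancestor_unchanged():
    anc = v.random_cds(40, seed=9)
    aln = v.evolve_codon_clade(anc, 4, 0.0, omega=1.0, seed=10)
    assert all(s == anc for s in aln.sequences)


def test_evolution_is_deterministic_and_stop_free():
    anc = v.random_cds(60, seed=11)
    a = v.evolve_codon_clade(anc, 5, 0.3, omega=2.0, kappa=2.0, seed=12)
    b = v.evolve_codon_clade(anc, 5, 0.3, omega=2.0, kappa=2.0, seed=12)
    assert a.sequences == b.sequences
    for seq in a.sequences:
        assert "*" not in v.translate(seq) if len(seq) % 3 == 0 else True


def test_neutral_evolution_matches_site_count_ratio():
    # at omega=1 the ratio of nonsynonymous to synonymous observed
    # differences approaches the ratio of nonsynonymous to synonymous site
    # counts (less ~5% from stop-bound mutations carrying no flux)
    anc = v.random_cds(2000, seed=13)
    aln = v.evolve_codon_clade(anc, 2, 0.05, omega=1.0, kappa=1.0, seed=14)
    est = v.ng86_pairwise(aln.sequences[0], aln.sequences[1])
    ratio = (est.N_diff / est.N_sites) / (est.S_diff / est.S_sites)
    assert 0.8 <= ratio <= 1.1


def test_omega_estimates_are_ordered_across_regimes():
    anc = v.random_cds(300, seed=15)
    est = {}
    for omega in (0.2, 2.4):
        aln = v.evolve_codon_clade(anc, 8, 0.1, omega=omega, kappa=2.0, seed=16)
        est[omega] = v.clade_omega(aln).pooled.omega
    assert est[0.2] < est[2.4]


def test_ancestor_with_internal_stop_rejected():
    with pytest.raises(ValueError, match="stop"):
        v.evolve_codon_clade("ATGTAAAAA", 3, 0.1, omega=1.0)


def test_fastq_roundtrip_is_lossless(tmp_path, small_transcriptome):
    reads = v.simulate_reads(small_transcriptome, 50, 100, 0.01, seed=17)
    path = tmp_path / "reads.fastq"
    write_fastq(reads, str(path))
    loaded = read_fastq(str(path))
    assert [(r.read_id, r.sequence, r.quality) for r in loaded] == [
        (r.read_id, r.sequence, r.quality) for r in reads
    ]


def test_truth_labels_never_leak_into_fastq(tmp_path, small_batch):
    _, batch = small_batch
    path = tmp_path / "s.fastq"
    write_fastq(batch.read_sets[0], str(path))
    text = path.read_text()
    assert "contaminant" not in text
    from venomtx.synthetic import batch_truth_rows

    rows = batch_truth_rows(batch)
    assert any(r["true_source"].startswith("contaminant:") for r in rows)
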