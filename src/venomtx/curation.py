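"""Contig quality control: chimera screening, species-of-origin assignment,
and isoform clustering.

Chimeric assemblies (artifactual joins of two transcripts) betray
themselves as sharp steps in read-coverage depth; the screen compares
median depth in adjacent windows.  Species of origin for each contig in a
multiplexed batch is decided by three indicators — relative expression,
similarity-search taxon, and coverage shape — combined by majority vote.
Near-identical isoforms are collapsed by greedy incremental clustering at
a 99% identity threshold (identity computed over the shorter sequence,
best-matching centroid wins, clusters sorted by size).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner

from .mapping import CoverageProfile
from .orfs import ToxinAnnotation
from .records import Contig

DEFAULT_CHIMERA_FOLD = 10.0
DEFAULT_CHIMERA_WINDOW = 25
DEFAULT_CHIMERA_MIN_DEPTH = 10
DEFAULT_EXPRESSION_FOLD = 5.0
DEFAULT_IDENTITY = 0.99
EQUIVOCAL = "equivocal"
AMBIGUOUS = "ambiguous"


@dataclass
class ChimeraCall:
    contig_id: str
    breakpoints: list[tuple[int, float]]  # (position, fold change)
    verdict: str  # "clean" | "chimeric" | "indeterminate"


@dataclass
class SpeciesAssignment:
    contig_id: str
    assigned_species: str  # species label or "ambiguous"
    expression_vote: str
    similarity_vote: str
    coverage_vote: str
    confidence: str  # "3/3" | "2/3" | "ambiguous"


@dataclass
class Cluster:
    centroid_id: str
    members: list[tuple[str, float]]  # (contig_id, identity to centroid)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> list[str]:
        return [m for m, _ in self.members]


def detect_chimera(
    profile: CoverageProfile,
    fold_threshold: float = DEFAULT_CHIMERA_FOLD,
    window: int = DEFAULT_CHIMERA_WINDOW,
    min_depth: int = DEFAULT_CHIMERA_MIN_DEPTH,
) -> ChimeraCall:
    """Call coverage-step breakpoints by adjacent-window median ratio.

    At every interior position the median depth of the ``window`` bases on
    each side is compared; positions where the higher/lower ratio reaches
    ``fold_threshold`` and the higher side reaches ``min_depth`` form
    candidate runs, each reported as one breakpoint at its maximal ratio.
    Contigs shorter than two windows are ``indeterminate``.
    """
    if fold_threshold < 1:
        raise ValueError("fold_threshold must be >= 1")
    depth = np.asarray(profile.depth, dtype=float)
    n = len(depth)
    if n < 2 * window:
        return ChimeraCall(profile.contig_id, [], "indeterminate")
    ratios = np.zeros(n)
    for i in range(window, n - window + 1):
        left = float(np.median(depth[i - window : i]))
        right = float(np.median(depth[i : i + window]))
        hi, lo = max(left, right), min(left, right)
        if hi < min_depth:
            continue
        ratios[i] = hi / lo if lo > 0 else np.inf
    breakpoints: list[tuple[int, float]] = []
    run_start = None
    for i in range(window, n - window + 2):
        firing = i <= n - window and ratios[i] >= fold_threshold
        if firing and run_start is None:
            run_start = i
        elif not firing and run_start is not None:
            segment = ratios[run_start:i]
            peak = segment.max()
            # a clean step fires over a symmetric run of tied ratios, so
            # the middle of the maximal stretch is the step position
            candidates = np.flatnonzero(segment == peak)
            best = run_start + int(candidates[len(candidates) // 2])
            breakpoints.append((best, float(peak)))
            run_start = None
    verdict = "chimeric" if breakpoints else "clean"
    return ChimeraCall(profile.contig_id, breakpoints, verdict)


def assign_species(
    contig: Contig,
    per_sample_expression: dict[str, float],
    annotation: ToxinAnnotation | None,
    profiles: dict[str, CoverageProfile],
    expression_fold: float = DEFAULT_EXPRESSION_FOLD,
    taxon_to_sample: dict[str, str] | None = None,
    breadth_full: float = 0.9,
    breadth_sparse: float = 0.5,
    min_depth: int = 1,
) -> SpeciesAssignment:
    """Majority vote of three indicators for a contig's species of origin.

    - expression vote: the sample whose TPM exceeds every other sample's by
      at least ``expression_fold``;
    - similarity vote: the sample matching the best hit's taxon;
    - coverage vote: the sample whose coverage is near-full-length
      (breadth >= ``breadth_full``) while every other sample's is sparse
      (breadth <= ``breadth_sparse``).
    An indicator that cannot decide is ``equivocal``.  The contig is
    assigned when at least two indicators agree; confidence is 3/3 when no
    indicator dissents, 2/3 when one does, ambiguous otherwise.  A species
    with zero mapped reads is never assigned.
    """
    expr_vote = EQUIVOCAL
    positives = {s: t for s, t in per_sample_expression.items() if t > 0}
    if positives:
        top_sample, top_tpm = max(positives.items(), key=lambda kv: (kv[1], kv[0]))
        others = [t for s, t in per_sample_expression.items() if s != top_sample]
        if all(top_tpm >= expression_fold * t for t in others) and (
            len(per_sample_expression) > 1 or top_tpm > 0
        ):
            expr_vote = top_sample

    sim_vote = EQUIVOCAL
    if annotation is not None and annotation.best_hit is not None:
        taxon = annotation.hits[0].taxon if annotation.hits else None
        if taxon is not None:
            mapped = (taxon_to_sample or {}).get(taxon, taxon)
            if mapped in per_sample_expression:
                sim_vote = mapped

    cov_vote = EQUIVOCAL
    breadths = {s: p.breadth(min_depth) for s, p in profiles.items()}
    full = [s for s, b in breadths.items() if b >= breadth_full]
    if len(full) == 1 and all(
        b <= breadth_sparse for s, b in breadths.items() if s != full[0]
    ):
        cov_vote = full[0]

    votes = [expr_vote, sim_vote, cov_vote]
    cast = [v for v in votes if v != EQUIVOCAL]
    # a species with no mapped reads cannot win
    cast = [v for v in cast if per_sample_expression.get(v, 0) > 0]
    assigned, confidence = AMBIGUOUS, AMBIGUOUS
    for candidate in set(cast):
        agree = cast.count(candidate)
        if agree >= 2:
            assigned = candidate
            dissent = len(cast) - agree
            confidence = "3/3" if dissent == 0 else "2/3"
            break
    return SpeciesAssignment(
        contig.contig_id, assigned, expr_vote, sim_vote, cov_vote, confidence
    )


def make_nucleotide_aligner() -> PairwiseAligner:
    """Global aligner with free end gaps (overlap-style), BLAST-like scores."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Fraction of the shorter sequence matched identically in a global
    (free-end-gap) alignment — the denominator convention of short-sequence
    clustering tools."""
    if aligner is None:
        aligner = make_nucleotide_aligner()
    alignment = aligner.align(a.upper(), b.upper())[0]
    counts = alignment.counts()
    return counts.identities / min(len(a), len(b))


def cluster_isoforms(
    contigs: list[Contig], identity_threshold: float = DEFAULT_IDENTITY
) -> list[Cluster]:
    """Greedy incremental clustering of near-identical isoforms.

    Sequences are processed longest-first (ties by id); each joins the
    existing centroid of highest identity when that identity reaches the
    threshold, otherwise founds a new cluster.  Centroids are therefore the
    longest member of their cluster.  Output is sorted by member count
    descending (ties by centroid id).
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    aligner = make_nucleotide_aligner()
    ordered = sorted(contigs, key=lambda c: (-len(c.sequence), c.contig_id))
    clusters: list[Cluster] = []
    centroids: list[Contig] = []
    for contig in ordered:
        best_idx, best_ident = -1, -1.0
        for idx, centroid in enumerate(centroids):
            ident = pairwise_identity(contig.sequence, centroid.sequence, aligner)
            if ident > best_ident:
                best_idx, best_ident = idx, ident
        if best_idx >= 0 and best_ident >= identity_threshold:
            clusters[best_idx].members.append((contig.contig_id, best_ident))
        else:
            clusters.append(Cluster(contig.contig_id, [(contig.contig_id, 1.0)]))
            centroids.append(contig)
    clusters.sort(key=lambda c: (-len(c.members), c.centroid_id))
    return clusters
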