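"""Read-to-contig mapping and per-base coverage.

A native seed-and-verify mapper (exact-seed lookup, full-length mismatch
verification, no indels) adequate for transcriptome-scale curation of
short reads; SAM import/export via pysam interoperates with external
aligners on real data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .records import Contig, ReadSet, reverse_complement

DEFAULT_SEED_LENGTH = 20


@dataclass
class Placement:
    read_id: str
    contig_id: str
    start: int  # 0-based on the contig's forward strand
    end: int  # half-open
    strand: str  # "+" or "-"
    mismatches: int
    weight: float = 1.0  # fractional under multi-mapping ties


@dataclass
class AlignmentSet:
    placements: list[Placement] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)
    policy: str = "fractional"

    def by_contig(self) -> dict[str, list[Placement]]:
        out: dict[str, list[Placement]] = {}
        for p in self.placements:
            out.setdefault(p.contig_id, []).append(p)
        return out

    def counts(self) -> dict[str, float]:
        """Mapped-read mass per contig (fractional ties preserved)."""
        out: dict[str, float] = {}
        for p in self.placements:
            out[p.contig_id] = out.get(p.contig_id, 0.0) + p.weight
        return out


@dataclass
class CoverageProfile:
    contig_id: str
    depth: np.ndarray  # per-base placement count

    def breadth(self, min_depth: int = 1) -> float:
        """Fraction of bases covered at >= ``min_depth``."""
        if len(self.depth) == 0:
            return 0.0
        return float(np.mean(self.depth >= min_depth))


def _count_mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def build_seed_index(
    contigs: list[Contig], seed_length: int
) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ci, contig in enumerate(contigs):
        seq = contig.sequence.upper()
        for pos in range(len(seq) - seed_length + 1):
            index.setdefault(seq[pos : pos + seed_length], []).append((ci, pos))
    return index


def map_reads(
    reads: ReadSet,
    contigs: list[Contig],
    seed_length: int = DEFAULT_SEED_LENGTH,
    max_mismatches: int | None = None,
    policy: str = "fractional",
    index: dict[str, list[tuple[int, int]]] | None = None,
) -> AlignmentSet:
    """Place each read at its fewest-mismatch location over contigs/strands.

    Seeds are non-overlapping exact ``seed_length``-mers of the read; every
    seed hit proposes a full-length gapless placement which is verified by
    mismatch counting.  ``max_mismatches`` defaults to 5% of the read
    length.  Ties at the best mismatch count are shared fractionally
    (``policy="fractional"``) or given to the first contig in id order
    (``policy="primary"``).
    """
    if policy not in ("fractional", "primary"):
        raise ValueError(f"unknown multi-mapping policy {policy!r}")
    result = AlignmentSet(policy=policy)
    if not contigs:
        result.unmapped = [r.read_id for r in reads]
        return result
    if index is None:
        index = build_seed_index(contigs, seed_length)
    seqs = [c.sequence.upper() for c in contigs]
    for read in reads:
        rlen = len(read.sequence)
        if rlen < seed_length:
            result.unmapped.append(read.read_id)
            continue
        limit = max_mismatches if max_mismatches is not None else max(1, rlen // 20)
        offsets = list(range(0, rlen - seed_length + 1, seed_length))
        if offsets[-1] != rlen - seed_length:
            offsets.append(rlen - seed_length)
        best: dict[tuple[int, int, str], int] = {}
        best_mm = limit + 1
        fwd = read.sequence.upper()
        for strand, oriented in (("+", fwd), ("-", reverse_complement(fwd))):
            tried: set[tuple[int, int]] = set()
            for off in offsets:
                for ci, pos in index.get(oriented[off : off + seed_length], ()):
                    start = pos - off
                    if start < 0 or start + rlen > len(seqs[ci]):
                        continue
                    if (ci, start) in tried:
                        continue
                    tried.add((ci, start))
                    mm = _count_mismatches(
                        oriented, seqs[ci][start : start + rlen], limit
                    )
                    if mm <= limit:
                        best[(ci, start, strand)] = mm
                        best_mm = min(best_mm, mm)
        if not best:
            result.unmapped.append(read.read_id)
            continue
        ties = sorted(
            key for key, mm in best.items() if mm == best_mm
        )
        if policy == "primary":
            ties = ties[:1]
        weight = 1.0 / len(ties)
        for ci, start, strand in ties:
            result.placements.append(
                Placement(
                    read.read_id,
                    contigs[ci].contig_id,
                    start,
                    start + rlen,
                    strand,
                    best_mm,
                    weight,
                )
            )
    return result


def coverage_profile(aln: AlignmentSet, contig: Contig) -> CoverageProfile:
    """Per-base depth: the number of placements whose interval covers each
    base (multi-mapping weights are ignored; depth counts placements)."""
    n = len(contig.sequence)
    diff = np.zeros(n + 1, dtype=np.int64)
    for p in aln.placements:
        if p.contig_id != contig.contig_id:
            continue
        if not (0 <= p.start < p.end <= n):
            raise ValueError(
                f"placement {p.read_id} [{p.start},{p.end}) outside contig "
                f"{contig.contig_id} of length {n}"
            )
        diff[p.start] += 1
        diff[p.end] -= 1
    return CoverageProfile(contig.contig_id, np.cumsum(diff[:-1]))


def write_sam(aln: AlignmentSet, contigs: list[Contig], reads: ReadSet, path: str) -> None:
    """Export placements as SAM (gapless matches, NM tag for mismatches)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c.contig_id, "LN": len(c.sequence)} for c in contigs],
    }
    ref_ids = {c.contig_id: i for i, c in enumerate(contigs)}
    read_lookup = {r.read_id: r for r in reads}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for p in aln.placements:
            read = read_lookup[p.read_id]
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = p.read_id
            seq = read.sequence
            if p.strand == "-":
                seq = reverse_complement(seq)
                seg.flag = 16
            seg.query_sequence = seq
            seg.reference_id = ref_ids[p.contig_id]
            seg.reference_start = p.start
            seg.mapping_quality = 60
            seg.cigarstring = f"{p.end - p.start}M"
            seg.set_tag("NM", p.mismatches)
            out.write(seg)
        for rid in aln.unmapped:
            read = read_lookup[rid]
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rid
            seg.query_sequence = read.sequence
            seg.flag = 4
            out.write(seg)


def read_sam(path: str) -> AlignmentSet:
    """Import alignments (e.g. from an external aligner) as an AlignmentSet."""
    result = AlignmentSet(policy="imported")
    with pysam.AlignmentFile(path, "r") as fh:
        for seg in fh:
            if seg.is_unmapped:
                result.unmapped.append(seg.query_name)
                continue
            result.placements.append(
                Placement(
                    seg.query_name,
                    seg.reference_name,
                    seg.reference_start,
                    seg.reference_end,
                    "-" if seg.is_reverse else "+",
                    int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                )
            )
    return result
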