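"""Complete-ORF discovery and toxin-family annotation.

Venom transcriptome curation keeps only open reading frames that carry
both a start and a stop codon; incomplete fragments are discarded.  Each
complete ORF is then classified into a toxin family (3FTx, kunitz, PLA2,
...) by Smith-Waterman local alignment of its protein against a labelled
reference database, taking the family of the best hit that clears the
score and identity thresholds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .records import Contig, reverse_complement

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"

DEFAULT_MIN_CODONS = 50
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_MIN_SCORE = 60.0
DEFAULT_MIN_IDENTITY = 40.0
UNCLASSIFIED = "unclassified"


def translate(cds: str) -> str:
    """Standard-code translation; a terminal stop is dropped, internal
    stops render as ``*`` (marking the frame invalid for annotation)."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein


def has_internal_stop(cds: str) -> bool:
    return "*" in translate(cds)


@dataclass
class OrfRecord:
    """A complete ORF located on a contig.

    ``start``/``end`` are 0-based half-open coordinates on the contig's
    forward strand and include the stop codon; ``cds`` is read in the ORF's
    own orientation (begins with ATG, ends with a stop codon).
    """

    contig_id: str
    strand: str  # "+" or "-"
    frame: int  # 0, 1, 2 on the strand the ORF was read from
    start: int
    end: int
    cds: str
    protein: str
    complete: bool = True

    @property
    def orf_id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}({self.strand})"

    @property
    def n_codons(self) -> int:
        """Codons excluding the stop."""
        return len(self.cds) // 3 - 1

    def start_end_1based(self) -> tuple[int, int]:
        """Coordinates as 1-based inclusive (for reporting)."""
        return self.start + 1, self.end


@dataclass
class ReferenceProtein:
    ref_id: str
    family: str
    taxon: str
    sequence: str


@dataclass
class Hit:
    ref_id: str
    family: str
    taxon: str
    score: float
    identity: float  # percent of aligned columns that match


@dataclass
class ToxinAnnotation:
    orf: OrfRecord
    family: str
    best_hit: str | None
    score: float
    identity: float
    hits: list[Hit] = field(default_factory=list)


def find_orfs(
    contig: Contig,
    min_codons: int = DEFAULT_MIN_CODONS,
    longest_per_stop: bool = True,
) -> list[OrfRecord]:
    """All complete ORFs (ATG...stop, no internal stop) on six frames.

    Only ORFs with at least ``min_codons`` codons (stop excluded) are kept.
    Nested ORFs ending at the same stop report only the longest unless
    ``longest_per_stop`` is False.  Results are sorted by forward-strand
    coordinates.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    length = len(contig.sequence)
    out: list[OrfRecord] = []
    for strand in "+-":
        seq = contig.sequence.upper()
        if strand == "-":
            seq = reverse_complement(seq)
        for frame in range(3):
            open_starts: list[int] = []
            for pos in range(frame, len(seq) - 2, 3):
                codon = seq[pos : pos + 3]
                if codon == START_CODON:
                    open_starts.append(pos)
                elif codon in STOP_CODONS:
                    starts = open_starts[:1] if longest_per_stop else open_starts
                    for s in starts:
                        if (pos - s) // 3 < min_codons:
                            continue
                        cds = seq[s : pos + 3]
                        protein = translate(cds)
                        if strand == "+":
                            fwd_start, fwd_end = s, pos + 3
                        else:
                            fwd_start, fwd_end = length - (pos + 3), length - s
                        out.append(
                            OrfRecord(
                                contig.contig_id,
                                strand,
                                frame,
                                fwd_start,
                                fwd_end,
                                cds,
                                protein,
                            )
                        )
                    open_starts = []
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def read_reference_fasta(path: str) -> list[ReferenceProtein]:
    """Load a reference DB whose headers follow ``>refid|FAMILY|taxon``."""
    db = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"reference header {rec.id!r} is not 'refid|FAMILY|taxon'"
            )
        db.append(ReferenceProtein(parts[0], parts[1], parts[2], str(rec.seq)))
    return db


def write_reference_fasta(db: list[ReferenceProtein], path: str) -> None:
    with open(path, "w") as fh:
        for ref in db:
            fh.write(f">{ref.ref_id}|{ref.family}|{ref.taxon}\n{ref.sequence}\n")


def make_protein_aligner(
    gap_open: int = DEFAULT_GAP_OPEN, gap_extend: int = DEFAULT_GAP_EXTEND
) -> PairwiseAligner:
    """Local aligner with BLOSUM62 and affine gaps (open 11, extend 1):
    a gap of length L costs ``gap_open + gap_extend * L``."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _alignment_identity(alignment) -> float:
    counts = alignment.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / total if total else 0.0


def similarity_search(
    protein: str,
    db: list[ReferenceProtein],
    aligner: PairwiseAligner | None = None,
    min_score: float = 0.0,
) -> list[Hit]:
    """Smith-Waterman search of a query protein against the reference DB.

    Hits scoring at least ``min_score`` are returned sorted by descending
    score, ties broken by higher identity then reference id.
    """
    if not protein:
        raise ValueError("empty query protein")
    if aligner is None:
        aligner = make_protein_aligner()
    hits: list[Hit] = []
    for ref in db:
        alignments = aligner.align(protein, ref.sequence)
        score = alignments.score
        if score < min_score:
            continue
        hits.append(
            Hit(ref.ref_id, ref.family, ref.taxon, score, _alignment_identity(alignments[0]))
        )
    hits.sort(key=lambda h: (-h.score, -h.identity, h.ref_id))
    return hits


def classify_family(
    orf: OrfRecord,
    hits: list[Hit],
    min_score: float = DEFAULT_MIN_SCORE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> ToxinAnnotation:
    """Assign the family of the best hit clearing both thresholds."""
    for hit in hits:
        if hit.score >= min_score and hit.identity >= min_identity:
            return ToxinAnnotation(orf, hit.family, hit.ref_id, hit.score, hit.identity, hits)
    return ToxinAnnotation(orf, UNCLASSIFIED, None, 0.0, 0.0, hits)


def annotate_orfs(
    orfs: list[OrfRecord],
    db: list[ReferenceProtein],
    min_score: float = DEFAULT_MIN_SCORE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[ToxinAnnotation]:
    """Search and classify every ORF against the reference database."""
    aligner = make_protein_aligner()
    out = []
    for orf in orfs:
        if "*" in orf.protein or not orf.protein:
            out.append(ToxinAnnotation(orf, UNCLASSIFIED, None, 0.0, 0.0, []))
            continue
        hits = similarity_search(orf.protein, db, aligner)
        out.append(classify_family(orf, hits, min_score, min_identity))
    return out
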