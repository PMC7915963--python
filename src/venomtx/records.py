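"""Core sequence records shared across pipeline stages.

The pipeline moves three kinds of objects between stages: sequencing reads
(grouped per multiplexed sample), assembled contigs, and the sidecar
ground-truth labels that synthetic data carries for scoring.  Truth labels
live on the records themselves (``true_source``) but are written to separate
TSV sidecars on disk so that no pipeline stage can see them through the
sequence files it consumes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N, case kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """A single sequencing read.

    ``true_source`` is the hidden provenance label used only for scoring
    synthetic data: the generating species id, or ``contaminant:<species>``
    for reads spiked across samples.  Real reads leave it ``None``.
    """

    read_id: str
    sequence: str
    quality: str
    true_source: str | None = None
    #: (transcript_id, start, strand) of the generating window; scoring
    #: metadata for synthetic reads, never written to FASTQ
    source_span: tuple[str, int, str] | None = None

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    """Reads belonging to one multiplexed sample."""

    sample_id: str
    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


@dataclass
class MultiplexBatch:
    """Several samples sequenced in one lane, with cross-sample leakage."""

    read_sets: list[ReadSet]
    contamination_rate: float

    def __post_init__(self) -> None:
        ids = [rs.sample_id for rs in self.read_sets]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample ids in batch: {ids}")
        if not (0 <= self.contamination_rate < 1):
            raise ValueError("contamination_rate must be in [0, 1)")

    def sample(self, sample_id: str) -> ReadSet:
        for rs in self.read_sets:
            if rs.sample_id == sample_id:
                return rs
        raise KeyError(sample_id)


@dataclass
class Contig:
    """An assembled sequence (assembly itself happens upstream)."""

    contig_id: str
    sequence: str
    assembly_source: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(
                f"contig {self.contig_id}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)
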