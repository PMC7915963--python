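"""FASTA/FASTQ/TSV readers and writers.

Thin wrappers over Biopython's SeqIO so every stage reads and writes the
standard formats the field uses.  Ground-truth sidecars are plain TSV via
pandas.  All writers round-trip losslessly through the matching reader.
"""
from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import Contig, Read, ReadSet

PHRED_OFFSET = 33


def read_fastq(path: str, sample_id: str | None = None) -> ReadSet:
    """Load a FASTQ file (Phred+33) into a ReadSet.

    ``sample_id`` defaults to the file's basename without extension.
    """
    if sample_id is None:
        sample_id = os.path.basename(path)
        for ext in (".fastq", ".fq"):
            if sample_id.endswith(ext):
                sample_id = sample_id[: -len(ext)]
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        qual = "".join(
            chr(q + PHRED_OFFSET) for q in rec.letter_annotations["phred_quality"]
        )
        reads.append(Read(rec.id, str(rec.seq), qual))
    return ReadSet(sample_id, reads)


def write_fastq(read_set: ReadSet, path: str) -> None:
    with open(path, "w") as fh:
        for r in read_set:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fasta_contigs(path: str) -> list[Contig]:
    return [Contig(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str, width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as wrapped FASTA."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, path, "fasta")
    del width  # SeqIO wraps at its default 60; kept for signature stability


def write_contigs(contigs: Iterable[Contig], path: str) -> None:
    write_fasta(((c.contig_id, c.sequence) for c in contigs), path)


def write_truth_table(rows: list[dict], path: str) -> None:
    """Write a ground-truth sidecar (one row per record) as TSV."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_truth_sources(read_set: ReadSet, truth: pd.DataFrame) -> ReadSet:
    """Attach ``true_source`` labels from a sidecar to a loaded ReadSet."""
    lookup = dict(zip(truth["read_id"], truth["true_source"]))
    for r in read_set:
        r.true_source = lookup.get(r.read_id)
    return read_set
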