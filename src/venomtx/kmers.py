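"""Cross-sample contamination filtering with canonical k-mers.

Multiplexed libraries leak a small fraction of reads between samples
("index hopping").  A read that truly belongs to another sample is built
from k-mers that are rare in the focal sample but abundant in the other
one, so the filter (i) counts canonical k-mers per sample, (ii) flags
focal k-mers whose count in another sample is at least ``fold_threshold``
times the focal count, and (iii) removes focal reads in which flagged
k-mer occurrences cover at least ``coverage_fraction`` of the bases.
A separate minimum-length rule removes short reads.

K-mers are strand-folded: each window is stored as the lexicographic
minimum of itself and its reverse complement, packed into a 2-bit-per-base
integer (A<C<G<T orders identically as characters and as 2-bit codes, so
integer min equals string min).  Windows containing non-ACGT characters
are skipped.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

from .records import Read, ReadSet

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"

DEFAULT_K = 57
DEFAULT_FOLD = 1000.0
DEFAULT_COVERAGE_FRACTION = 0.25
DEFAULT_MIN_LENGTH = 75


def encode_kmer(kmer: str) -> int:
    value = 0
    for ch in kmer:
        value = (value << 2) | _CODE[ch]
    return value


def decode_kmer(value: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[value & 3])
        value >>= 2
    return "".join(reversed(out))


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = kmer.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    return kmer if kmer <= rc else rc


def iter_canonical(seq: str, k: int) -> Iterator[tuple[int, int]]:
    """Yield ``(position, packed canonical k-mer)`` for each valid window.

    Rolling 2-bit encoding; a non-ACGT character resets the window so no
    window containing it is emitted.
    """
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = rc = 0
    run = 0
    code = _CODE
    for i, ch in enumerate(seq):
        c = code.get(ch)
        if c is None:
            run = 0
            fwd = rc = 0
            continue
        fwd = ((fwd << 2) | c) & mask
        rc = (rc >> 2) | ((3 - c) << shift)
        run += 1
        if run >= k:
            yield i - k + 1, fwd if fwd <= rc else rc


@dataclass
class KmerSpectrum:
    """Per-sample canonical k-mer counts (keys packed as integers)."""

    sample_id: str
    k: int
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_strings(self) -> dict[str, int]:
        """Counts keyed by the k-mer string (for display/dumps/tests)."""
        return {decode_kmer(v, self.k): c for v, c in self.counts.items()}

    def to_tsv(self, path: str) -> None:
        rows = sorted(self.as_strings().items())
        pd.DataFrame(rows, columns=["kmer", "count"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class FlaggedKmerSet:
    """Focal k-mers over-represented in another sample of the same lane."""

    focal_sample: str
    other_sample: str
    fold_threshold: float
    k: int
    kmers: set[int] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.kmers)


@dataclass
class FilterReport:
    """Per-read decisions plus summary counts for one focal sample."""

    sample_id: str
    decisions: list[tuple[str, float, bool, str]]  # read_id, frac, kept, reason

    @property
    def n_input(self) -> int:
        return len(self.decisions)

    @property
    def n_kept(self) -> int:
        return sum(1 for d in self.decisions if d[2])

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept

    def removed_by_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, _, kept, reason in self.decisions:
            if not kept:
                out[reason] = out.get(reason, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.decisions,
            columns=["read_id", "flagged_fraction", "kept", "reason"],
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def count_kmers(reads: ReadSet, k: int) -> KmerSpectrum:
    """Count every length-``k`` window of every read in canonical form."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[int, int] = {}
    get = counts.get
    for read in reads:
        for _, kmer in iter_canonical(read.sequence.upper(), k):
            counts[kmer] = get(kmer, 0) + 1
    return KmerSpectrum(reads.sample_id, k, counts)


def flag_kmers(
    focal: KmerSpectrum,
    other: KmerSpectrum,
    fold_threshold: float = DEFAULT_FOLD,
    normalize: bool = False,
) -> FlaggedKmerSet:
    """Flag focal k-mers present in ``other`` at >= ``fold_threshold`` level.

    Only k-mers that occur in the focal spectrum can be flagged (absent
    k-mers cannot mark any focal read).  With ``normalize=True`` the other
    sample's counts are rescaled by the ratio of spectrum totals, which
    compensates unequal library depths; the raw-count ratio is the default.
    """
    if focal.k != other.k:
        raise ValueError(f"k mismatch: focal {focal.k} vs other {other.k}")
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    scale = 1.0
    if normalize and other.total > 0:
        scale = focal.total / other.total
    other_counts = other.counts
    flagged = {
        kmer
        for kmer, fc in focal.counts.items()
        if (oc := other_counts.get(kmer)) is not None
        and oc * scale / fc >= fold_threshold
    }
    return FlaggedKmerSet(focal.sample_id, other.sample_id, fold_threshold, focal.k, flagged)


def filter_reads(
    reads: ReadSet,
    flagged: list[FlaggedKmerSet],
    coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[ReadSet, FilterReport]:
    """Remove likely-contaminant and too-short reads from the focal sample.

    A read is removed as contamination when the union (over all flagged
    sets) of base positions covered by flagged k-mer occurrences amounts to
    at least ``coverage_fraction`` of its length; independently, reads
    shorter than ``min_length`` are removed.  Decisions are independent of
    read order.
    """
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in (0, 1]")
    ks = {fs.k for fs in flagged}
    if len(ks) > 1:
        raise ValueError(f"flagged sets disagree on k: {sorted(ks)}")
    focals = {fs.focal_sample for fs in flagged}
    if focals and focals != {reads.sample_id}:
        raise ValueError(
            f"flagged sets are for {sorted(focals)}, not focal sample {reads.sample_id}"
        )
    k = ks.pop() if ks else 0
    union: set[int] = set()
    for fs in flagged:
        union |= fs.kmers

    kept_reads: list[Read] = []
    decisions: list[tuple[str, float, bool, str]] = []
    for read in reads:
        n = len(read.sequence)
        frac = 0.0
        if union and n >= k:
            covered = bytearray(n)
            for pos, kmer in iter_canonical(read.sequence.upper(), k):
                if kmer in union:
                    covered[pos : pos + k] = b"\x01" * k
            frac = sum(covered) / n
        if frac >= coverage_fraction:
            decisions.append((read.read_id, frac, False, "contamination"))
        elif n < min_length:
            decisions.append((read.read_id, frac, False, "too_short"))
        else:
            decisions.append((read.read_id, frac, True, "kept"))
            kept_reads.append(read)
    return ReadSet(reads.sample_id, kept_reads), FilterReport(reads.sample_id, decisions)


def filter_sample(
    focal_reads: ReadSet,
    other_reads: list[ReadSet],
    k: int = DEFAULT_K,
    fold_threshold: float = DEFAULT_FOLD,
    coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
    min_length: int = DEFAULT_MIN_LENGTH,
    mode: str = "pairwise",
    normalize: bool = False,
    focal_spectrum: KmerSpectrum | None = None,
    other_spectra: list[KmerSpectrum] | None = None,
) -> tuple[ReadSet, FilterReport]:
    """End-to-end contamination + length filter for one focal sample.

    ``mode="pairwise"`` flags against each other sample separately and
    removes on the union of flagged positions; ``mode="pooled"`` first sums
    the other samples' spectra into a single rest-of-lane spectrum.
    Precomputed spectra may be passed to avoid recounting.
    """
    if mode not in ("pairwise", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    focal = focal_spectrum or count_kmers(focal_reads, k)
    others = other_spectra or [count_kmers(rs, k) for rs in other_reads]
    if mode == "pooled" and len(others) > 1:
        pooled: dict[int, int] = {}
        for sp in others:
            for kmer, c in sp.counts.items():
                pooled[kmer] = pooled.get(kmer, 0) + c
        others = [KmerSpectrum("pooled", k, pooled)]
    flagged = [flag_kmers(focal, sp, fold_threshold, normalize=normalize) for sp in others]
    return filter_reads(focal_reads, flagged, coverage_fraction, min_length)
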