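"""Counting-method dN/dS (Nei-Gojobori 1986) on mature-protein codon data.

Toxin genes under diversifying selection show an excess of nonsynonymous
over synonymous substitutions (omega = dN/dS > 1).  This module trims
precursor coding sequences to the mature peptide, and estimates dN and dS
by the classic counting method: synonymous/nonsynonymous site counts per
codon (mutations creating stop codons count as nonsynonymous sites, so
sites sum to exactly 3 per codon), difference counts averaged over all
minimal mutational pathways with stop-traversing pathways excluded, and a
Jukes-Cantor multiple-hit correction d = -3/4 ln(1 - 4p/3).  Clade-level
estimates pool site and difference counts over all pairs before the
correction.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

GAP = "-"
_STOPS = set(standard_dna_table.stop_codons)
_CODON_TABLE = dict(standard_dna_table.forward_table)
SENSE_CODONS = sorted(_CODON_TABLE)  # 61 codons
_BASES = "ACGT"


def aa_of(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop codon."""
    return _CODON_TABLE.get(codon)


@dataclass
class CodonAlignment:
    """An aligned set of coding sequences, gapped in whole-codon units."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"rows differ in length: {sorted(lengths)}")
        if lengths and lengths.pop() % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        for name, seq in zip(self.taxa, self.sequences):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if GAP in codon:
                    if codon != GAP * 3:
                        raise ValueError(
                            f"{name}: partial-codon gap at position {i}"
                        )
                elif codon in _STOPS and i < len(seq) - 3:
                    raise ValueError(f"{name}: internal stop codon at {i}")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    def codons(self, row: int) -> list[str]:
        seq = self.sequences[row]
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]


@dataclass
class DnDsEstimate:
    """NG86 site/difference counts and corrected distances for a comparison."""

    N_sites: float
    S_sites: float
    N_diff: float
    S_diff: float
    n_codons: int
    pN: float = field(init=False)
    pS: float = field(init=False)
    dN: float = field(init=False)
    dS: float = field(init=False)
    omega: float = field(init=False)
    status: str = field(init=False)

    def __post_init__(self) -> None:
        self.pN = self.N_diff / self.N_sites if self.N_sites > 0 else 0.0
        self.pS = self.S_diff / self.S_sites if self.S_sites > 0 else 0.0
        self.status = "ok"
        self.dN = _jukes_cantor(self.pN)
        self.dS = _jukes_cantor(self.pS)
        if math.isnan(self.dN) or math.isnan(self.dS):
            self.status = "saturated"
        if self.pN == 0.0 and self.S_diff > 0:
            # no nonsynonymous change observed: the ratio is 0 even when
            # the synonymous correction saturates
            self.omega = 0.0
        elif self.status == "saturated":
            self.omega = math.nan
        elif self.dS == 0.0:
            self.status = "undefined_dS_zero"
            self.omega = math.nan
        else:
            self.omega = self.dN / self.dS


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes to stop codons are nonsynonymous, so the
    two counts always sum to exactly 3.
    """
    if codon in _STOPS or len(codon) != 3:
        raise ValueError(f"not a sense codon: {codon!r}")
    syn = 0.0
    aa = _CODON_TABLE[codon]
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TABLE.get(mutant) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Averaged with equal weight over all minimal mutational pathways that do
    not pass through a stop codon; if every pathway is blocked by a stop,
    all pathways are used (degenerate case, documented).
    """
    for c in (c1, c2):
        if c in _STOPS or len(c) != 3:
            raise ValueError(f"not a sense codon: {c!r}")
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(positions):
        current = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            steps.append((current, nxt))
            current = nxt
        pathways.append((blocked, steps))
    usable = [steps for blocked, steps in pathways if not blocked]
    if not usable:
        usable = [steps for _, steps in pathways]
    syn = nonsyn = 0.0
    for steps in usable:
        for before, after in steps:
            if _CODON_TABLE.get(before) == _CODON_TABLE.get(after) and (
                before not in _STOPS and after not in _STOPS
            ):
                syn += 1.0
            else:
                nonsyn += 1.0
    n = len(usable)
    return syn / n, nonsyn / n


def _usable_codon(codon: str) -> bool:
    return codon in _CODON_TABLE


def ng86_counts(a: str, b: str) -> tuple[float, float, float, float, int]:
    """Pooled (N_sites, S_sites, N_diff, S_diff, codons_compared) for a pair.

    Codon columns where either sequence is gapped, contains an ambiguous
    base, or is a stop codon are skipped (pairwise deletion).
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3 != 0:
        raise ValueError("length not divisible by 3")
    S_sites = N_sites = S_diff = N_diff = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if not (_usable_codon(ca) and _usable_codon(cb)):
            continue
        n_codons += 1
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S_sites += (sa + sb) / 2.0
        N_sites += (na + nb) / 2.0
        sd, nd = codon_differences(ca, cb)
        S_diff += sd
        N_diff += nd
    return N_sites, S_sites, N_diff, S_diff, n_codons


def ng86_pairwise(a: str, b: str) -> DnDsEstimate:
    """NG86 dN/dS estimate for one pair of equal-length coding sequences."""
    N_sites, S_sites, N_diff, S_diff, n_codons = ng86_counts(a, b)
    return DnDsEstimate(N_sites, S_sites, N_diff, S_diff, n_codons)


@dataclass
class CladeOmega:
    pooled: DnDsEstimate
    pairs: pd.DataFrame  # per-pair table of counts and estimates


def clade_omega(aln: CodonAlignment) -> CladeOmega:
    """Overall dN/dS of a clade alignment.

    Site and difference counts are pooled over all unordered pairs before
    the Jukes-Cantor correction, so highly similar pairs do not dominate
    through their individually noisy ratios.
    """
    if len(aln.taxa) < 2:
        raise ValueError("clade_omega needs at least 2 taxa")
    rows = []
    tot = [0.0, 0.0, 0.0, 0.0]
    n_codons_total = 0
    for (i, ti), (j, tj) in itertools.combinations(enumerate(aln.taxa), 2):
        N_sites, S_sites, N_diff, S_diff, n_codons = ng86_counts(
            aln.sequences[i], aln.sequences[j]
        )
        est = DnDsEstimate(N_sites, S_sites, N_diff, S_diff, n_codons)
        rows.append(
            {
                "taxon_a": ti,
                "taxon_b": tj,
                "N_sites": N_sites,
                "S_sites": S_sites,
                "N_diff": N_diff,
                "S_diff": S_diff,
                "dN": est.dN,
                "dS": est.dS,
                "omega": est.omega,
                "status": est.status,
            }
        )
        tot[0] += N_sites
        tot[1] += S_sites
        tot[2] += N_diff
        tot[3] += S_diff
        n_codons_total += n_codons
    pooled = DnDsEstimate(tot[0], tot[1], tot[2], tot[3], n_codons_total)
    return CladeOmega(pooled, pd.DataFrame(rows))


def trim_to_mature(cds: str, signal_codons: int) -> str:
    """Drop the signal-peptide codons and the terminal stop codon.

    ``signal_codons`` comes from annotation metadata (signal-peptide
    prediction is out of scope); the result is the mature-protein CDS the
    selection analysis runs on.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if signal_codons < 0:
        raise ValueError("signal_codons must be >= 0")
    n_codons = len(cds) // 3
    if signal_codons >= n_codons:
        raise ValueError("signal peptide spans the whole CDS")
    trimmed = cds[3 * signal_codons :]
    if trimmed[-3:].upper() in _STOPS:
        trimmed = trimmed[:-3]
    if not trimmed:
        raise ValueError("trimming left no codons")
    return trimmed
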