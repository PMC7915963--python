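"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by the most direct method available
(full enumeration, naive dynamic programming) and deliberately shares no
code with the package's optimized paths.
"""
from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def brute_force_kmer_counts(sequences: list[str], k: int) -> dict[str, int]:
    """Enumerate every window of every sequence; canonicalize by string min."""
    counts: dict[str, int] = {}
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if set(window) - set("ACGT"):
                continue
            canon = min(window, revcomp(window))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def brute_force_orfs(sequence: str, min_codons: int) -> set[tuple[int, int, str]]:
    """Six-frame scan for complete ORFs, longest per stop codon.

    Returns forward-strand (start, end, strand) triples, end including the
    stop codon.
    """
    stops = {"TAA", "TAG", "TGA"}
    found: set[tuple[int, int, str]] = set()
    n = len(sequence)
    for strand in "+-":
        seq = sequence.upper() if strand == "+" else revcomp(sequence.upper())
        for frame in range(3):
            # for each stop, find the first ATG after the previous stop
            prev_stop_end = frame
            pos = frame
            while pos + 3 <= len(seq):
                codon = seq[pos : pos + 3]
                if codon in stops:
                    for atg in range(prev_stop_end, pos, 3):
                        if seq[atg : atg + 3] == "ATG":
                            if (pos - atg) // 3 >= min_codons:
                                if strand == "+":
                                    found.add((atg, pos + 3, "+"))
                                else:
                                    found.add((n - (pos + 3), n - atg, "-"))
                            break
                    prev_stop_end = pos + 3
                pos += 3
    return found


def smith_waterman_score(
    a: str, b: str, gap_open: int = 11, gap_extend: int = 1
) -> float:
    """Affine-gap local alignment score (Gotoh), BLOSUM62.

    A gap of length L costs gap_open + gap_extend * L.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend
            )
            F[i][j] = max(
                H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend
            )
            diag = H[i - 1][j - 1] + blosum[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def interval_stabbing_depth(intervals: list[tuple[int, int]], length: int) -> list[int]:
    """depth[i] = number of [start, end) intervals containing i."""
    return [sum(1 for s, e in intervals if s <= i < e) for i in range(length)]


def ng86_oracle(a: str, b: str) -> dict[str, float]:
    """Pathway-enumerating NG86 estimate, written independently.

    Synonymy decided by Biopython translation; sites per codon count
    mutations to stop codons as nonsynonymous; multi-hit codons average
    over all stop-free orderings (all orderings if every one is blocked).
    """
    stops = {"TAA", "TAG", "TGA"}

    def tr(codon):
        return None if codon in stops else str(Seq(codon).translate())

    def sites(codon):
        syn = 0.0
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1 :]
                if tr(mutant) is not None and tr(mutant) == tr(codon):
                    syn += 1 / 3
        return syn, 3 - syn

    S_sites = N_sites = S_diff = N_diff = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca in stops or cb in stops or set(ca + cb) - set("ACGT"):
            continue
        n_codons += 1
        for c in (ca, cb):
            s, ns = sites(c)
            S_sites += s / 2
            N_sites += ns / 2
        diffs = [p for p in range(3) if ca[p] != cb[p]]
        if not diffs:
            continue
        paths = []
        for order in itertools.permutations(diffs):
            cur, steps, blocked = ca, [], False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1 :]
                if nxt in stops:
                    blocked = True
                steps.append((cur, nxt))
                cur = nxt
            paths.append((blocked, steps))
        usable = [s for bl, s in paths if not bl] or [s for _, s in paths]
        sd = nd = 0.0
        for steps in usable:
            for c1, c2 in steps:
                if tr(c1) is not None and tr(c2) is not None and tr(c1) == tr(c2):
                    sd += 1
                else:
                    nd += 1
        S_diff += sd / len(usable)
        N_diff += nd / len(usable)

    def jc(p):
        return math.nan if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    pN = N_diff / N_sites if N_sites else 0.0
    pS = S_diff / S_sites if S_sites else 0.0
    return {
        "N_sites": N_sites,
        "S_sites": S_sites,
        "N_diff": N_diff,
        "S_diff": S_diff,
        "pN": pN,
        "pS": pS,
        "dN": jc(pN),
        "dS": jc(pS),
        "n_codons": n_codons,
    }


def longest_leaf_path(tree) -> tuple[float, set[str]]:
    """Brute-force maximum patristic distance and the pair(s) achieving it."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    best, pairs = -1.0, set()
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            d = pdm.patristic_distance(t1, t2)
            if d > best + 1e-12:
                best, pairs = d, {(t1.label, t2.label)}
            elif abs(d - best) <= 1e-12:
                pairs.add((t1.label, t2.label))
    return best, {lbl for pair in pairs for lbl in pair}
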