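"""Synthetic multiplexed venom-gland libraries with known ground truth.

The generator emulates the study design the curation pipeline targets:
several species' venom-gland transcriptomes multiplexed in one sequencing
lane.  Each species gets a repertoire of toxin transcripts whose families
follow a configurable profile (a few families — 3FTx, kunitz, PLA2 —
dominate expression), with log-normal expression skew, uniform-substitution
sequencing error, low-rate cross-sample read contamination, optional
planted chimeric contigs, and codon sequences evolved under a known
dN/dS ratio for selection-analysis recovery tests.

Every generated object carries provenance labels (``true_source``,
per-transcript family/weight, chimera breakpoints) which are exported as
TSV sidecars, never embedded in the sequence data the pipeline consumes.
All functions are deterministic for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .orfs import ReferenceProtein, translate
from .records import Contig, MultiplexBatch, Read, ReadSet, reverse_complement
from .selection import SENSE_CODONS, CodonAlignment, aa_of

_BASES = np.array(list("ACGT"))
_AA = "ACDEFGHIKLMNPQRSTVWY"
_PHRED40 = "I"  # constant high quality; quality trimming is out of scope

# codons per amino acid, for back-translation
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    _CODONS_BY_AA.setdefault(aa_of(_codon), []).append(_codon)

DEFAULT_FAMILY_PROFILE = {
    # three dominant families (>1% of expression) plus a tail of minor
    # families each well below 1%, mirroring a typical elapid venom gland
    "3FTx": 0.60,
    "kunitz": 0.25,
    "PLA2": 0.10,
    "CRiSP": 0.009,
    "SVMP": 0.009,
    "vespryn": 0.008,
    "cystatin": 0.008,
    "hyaluronidase": 0.008,
    "natriuretic": 0.008,
}


@dataclass
class Transcript:
    transcript_id: str
    sequence: str
    family: str
    weight: float
    orf_start: int  # 0-based position of the designed ATG
    orf_end: int  # half-open end of the designed ORF incl. stop codon

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptSet:
    species_id: str
    transcripts: list[Transcript]
    family_proteins: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript ids")
        if self.transcripts and sum(t.weight for t in self.transcripts) <= 0:
            raise ValueError("expression weights must sum to > 0")

    def __len__(self) -> int:
        return len(self.transcripts)

    def truth_rows(self) -> list[dict]:
        return [
            {
                "transcript_id": t.transcript_id,
                "species": self.species_id,
                "family": t.family,
                "weight": t.weight,
                "orf_start": t.orf_start,
                "orf_end": t.orf_end,
            }
            for t in self.transcripts
        ]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate_protein(rng: np.random.Generator, protein: str, divergence: float) -> str:
    out = list(protein)
    for i in range(1, len(out)):  # keep the initiator Met
        if rng.random() < divergence:
            choices = [a for a in _AA if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in protein
    )


def generate_transcriptome(
    n_transcripts: int,
    family_profile: dict[str, float] | None = None,
    mean_length: int = 500,
    seed: int = 0,
    species_id: str = "sp",
    expression_sigma: float = 1.5,
    family_divergence: float = 0.08,
) -> TranscriptSet:
    """Generate a species' toxin transcript repertoire.

    Families are drawn per transcript from ``family_profile``; each family
    has a random ancestral protein from which members diverge by
    ``family_divergence`` amino-acid substitutions, so family membership is
    recoverable by similarity search.  Within a family, log-normal
    per-transcript weights (sigma ``expression_sigma``) are rescaled so the
    family's total expression share equals its profile weight.  Every
    transcript embeds exactly one designed complete ORF (ATG ... stop, no
    premature in-frame stop) flanked by untranslated ends.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    profile = dict(
        DEFAULT_FAMILY_PROFILE if family_profile is None else family_profile
    )
    if not profile:
        raise ValueError("family_profile must not be empty")
    if any(w < 0 for w in profile.values()) or sum(profile.values()) <= 0:
        raise ValueError("family weights must be nonnegative and not all zero")
    rng = np.random.default_rng(seed)
    families = sorted(profile)
    probs = np.array([profile[f] for f in families], dtype=float)
    probs /= probs.sum()
    fam_idx = rng.choice(len(families), size=n_transcripts, p=probs)

    # ancestral protein per family; length tied to the requested mean
    # transcript length (UTRs + in-frame leader stop + start/stop ~ 120 nt)
    orf_codons = max(60, round((mean_length - 120) / 3))
    ancestors = {
        f: "M" + "".join(rng.choice(list(_AA), size=orf_codons - 1))
        for f in families
    }

    raw_weights = rng.lognormal(mean=0.0, sigma=expression_sigma, size=n_transcripts)
    transcripts: list[Transcript] = []
    stop_codons = ("TAA", "TAG", "TGA")
    for i in range(n_transcripts):
        fam = families[fam_idx[i]]
        protein = _mutate_protein(rng, ancestors[fam], family_divergence)
        cds = _back_translate(rng, protein) + stop_codons[rng.integers(3)]
        utr5 = _random_seq(rng, int(rng.integers(30, 91)))
        utr3 = _random_seq(rng, int(rng.integers(30, 91)))
        # in-frame leader stop prevents the designed ORF from extending
        # upstream through an incidental UTR start codon
        seq = utr5 + "TAA" + cds + utr3
        orf_start = len(utr5) + 3
        transcripts.append(
            Transcript(
                f"{species_id}_t{i:04d}",
                seq,
                fam,
                float(raw_weights[i]),
                orf_start,
                orf_start + len(cds),
            )
        )
    # rescale so each family's total weight equals its profile share
    for j, fam in enumerate(families):
        members = [t for t in transcripts if t.family == fam]
        total = sum(t.weight for t in members)
        if total > 0:
            for t in members:
                t.weight *= probs[j] / total
    return TranscriptSet(species_id, transcripts, ancestors)


def reference_database(transcript_sets: list[TranscriptSet]) -> list[ReferenceProtein]:
    """Family ancestor proteins of each species as a labelled reference DB."""
    db = []
    for ts in transcript_sets:
        for family, protein in sorted(ts.family_proteins.items()):
            db.append(
                ReferenceProtein(
                    f"{ts.species_id}_{family}_ref", family, ts.species_id, protein
                )
            )
    return db


def simulate_reads(
    ts: TranscriptSet,
    n_reads: int,
    read_length: int = 150,
    error_rate: float = 0.01,
    seed: int = 0,
) -> ReadSet:
    """Draw error-bearing reads from a transcript set.

    Transcripts are sampled proportionally to expression weight times
    transcript length (longer transcripts shed more fragments); start
    positions are uniform, strand is uniform, and each base substitutes
    uniformly to another base with probability ``error_rate``.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    eligible = [t for t in ts.transcripts if len(t) >= read_length]
    if n_reads > 0 and not eligible:
        raise ValueError(
            f"read_length {read_length} exceeds every transcript length"
        )
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    if n_reads == 0:
        return ReadSet(ts.species_id, reads)
    weights = np.array([t.weight * len(t) for t in eligible], dtype=float)
    weights /= weights.sum()
    choices = rng.choice(len(eligible), size=n_reads, p=weights)
    quality = _PHRED40 * read_length
    for i in range(n_reads):
        t = eligible[choices[i]]
        start = int(rng.integers(0, len(t) - read_length + 1))
        seq = t.sequence[start : start + read_length]
        strand = "+"
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
            strand = "-"
        n_err = rng.binomial(read_length, error_rate)
        if n_err:
            seq_list = list(seq)
            positions = rng.choice(read_length, size=n_err, replace=False)
            for pos in positions:
                alt = [b for b in "ACGT" if b != seq_list[pos]]
                seq_list[pos] = alt[rng.integers(3)]
            seq = "".join(seq_list)
        reads.append(
            Read(
                f"{ts.species_id}_r{i:06d}",
                seq,
                quality,
                ts.species_id,
                source_span=(t.transcript_id, start, strand),
            )
        )
    return ReadSet(ts.species_id, reads)


def spike_contamination(
    read_sets: list[ReadSet], rate: float, seed: int = 0
) -> MultiplexBatch:
    """Copy reads across samples so each sample's expected contaminant
    fraction is ``rate``.

    Contaminants are verbatim copies of reads drawn uniformly from the
    other samples, relabelled ``contaminant:<origin species>``; the genuine
    reads of every sample are left untouched.
    """
    if len(read_sets) < 2:
        raise ValueError("contamination needs at least 2 samples")
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out_sets: list[ReadSet] = []
    for focal in read_sets:
        donors = [
            (rs.sample_id, r) for rs in read_sets if rs is not focal for r in rs.reads
        ]
        new_reads = list(focal.reads)
        if rate > 0 and donors:
            # adding c contaminants to n genuine reads gives fraction
            # c/(n+c); Binomial(n, rate/(1-rate)) has the right expectation
            n_cont = rng.binomial(len(focal.reads), rate / (1.0 - rate))
            picks = rng.integers(0, len(donors), size=n_cont)
            for j, pick in enumerate(picks):
                origin_sample, src = donors[pick]
                origin = src.true_source or origin_sample
                new_reads.append(
                    Read(
                        f"{focal.sample_id}_c{j:06d}",
                        src.sequence,
                        src.quality,
                        f"contaminant:{origin}",
                    )
                )
        out_sets.append(ReadSet(focal.sample_id, new_reads))
    return MultiplexBatch(out_sets, rate)


def batch_truth_rows(batch: MultiplexBatch) -> list[dict]:
    """Read-provenance sidecar rows (read_id -> true_source) for a batch."""
    return [
        {"read_id": r.read_id, "sample": rs.sample_id, "true_source": r.true_source}
        for rs in batch.read_sets
        for r in rs
    ]


@dataclass
class PlantedChimera:
    """A deliberately mis-joined contig with its scoring metadata."""

    contig: Contig
    breakpoint: int
    parent_a: str
    parent_b: str
    suffix_start: int


def make_chimera(
    a: Contig, b: Contig, breakpoint: int, suffix_start: int | None = None
) -> PlantedChimera:
    """Join a prefix of ``a`` with a suffix of ``b`` at ``breakpoint``.

    ``suffix_start`` defaults to ``breakpoint`` (a positionally honest
    mis-join); the true breakpoint is recorded for detector scoring.
    """
    if not 0 < breakpoint <= len(a.sequence):
        raise ValueError(
            f"breakpoint {breakpoint} out of range (0, {len(a.sequence)}]"
        )
    if suffix_start is None:
        suffix_start = min(breakpoint, len(b.sequence))
    if not 0 <= suffix_start <= len(b.sequence):
        raise ValueError(f"suffix_start {suffix_start} out of range")
    seq = a.sequence[:breakpoint] + b.sequence[suffix_start:]
    contig = Contig(f"chimera_{a.contig_id}_{b.contig_id}", seq)
    return PlantedChimera(contig, breakpoint, a.contig_id, b.contig_id, suffix_start)


def random_cds(n_codons: int, seed: int = 0) -> str:
    """A random stop-free coding sequence of ``n_codons`` codons."""
    rng = np.random.default_rng(seed)
    return "".join(
        SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)
    )


def _is_transition(b1: str, b2: str) -> bool:
    return {b1, b2} in ({"A", "G"}, {"C", "T"})


def codon_rate_matrix(omega: float, kappa: float) -> np.ndarray:
    """61x61 codon substitution rate matrix (MG94-flavoured HKY kernel).

    Single-nucleotide changes only; transitions are scaled by ``kappa`` and
    nonsynonymous changes by ``omega``; stop codons are unreachable.  The
    matrix is scaled so one unit of branch length equals one expected
    substitution per codon site at the uniform codon distribution.
    """
    if omega <= 0 or kappa <= 0:
        raise ValueError("omega and kappa must be positive")
    n = len(SENSE_CODONS)
    index = {c: i for i, c in enumerate(SENSE_CODONS)}
    Q = np.zeros((n, n))
    for i, c1 in enumerate(SENSE_CODONS):
        for pos in range(3):
            for base in "ACGT":
                if base == c1[pos]:
                    continue
                c2 = c1[:pos] + base + c1[pos + 1 :]
                j = index.get(c2)
                if j is None:  # stop codon
                    continue
                rate = kappa if _is_transition(c1[pos], base) else 1.0
                if aa_of(c1) != aa_of(c2):
                    rate *= omega
                Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.mean(np.diag(Q))
    return Q / mean_rate


def evolve_codon_clade(
    ancestor_cds: str,
    n_taxa: int,
    branch_length: float,
    omega: float,
    kappa: float = 2.0,
    seed: int = 0,
    tree=None,
) -> CodonAlignment:
    """Evolve descendant coding sequences under a known dN/dS ratio.

    By default the ``n_taxa`` descendants radiate from the ancestor on a
    star tree with equal ``branch_length`` (expected substitutions per
    codon site); passing a tree evolves along its topology and branch
    lengths instead.  Codon states follow a continuous-time Markov process
    whose transition matrix is the exponential of the scaled rate matrix.
    """
    if len(ancestor_cds) % 3 != 0:
        raise ValueError("ancestor length must be divisible by 3")
    anc_codons = [ancestor_cds[i : i + 3] for i in range(0, len(ancestor_cds), 3)]
    index = {c: i for i, c in enumerate(SENSE_CODONS)}
    try:
        anc_idx = np.array([index[c] for c in anc_codons])
    except KeyError as exc:
        raise ValueError(f"ancestor contains a stop or invalid codon: {exc}") from exc
    rng = np.random.default_rng(seed)
    Q = codon_rate_matrix(omega, kappa)

    def evolve_along(state: np.ndarray, length: float) -> np.ndarray:
        if length <= 0:
            return state.copy()
        P = expm(Q * length)
        cum = np.cumsum(P, axis=1)
        u = rng.random(len(state))
        rows = cum[state]
        idx = (rows < u[:, None]).sum(axis=1)
        return np.minimum(idx, len(SENSE_CODONS) - 1)

    taxa: list[str] = []
    seqs: list[str] = []
    if tree is None:
        if n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        for t in range(n_taxa):
            idx = evolve_along(anc_idx, branch_length)
            taxa.append(f"t{t}")
            seqs.append("".join(SENSE_CODONS[i] for i in idx))
    else:
        states = {id(tree.seed_node): anc_idx}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent_state = states[id(node.parent_node)]
            states[id(node)] = evolve_along(parent_state, node.edge.length or 0.0)
            if node.is_leaf():
                taxa.append(node.taxon.label)
                seqs.append("".join(SENSE_CODONS[i] for i in states[id(node)]))
    return CodonAlignment(taxa, seqs)
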