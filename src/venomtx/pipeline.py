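"""End-to-end curation pipeline: filter, annotate, screen, assign, cluster,
quantify — from a single configuration, with a machine-readable report.

Assembly is an explicit external hand-off: the pipeline consumes contigs
(from de novo assemblers on real data, or from the synthetic generator's
truth transcripts in tests) and never builds them itself.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import yaml

from . import io as vio
from .curation import (
    AMBIGUOUS,
    ChimeraCall,
    assign_species,
    cluster_isoforms,
    detect_chimera,
)
from .expression import compute_tpm, summarize_families
from .kmers import count_kmers, filter_sample
from .mapping import build_seed_index, coverage_profile, map_reads
from .orfs import (
    UNCLASSIFIED,
    annotate_orfs,
    find_orfs,
    read_reference_fasta,
)
from .records import Contig, ReadSet


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults, plus input/output paths.

    Defaults are the curation settings the pipeline is built around:
    57-mers at a 1000-fold cross-sample ratio, 25% read coverage, 75 bp
    minimum read length, 50-codon minimum ORFs, 99% isoform identity,
    5-fold expression ratio for species assignment, 10-fold coverage step
    over 25 nt windows for the chimera screen, and a 1% family-share
    reporting threshold.
    """

    sample_fastqs: dict[str, str] = field(default_factory=dict)
    contigs_fasta: str | None = None
    reference_fasta: str | None = None
    output_dir: str | None = None
    seed: int = 0
    # contamination filter
    k: int = 57
    fold: float = 1000.0
    frac: float = 0.25
    min_len: int = 75
    contamination_mode: str = "pairwise"  # or "pooled"
    normalize_kmer_counts: bool = False
    # ORF finding / annotation
    min_codons: int = 50
    min_score: float = 60.0
    min_identity: float = 40.0
    # mapping
    seed_length: int = 20
    max_mismatches: int | None = None
    # chimera screen
    chimera_fold: float = 10.0
    chimera_window: int = 25
    chimera_min_depth: int = 10
    # species assignment
    expression_fold: float = 5.0
    # clustering
    identity: float = 0.99
    # family summary
    tpm_threshold: float = 0.01

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineInputs:
    """In-memory pipeline inputs (bypasses file loading for tests)."""

    read_sets: list[ReadSet]
    contigs: list[Contig]
    reference: list


@dataclass
class CurationReport:
    """Per-stage counts, per-species catalogs, and provenance."""

    config: dict
    config_hash: str
    seed: int
    stages: dict
    family_summaries: dict
    catalogs: dict  # species -> list of {contig_id, family, tpm, cluster_size}

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": self.stages,
            "family_summaries": self.family_summaries,
            "catalogs": self.catalogs,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def check_conservation(self) -> None:
        """Raise if any stage's in/out/removed counts do not add up."""
        for sample, c in self.stages["contamination_filter"].items():
            if c["reads_in"] != c["reads_kept"] + c["removed_contamination"] + c[
                "removed_too_short"
            ]:
                raise AssertionError(f"read counts inconsistent for {sample}")
        cstage = self.stages["contigs"]
        if cstage["contigs_in"] != cstage["toxin_annotated"] + cstage["unannotated"]:
            raise AssertionError("contig annotation counts inconsistent")
        if cstage["toxin_annotated"] != (
            cstage["chimeric_removed"] + cstage["assigned"] + cstage["ambiguous"]
        ):
            raise AssertionError("contig curation counts inconsistent")
        clusters = self.stages["clusters"]
        assigned_by_species = self.stages["assigned_by_species"]
        for species, info in clusters.items():
            if info["member_total"] != assigned_by_species.get(species, 0):
                raise AssertionError(f"cluster membership inconsistent for {species}")


def _load_inputs(config: PipelineConfig) -> PipelineInputs:
    for label, path in [
        *[(f"sample {s}", p) for s, p in config.sample_fastqs.items()],
        ("contigs", config.contigs_fasta),
        ("reference", config.reference_fasta),
    ]:
        if path is None:
            raise FileNotFoundError(f"missing required input path for {label}")
        if not os.path.exists(path):
            raise FileNotFoundError(f"input for {label} not found: {path}")
    read_sets = [
        vio.read_fastq(path, sample_id=s) for s, path in config.sample_fastqs.items()
    ]
    contigs = vio.read_fasta_contigs(config.contigs_fasta)
    reference = read_reference_fasta(config.reference_fasta)
    return PipelineInputs(read_sets, contigs, reference)


def run_pipeline(
    config: PipelineConfig, inputs: PipelineInputs | None = None
) -> CurationReport:
    """Run every curation stage and return the consolidated report.

    Stage order: cross-contamination + length filtering of reads; complete
    ORF discovery and toxin-family annotation of the input contigs;
    read mapping and coverage; chimera screen (a contig is removed when
    every sample with informative depth shows a coverage step); species
    assignment by three-indicator vote; per-species isoform clustering;
    TPM quantification of cluster representatives; family summaries.
    """
    if inputs is None:
        inputs = _load_inputs(config)
    out_dir = config.output_dir
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)

    stages: dict = {}

    # --- stage 1: contamination + length filter -------------------------
    spectra = {
        rs.sample_id: count_kmers(rs, config.k) for rs in inputs.read_sets
    }
    filtered: list[ReadSet] = []
    filter_counts: dict = {}
    for focal in inputs.read_sets:
        others = [rs for rs in inputs.read_sets if rs is not focal]
        kept, report = filter_sample(
            focal,
            others,
            k=config.k,
            fold_threshold=config.fold,
            coverage_fraction=config.frac,
            min_length=config.min_len,
            mode=config.contamination_mode,
            normalize=config.normalize_kmer_counts,
            focal_spectrum=spectra[focal.sample_id],
            other_spectra=[spectra[rs.sample_id] for rs in others],
        )
        filtered.append(kept)
        removed = report.removed_by_reason()
        filter_counts[focal.sample_id] = {
            "reads_in": report.n_input,
            "reads_kept": report.n_kept,
            "removed_contamination": removed.get("contamination", 0),
            "removed_too_short": removed.get("too_short", 0),
        }
        if out_dir:
            vio.write_fastq(kept, os.path.join(out_dir, f"{kept.sample_id}.filtered.fastq"))
            report.to_tsv(os.path.join(out_dir, f"{kept.sample_id}.filter_report.tsv"))
    stages["contamination_filter"] = filter_counts

    # --- stage 2: ORF discovery and annotation --------------------------
    orfs_by_contig = {
        c.contig_id: find_orfs(c, min_codons=config.min_codons) for c in inputs.contigs
    }
    all_orfs = [o for orfs in orfs_by_contig.values() for o in orfs]
    annotations = annotate_orfs(
        all_orfs, inputs.reference, config.min_score, config.min_identity
    )
    ann_by_contig: dict[str, list] = {}
    for ann in annotations:
        ann_by_contig.setdefault(ann.orf.contig_id, []).append(ann)
    contig_best_ann = {}
    for cid, anns in ann_by_contig.items():
        classified = [a for a in anns if a.family != UNCLASSIFIED]
        if classified:
            contig_best_ann[cid] = max(classified, key=lambda a: a.score)
    toxin_contigs = [c for c in inputs.contigs if c.contig_id in contig_best_ann]
    stages["orfs"] = {
        "orfs_found": len(all_orfs),
        "orfs_classified": sum(1 for a in annotations if a.family != UNCLASSIFIED),
    }

    # --- stage 3: mapping and coverage ----------------------------------
    index = build_seed_index(inputs.contigs, config.seed_length)
    alignments = {
        rs.sample_id: map_reads(
            rs,
            inputs.contigs,
            seed_length=config.seed_length,
            max_mismatches=config.max_mismatches,
            index=index,
        )
        for rs in filtered
    }
    contig_by_id = {c.contig_id: c for c in inputs.contigs}
    profiles = {
        sample: {
            cid: coverage_profile(aln, contig_by_id[cid]) for cid in contig_by_id
        }
        for sample, aln in alignments.items()
    }

    # --- stage 4: chimera screen ----------------------------------------
    chimera_calls: dict[str, dict[str, ChimeraCall]] = {}
    chimeric_ids: set[str] = set()
    for contig in toxin_contigs:
        calls = {}
        eligible = 0
        fired = 0
        for sample in alignments:
            profile = profiles[sample][contig.contig_id]
            if profile.depth.max(initial=0) < config.chimera_min_depth:
                continue
            call = detect_chimera(
                profile,
                fold_threshold=config.chimera_fold,
                window=config.chimera_window,
                min_depth=config.chimera_min_depth,
            )
            calls[sample] = call
            if call.verdict != "indeterminate":
                eligible += 1
                if call.verdict == "chimeric":
                    fired += 1
        chimera_calls[contig.contig_id] = calls
        # removed only when the discontinuity shows in every sample with
        # informative depth
        if eligible > 0 and fired == eligible:
            chimeric_ids.add(contig.contig_id)

    # --- stage 5: species assignment ------------------------------------
    sample_ids = [rs.sample_id for rs in filtered]
    counts_by_sample = {s: alignments[s].counts() for s in sample_ids}
    lengths = {c.contig_id: len(c.sequence) for c in inputs.contigs}
    tpm_by_sample = {}
    for s in sample_ids:
        counts = {cid: counts_by_sample[s].get(cid, 0.0) for cid in contig_by_id}
        table = compute_tpm(counts, lengths)
        tpm_by_sample[s] = dict(zip(table["contig_id"], table["tpm"]))
    assignments = {}
    for contig in toxin_contigs:
        if contig.contig_id in chimeric_ids:
            continue
        assignments[contig.contig_id] = assign_species(
            contig,
            {s: tpm_by_sample[s][contig.contig_id] for s in sample_ids},
            contig_best_ann.get(contig.contig_id),
            {s: profiles[s][contig.contig_id] for s in sample_ids},
            expression_fold=config.expression_fold,
        )
    assigned_by_species: dict[str, int] = {}
    for a in assignments.values():
        if a.assigned_species != AMBIGUOUS:
            assigned_by_species[a.assigned_species] = (
                assigned_by_species.get(a.assigned_species, 0) + 1
            )
    n_ambiguous = sum(
        1 for a in assignments.values() if a.assigned_species == AMBIGUOUS
    )
    stages["contigs"] = {
        "contigs_in": len(inputs.contigs),
        "toxin_annotated": len(toxin_contigs),
        "unannotated": len(inputs.contigs) - len(toxin_contigs),
        "chimeric_removed": len(chimeric_ids),
        "assigned": len(assignments) - n_ambiguous,
        "ambiguous": n_ambiguous,
    }
    stages["assigned_by_species"] = assigned_by_species

    # --- stage 6: clustering, quantification, summaries -----------------
    cluster_info: dict = {}
    family_summaries: dict = {}
    catalogs: dict = {}
    for species in sample_ids:
        members = [
            contig_by_id[cid]
            for cid, a in sorted(assignments.items())
            if a.assigned_species == species
        ]
        clusters = cluster_isoforms(members, identity_threshold=config.identity)
        cluster_info[species] = {
            "clusters": len(clusters),
            "member_total": sum(len(c) for c in clusters),
        }
        # representative counts aggregate the member counts of the cluster
        rep_counts = {
            c.centroid_id: sum(
                counts_by_sample[species].get(mid, 0.0) for mid in c.member_ids
            )
            for c in clusters
        }
        rep_lengths = {c.centroid_id: lengths[c.centroid_id] for c in clusters}
        table = compute_tpm(rep_counts, rep_lengths)
        families = {
            cid: contig_best_ann[cid].family for cid in rep_counts if cid in contig_best_ann
        }
        summary = summarize_families(
            table, families, clusters, threshold=config.tpm_threshold
        )
        family_summaries[species] = {
            "dominant_families": summary.dominant_families,
            "table": summary.table.to_dict(orient="records"),
        }
        tpm_lookup = dict(zip(table["contig_id"], table["tpm"]))
        size_lookup = {c.centroid_id: len(c) for c in clusters}
        catalogs[species] = [
            {
                "contig_id": cid,
                "family": families.get(cid, UNCLASSIFIED),
                "tpm": tpm_lookup[cid],
                "cluster_size": size_lookup[cid],
            }
            for cid in sorted(rep_counts)
        ]
        if out_dir:
            table.to_csv(
                os.path.join(out_dir, f"{species}.expression.tsv"), sep="\t", index=False
            )
    stages["clusters"] = cluster_info
    stages["final_toxin_count"] = sum(len(cat) for cat in catalogs.values())

    report = CurationReport(
        config=config.to_dict(),
        config_hash=config.config_hash(),
        seed=config.seed,
        stages=stages,
        family_summaries=family_summaries,
        catalogs=catalogs,
    )
    report.check_conservation()
    if out_dir:
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            fh.write(report.to_json())
    return report
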