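"""TPM expression quantification and family-composition summaries.

TPM_i = 1e6 * (r_i / l_i) / sum_j (r_j / l_j), where r_i is the mapped-read
count (possibly fractional under multi-mapping) and l_i the contig length
in nucleotides.  Values sum to one million per sample, making libraries of
different depth directly comparable.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .curation import Cluster
from .orfs import UNCLASSIFIED

DEFAULT_FAMILY_THRESHOLD = 0.01

#: An ExpressionTable is a DataFrame with columns contig_id, length, count, tpm.
ExpressionTable = pd.DataFrame


def compute_tpm(counts: dict[str, float], lengths: dict[str, int]) -> ExpressionTable:
    """Length-normalized expression as Transcripts Per Million.

    All-zero counts yield all-zero TPM (no division by zero); a contig with
    a count but no length is an error.
    """
    missing = set(counts) - set(lengths)
    if missing:
        raise ValueError(f"contigs with counts but no length: {sorted(missing)}")
    ids = sorted(counts)
    rows = []
    for cid in ids:
        length = lengths[cid]
        if length <= 0:
            raise ValueError(f"contig {cid}: nonpositive length {length}")
        count = counts[cid]
        if count < 0:
            raise ValueError(f"contig {cid}: negative count {count}")
        rows.append((cid, length, count, count / length))
    table = pd.DataFrame(rows, columns=["contig_id", "length", "count", "rate"])
    total_rate = table["rate"].sum()
    # divide before scaling so a lone contig gets exactly 1e6
    table["tpm"] = 0.0 if total_rate == 0 else (table["rate"] / total_rate) * 1e6
    return table.drop(columns="rate")


@dataclass
class FamilySummary:
    """Per-family expression totals and the above-threshold family list."""

    table: pd.DataFrame  # family, tpm, proportion, contig_count (desc by proportion)
    threshold: float

    @property
    def dominant_families(self) -> list[str]:
        """Families whose share of total expression exceeds the threshold,
        in descending order of proportion."""
        mask = self.table["proportion"] > self.threshold
        return list(self.table.loc[mask, "family"])


def summarize_families(
    table: ExpressionTable,
    families: dict[str, str],
    clusters: list[Cluster] | None = None,
    threshold: float = DEFAULT_FAMILY_THRESHOLD,
) -> FamilySummary:
    """Aggregate a sample's expression by toxin family.

    ``families`` maps contig_id to its annotated family (missing contigs
    count as unclassified).  Contig counts are per-cluster representatives
    when ``clusters`` is given, otherwise per table row.  Proportions are
    of the table's total TPM, so annotated and unclassified rows together
    sum to 1.
    """
    work = table.copy()
    work["family"] = [families.get(cid, UNCLASSIFIED) for cid in work["contig_id"]]
    grouped = work.groupby("family", as_index=False).agg(
        tpm=("tpm", "sum"), contig_count=("contig_id", "nunique")
    )
    if clusters is not None:
        centroid_family = {
            c.centroid_id: families.get(c.centroid_id, UNCLASSIFIED) for c in clusters
        }
        counts: dict[str, int] = {}
        for fam in centroid_family.values():
            counts[fam] = counts.get(fam, 0) + 1
        grouped["contig_count"] = [
            counts.get(fam, 0) for fam in grouped["family"]
        ]
    total = grouped["tpm"].sum()
    grouped["proportion"] = 0.0 if total == 0 else grouped["tpm"] / total
    grouped = grouped.sort_values(
        ["proportion", "family"], ascending=[False, True], ignore_index=True
    )[["family", "tpm", "proportion", "contig_count"]]
    return FamilySummary(grouped, threshold)
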