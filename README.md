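# venomtx

Curation and molecular-evolution analysis of multiplexed venom-gland
transcriptomes.

## The problem

Venom-gland RNA-seq studies of snakes (and other venomous taxa) often
multiplex several species in one sequencing run. Producing a trustworthy
toxin catalog from such data requires a chain of curation steps after de
novo assembly: removing the low but real fraction of reads that leak
between samples ("index hopping"), keeping only complete open reading
frames, recognizing toxin families by similarity to curated references,
discarding chimeric contigs that assemblers stitch together from distinct
transcripts, deciding which multiplexed species each contig actually came
from, collapsing near-identical isoforms, and normalizing expression so
that libraries are comparable. Downstream, the hallmark question for
rapidly evolving toxin families such as the three-finger toxins (3FTx) is
whether they evolve under diversifying selection, read off the ratio of
nonsynonymous to synonymous substitution rates (dN/dS = ω).

`venomtx` implements this whole path as a tested, reusable Python library
with a thin CLI, plus a synthetic-data generator that produces multiplexed
venom-gland-like batches with known ground truth, so every stage can be
validated end to end without touching external archives.

## Methods at the core

- **Cross-contamination filter.** Canonical k-mers (k = 57 by default) are
  counted per sample; a focal k-mer is flagged when another sample of the
  same lane carries it at ≥ 1000-fold the focal count, and a read is
  removed when flagged k-mer occurrences cover ≥ 25% of its bases. Reads
  shorter than 75 bp are removed independently.
- **ORF curation and annotation.** Six-frame scan for complete ORFs
  (ATG…stop, no internal stop, ≥ 50 codons); Smith–Waterman (BLOSUM62,
  affine gaps 11/1) against a family-labelled reference database; the
  family of the best hit above score/identity thresholds is assigned.
- **Chimera screen.** Read coverage is profiled per base; adjacent-window
  median ratios ≥ 10 (window 25 nt) mark coverage discontinuities.
- **Species assignment.** Three indicators — relative expression (≥ 5-fold
  TPM ratio), best-hit taxon, and coverage breadth — vote per contig;
  two agreeing indicators decide.
- **Isoform clustering.** Greedy incremental clustering at 99% identity,
  longest sequence first, identity computed over the shorter sequence,
  best-matching centroid wins, clusters sorted by size.
- **Expression.** TPMᵢ = 10⁶·(rᵢ/ℓᵢ)/Σⱼ(rⱼ/ℓⱼ) for count rᵢ and length ℓᵢ,
  with per-family totals and the list of families above 1% of expression.
- **Selection analysis.** Nei–Gojobori (1986) counting method: synonymous
  and nonsynonymous site and difference counts (all minimal mutational
  pathways weighted equally, stop-traversing pathways excluded),
  Jukes–Cantor correction d = −¾·ln(1 − 4p/3), ω = dN/dS; clade estimates
  pool counts over all sequence pairs before correction. Tree utilities
  cover Newick I/O, midpoint rooting and clade extraction.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/04_cluster_and_quantify.py` prints:

```
9 contigs -> 3 clusters
  centroid 3FTx_iso0: members ['3FTx_iso0', '3FTx_iso1', '3FTx_iso2']
  centroid PLA2_iso0: members ['PLA2_iso0', 'PLA2_iso1', 'PLA2_iso2']
  centroid kunitz_iso0: members ['kunitz_iso0', 'kunitz_iso1', 'kunitz_iso2']

TPM sum: 1,000,000
family           tpm  proportion  contig_count
  3FTx 721895.734597    0.721896             1
kunitz 241706.161137    0.241706             1
  PLA2  36398.104265    0.036398             1
families above 1% of expression: ['3FTx', 'kunitz', 'PLA2']
```

Nine isoform contigs collapse to one representative per planted family;
TPM sums to one million by construction; and the family summary reads off
which toxin families carry more than 1% of the gland's transcription —
here the classic elapid trio of 3FTx, kunitz peptides and PLA2.

Selection analysis (`python examples/05_selection_analysis.py`) recovers a
simulated diversifying-selection regime:

```
simulated omega: 2.4
pooled estimate: dN=0.0677 dS=0.0298 omega=2.27 (ok) over 66 pairs
```

ω well above 1 is the signature of positive selection that fast-evolving
toxin families show.

The same stages are available from the shell, e.g.:

```bash
venomtx xcontam --k 57 --fold 1000 --frac 0.25 --min-len 75 \
    --focal A.fastq --others B.fastq --others C.fastq
venomtx omega --aln clade.fasta
venomtx run --config run.yml
```

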