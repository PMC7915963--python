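# Methods

This note records the models, parameter choices and numerical conventions
behind `venomtx`, what the synthetic data does and does not emulate, and
the known limitations.

## Cross-contamination filter

Reads leaked between multiplexed samples are detected at the k-mer level.
All length-k windows of every read are counted in canonical (strand-folded)
form — the lexicographic minimum of the window and its reverse complement,
packed two bits per base; windows containing non-ACGT characters are
skipped, but ambiguous positions still count toward read length in the
coverage denominator. A focal-sample k-mer is *flagged* against another
sample when `other_count / focal_count >= fold` (inclusive, default 1000);
k-mers absent from the focal spectrum are never flagged because they
cannot mark any focal read. A read is removed when the union of base
positions covered by flagged k-mer occurrences — across all other samples
in pairwise mode, or against a pooled rest-of-lane spectrum in pooled
mode — reaches `frac` (default 0.25, inclusive) of its length. Reads
shorter than `min_len` (default 75 nt) are removed independently. Ratios
use raw counts by default; an optional normalization rescales the other
sample's counts by the ratio of spectrum totals when library depths are
unequal.

**A structural property worth knowing.** The count of a contaminant k-mer
in the focal sample comes from the contaminant reads themselves, so the
other/focal ratio concentrates around `(n_samples − 1) / rate`
independently of depth or transcriptome size. A 1000-fold threshold can
therefore only fire when the per-sample contamination rate is below about
0.1% (for three samples); at deeper contamination the fold threshold must
be lowered accordingly. The filter is exposed with every threshold
configurable for exactly this reason, and the acceptance script reports
the measured sensitivity at the default settings rather than assuming
them adequate.

## ORF discovery and family annotation

Complete ORFs (ATG…stop in one frame, no internal stop) are enumerated on
all six frames; incomplete fragments are discarded, which is the binding
curation rule — no coding-likelihood model is used. Nested ORFs sharing a
stop codon report only the longest by default. Coordinates are 0-based
half-open on the forward strand (converters to 1-based inclusive are
provided). `min_codons` defaults to 50, small enough for short toxin
precursors (three-finger toxin precursors run under 100 aa).

Annotation is Smith–Waterman local alignment (BLOSUM62; affine gaps with
open 11, extend 1, i.e. a gap of length L costs 11 + L) of the ORF protein
against a reference database whose FASTA headers carry
`refid|FAMILY|taxon`. Hits are ranked by score, ties by identity
(identical aligned columns over alignment length) then reference id; the
best hit clearing `min_score` (60) and `min_identity` (40%) assigns the
family, otherwise the ORF is `unclassified`. Raw score plus identity
thresholds stand in for E-values, whose database-size calibration is out
of scope.

## Mapping and coverage

The native mapper is seed-and-verify: non-overlapping exact seeds
(default 20 nt) index the contigs; each seed hit proposes one gapless
full-length placement verified by mismatch counting, capped at
`max_mismatches` (default 5% of read length). Ties at the best mismatch
count are shared fractionally (1/n to each location) for quantification,
or resolved to the first contig in id order in primary mode. There are no
indels and no soft clipping; SAM import via pysam plugs in an external
aligner when that matters. Coverage depth counts placements per base
(weights are not applied to depth).

## Chimera screen

Chimeric assemblies appear as sharp discontinuities in coverage. At every
interior position the median depth over the `window` (25 nt) bases on each
side is compared; a position fires when the higher/lower ratio reaches
`fold` (10) and the higher side reaches `min_depth` (10). Consecutive
firing positions form a run reported as a single breakpoint at the middle
of the run's maximal-ratio stretch — on a clean step the firing run is
symmetric around the junction, so its center estimates the breakpoint.
Windowed medians rather than single-base ratios resist sampling noise.
Because the mapper is gapless and end-to-end, junction-spanning reads drop
out entirely and a planted chimera shows a V-shaped dip one read length
wide around the junction in addition to the step; shorter reads therefore
sharpen the signal, and the recovery analyses simulate 50 nt reads for
this stage. In the pipeline a contig is removed only when every sample
with informative depth (maximum depth at least `min_depth`) shows a
discontinuity.

## Species assignment

Each contig in a multiplexed batch is assigned by three indicators:

- expression vote — the sample whose TPM exceeds every other sample's by
  `expression_fold` (default 5; contamination-driven expression is
  typically hundreds of folds lower, so a statistical test adds nothing
  at these asymmetries);
- similarity vote — the sample matching the best hit's taxon label;
- coverage vote — the sample with near-complete breadth (≥ 0.9 of bases
  covered) while every other sample is sparse (≤ 0.5).

An indicator that cannot decide is `equivocal`. Two agreeing indicators
assign the contig; confidence is 3/3 with no dissenting indicator, 2/3
with one, and the contig is `ambiguous` otherwise. A species with zero
mapped reads can never win.

## Isoform clustering

Greedy incremental clustering: sequences sorted longest-first (ties by
id); each joins the existing centroid of highest identity when that
identity reaches the threshold (default 0.99), else founds a cluster.
Identity is identical aligned columns over the *shorter* sequence, from a
global alignment with free end gaps — the conventions of the standard
short-sequence clustering tools. Output clusters are sorted by member
count descending. The partition property (members sum to inputs) holds by
construction and is asserted in tests.

## Expression

TPMᵢ = 10⁶·(rᵢ/ℓᵢ)/Σⱼ(rⱼ/ℓⱼ) with effective length equal to contig
length — no fragment-length correction, the convention of venom
transcriptomics. All-zero counts give all-zero TPM. Rates are normalized
before scaling so a lone contig receives exactly 10⁶. Family summaries
report per-family TPM totals, proportions of the summarized set (the
toxin-annotated subset in the pipeline; unannotated rows count as
`unclassified` so proportions always sum to 1) and unique-contig counts
after clustering, plus the families above the reporting threshold
(default 1%).

## Selection analysis

dN/dS uses the Nei–Gojobori (1986) counting method. Site counts per sense
codon take each position's synonymous fraction of its three possible
changes; mutations creating stop codons count as nonsynonymous, so
synonymous + nonsynonymous sites equal exactly 3 per codon. Differences
between codons average over all minimal mutational pathways with equal
weight, excluding pathways through stop codons (if every pathway is
blocked, all are used). Proportions are corrected with Jukes–Cantor,
d = −¾·ln(1 − 4p/3), undefined at p ≥ ¾ (flagged `saturated`). ω = dN/dS;
ω is 0 whenever no nonsynonymous difference is observed and some
synonymous difference is, and undefined (with explicit status) when
dS = 0. Clade-level estimates pool site and difference counts over all
unordered pairs *before* correction, so nearly identical pairs do not
dominate through individually noisy ratios; gapped or ambiguous codon
columns are dropped per pair, not listwise. The counting estimator is a
deliberate, documented substitute for likelihood machinery: point
estimates on real data will differ from ML values, and the recovery
analyses quantify its behaviour on simulated data instead.

Mature-protein trimming removes a stated number of signal-peptide codons
and the terminal stop; signal-peptide prediction is out of scope and the
length comes from annotation metadata.

## Codon simulator

`evolve_codon_clade` evolves sequences under a continuous-time Markov
chain on the 61 sense codons with an HKY-style nucleotide kernel:
single-nucleotide changes only, transitions scaled by κ, nonsynonymous
changes scaled by ω (an MG94-flavoured parameterization); stop codons are
unreachable. The matrix is scaled so one unit of branch length is one
expected substitution per codon site at the uniform codon distribution.
Descendants radiate from the ancestor on a star tree by default or along
a supplied tree. This is simpler than a full ML codon model but
sufficient for recovery tests.

Recovery analyses simulate 20 taxa × 100 codons at branch length 0.1 with
κ = 1, matching the counting estimator's own assumption of no transition
bias — the proper consistency check for an estimator that counts sites
unweighted. Under these conditions the estimator's analytic bias is about
−5.5% (stop-bound changes contribute nonsynonymous sites but no flux), so
ω = 2.4 is recovered near 2.27. Ordering across ω regimes is additionally
checked at κ = 2.

## Trees

Newick parsing, midpoint rooting and clade extraction are thin wrappers
over dendropy. Midpoint rooting places the root halfway along the longest
leaf-to-leaf path; tests assert the two deepest root-to-leaf distances
agree within 10⁻⁹ and that the root lies on the brute-force diameter
path. Clade extraction requires the leaf set to be monophyletic in the
rooted tree and names the intruding leaves otherwise.

## Synthetic data: what it emulates, what it does not

The generator emulates: several species' toxin repertoires with family
composition following a configurable profile (defaults: 3FTx 60%,
kunitz 25%, PLA2 10%, and six minor families each under 1% — a typical
elapid venom-gland profile with exactly three families above the 1%
reporting threshold); log-normal per-transcript expression skew (σ = 1.5)
rescaled so each family's total share matches its profile weight; one
designed complete ORF per transcript, derived from a per-family ancestral
protein with 8% amino-acid divergence per member so family membership is
recoverable by similarity; uniform substitution sequencing error; uniform
strand; verbatim cross-sample read copies at a set rate; planted chimeric
joins with recorded breakpoints; and codon evolution at known ω.

It does not emulate: indels, PCR duplicates, paired ends or insert-size
structure, empirical quality profiles (qualities are constant Phred 40 —
quality trimming is external to this pipeline), strand-specific library
chemistry (the k-mer logic is strand-canonical anyway), untranslated-
region biology, or shared toxin sequences between species (species are
deliberately disjoint in sequence space, which is what makes ground-truth
contamination scoring meaningful). Passing tests therefore demonstrate
the correctness of the curation logic under known conditions, not the
behaviour of assemblers or aligners on real libraries.

Ground-truth labels (read provenance, transcript family and weight,
chimera breakpoints) live on the in-memory objects and in TSV sidecars;
they are never embedded in the FASTA/FASTQ the pipeline stages consume.

Default study conditions for the end-to-end analyses: 3 species ×
20 transcripts (mean length 500 nt), 100,000 reads per sample, 150 nt
reads, 1% substitution error, 1% cross-sample contamination. These sizes
keep a full run around two minutes on one CPU while leaving every
per-stage signal (coverage ~1500×, contamination ~200-fold below genuine
expression) far from sampling noise.

## Degenerate inputs and numerical conventions

- Empty read sets, empty contig sets and all-zero counts flow through
  every stage without error and produce zero-count reports.
- `filter_reads` decisions are independent of read order; reason
  precedence is contamination before length.
- Thresholds quoted as "N-fold or higher" / "X% or more" are inclusive
  (≥) everywhere.
- TPM sums to 10⁶ within 10⁻⁶ relative tolerance whenever any count is
  positive; the single-contig case is exact.
- Contigs shorter than two chimera windows are `indeterminate`, never
  removed.
- Fixed seeds make every generator and the pipeline byte-reproducible;
  the pipeline report embeds the seed and a config hash.

## Known limitations

- The mapper is gapless and end-to-end; real indel-bearing reads need an
  external aligner via SAM import.
- The counting dN/dS estimator saturates at p ≥ ¾ and carries the −5%
  structural bias discussed above; it is not a substitute for ML
  branch-site models when site-level inference matters.
- The 1000-fold contamination rule is only effective at contamination
  rates below roughly 0.1% per sample pair (see the structural property
  above); deeper contamination requires lowering the fold threshold.
- Greedy clustering is order-dependent by design (longest-first); it
  reproduces the standard tool's behaviour, not an optimal partition.
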