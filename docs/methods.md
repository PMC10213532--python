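# Methods

This note documents the models, conventions and design choices behind
acetotrace, in the order the pipeline applies them.

## Concatenated queries

Translated searches against whole-genome nucleotide databases are run with
protein subqueries joined into one concatenated query, separated by spacers
of 100 lowercase `x` letters. The spacer symbol is reserved: subquery
sequences containing `x` are rejected, which makes coordinate bookkeeping
unambiguous (splitting is done by the interval registry, never by scanning
for the symbol). The conventional cap of 17 subqueries is a soft limit —
exceeding it warns but does not fail, since nothing in the method breaks at
18. Subquery *i* occupies positions `1 + Σ_{j<i}(len_j + 100)` onward; the
`locate` operation clips any concatenated-query range to the subqueries it
overlaps and is total over valid coordinates.

## Hit screening

**Input dialect.** The parser reads the common 12-column tabular search
output extended with aligned sequence strings (`qseqid sseqid pident length
qstart qend sstart send evalue bitscore qseq sseq`), tab-separated, no
header; a user-declared column order is accepted. `sseqid` is split as
`genome|contig`. `sstart > send` encodes the minus strand. Malformed rows
abort with their line numbers rather than being silently dropped.

**Per-subquery assignment.** Each HSP is walked column by column; columns
whose query position falls in spacer sequence are excluded from both
identity and coverage (the spacer is artificial sequence), and HSPs
spanning a spacer are split into per-subquery segments. Subject codon
coordinates are tracked per column so each segment carries a genomic
interval.

**Gene grouping.** Same-strand segments on one replicon whose subject
intervals lie within 300 bp of each other are merged into one gene locus
before screening. The threshold only has to be small relative to the
intergenic distances that matter downstream (0.5 kb and 15 kb windows);
values between ~100 bp and ~500 bp give identical results on realistic
layouts, since genuine HSP fragments of one gene are separated by at most a
few codons of unaligned sequence.

**Retention rules.** Identity is `100 × matching columns / all alignment
columns` (gap columns included, case-insensitive, a gap never matches) —
the common translated-search convention. When a locus has several HSPs on
one subquery, identity is taken from the best-scoring HSP and coverage from
the union of their query intervals — the most permissive reading of a
coverage requirement. Cut-offs are inclusive minima: identity ≥ 25% and
coverage ≥ 80% by default, with a per-subquery override table. EchE-tagged
subqueries default to identity ≥ 28% plus ≥ 2 CxxC motifs in the ungapped
hit translation; the motif count is the number of positions *i* with
cysteine at *i* and *i+3*, overlapping occurrences counted (the biological
requirement is "at least two", so overlap handling cannot change a
verdict). Failures are attributed in the fixed order identity → coverage →
motif, which makes fail reasons deterministic when several rules fail at
once. Exact-duplicate removal keeps the first occurrence of each distinct
sequence after case normalization and gap stripping — the 100%-identity
collapse used before tree building.

## Co-location

Distance between neighboring genes is the end-to-start gap on the
forward-normalized axis (minus-strand intervals are normalized to
`(min, max)`; co-location is strand-agnostic); overlapping genes count as
gap 0. Clustering is single-linkage per (genome, contig): a gene joins the
current cluster iff its start lies within the window of the running cluster
end. Two windows are reported: 15 kb (default) and 0.5 kb (tight,
operon-like). Because 0.5 ≤ 15, tight clusters are always a refinement of
default clusters, and both are partitions of the retained hits — these
invariants are property-tested.

Extracted sequences are the ungapped subject translations of the
best-scoring HSP per locus, named
`taxonomy|genome|contig:start-end(strand)|context` with whitespace replaced
by `_` for tree-label safety; the context code lists cluster members in
genomic order with strand signs (`acsB+.acsC+.acsD-`), so it is invariant
under input reordering.

## Pairwise identity and genome statistics

Global percent identity uses Needleman–Wunsch with BLOSUM62 and affine
gaps costing 11 to open plus 1 per residue (the classic translated-search
defaults; implemented as open −12 / extend −1 in the aligner's
first-residue convention), with identity = matches over all alignment
columns. Nucleotide comparisons (e.g. 16S rRNA copies) use +2/−3 with
7/2 gap costs. Cluster identity profiles apply this per homolog pair and
report min/max — the per-subunit identity ranges quoted when comparing two
gene clusters. G+C content is `100 × (G+C)/(A+C+G+T)` in mol% to one
decimal, ambiguity symbols excluded from both numerator and denominator,
and is invariant under reverse complement. GenBank CDS extraction prefers
the deposited `/translation` (bit-exact agreement with annotation) and
falls back to translating the feature location with the bacterial code
(table 11).

## Gain/loss reconstruction

Ancestral presence/absence is reconstructed per family by Sankoff dynamic
programming over the fixed rooted reference tree with asymmetric penalties:
gain 2, loss 1 by default, reflecting that independent acquisition of a
gene family is rarer than loss. A probabilistic birth–death model with
optimized rates would estimate event *rates*; the downstream question here
only needs presence/absence calls and branch placement of losses, for which
weighted parsimony gives the same qualitative calls on low-homoplasy data,
deterministically and without rate fitting. Ties are broken toward
ancestral presence (root ties resolve to present; child-state ties at equal
penalty prefer present), consistent with the gain-averse penalty asymmetry
and making the reconstruction unique. The dynamic program is verified
against exhaustive enumeration of all internal labelings on trees up to 12
leaves.

Focal-loss classification compares two focal taxa against a background set
(the rest of their clade): a family is a **paired loss** iff a loss event
lies on branches covering each focal taxon separately — its terminal
branch, or a branch ancestral to exactly one focal taxon and no background
taxon — while every background taxon retains the family; a **unique loss**
is the same condition for exactly one focal taxon; families present in all
focal and background taxa are **retained**; everything else (e.g.
background absences, or a single shared ancestral loss covering both focal
taxa) is **other**. A shared ancestral loss is deliberately *not* a paired
loss: the definition requires parallel, independent events.

## Synthetic databases

The generator emulates a representative-genome database annotated with
7-rank GTDB taxonomy strings. Its defaults are the study conditions used
throughout the tests and the acceptance script:

- 20 genomes, one contig each, background G+C 0.40 (a typical
  low-G+C Firmicutes value);
- homologs planted at 80% identity to the queries, decoys at 20%
  (straddling the 25% cut-off from both sides), EchE variants at ~55%
  (above the 28% cut-off, so verdicts isolate the motif rule);
- cluster spacings 0.4 kb (tight), 2–9.5 kb (default window), 16.8 kb and
  20 kb (beyond the default window) — the 16.8 kb/9.5 kb pair mirrors a
  CO-dehydrogenase gene sitting just outside a WLP cluster while another
  member sits just inside;
- a truncated homolog at 70% of query length (coverage failure), EchE
  genes with 2/1/0 CxxC motifs, filler genomes with random 2–4 gene
  subsets at 30–90% identity on random strands, and one empty genome as a
  negative control.

Mutation to a target identity substitutes `round(L·(1−t/100))` distinct
positions, each to a different standard amino acid (never a stop), so the
realized identity is exact up to rounding (±2 points even for short
proteins, per-site mutation being quantized at 1/L). Coding sequences are
random synonymous back-translations under table 11 placed at the planted
coordinates (reverse-complemented on the minus strand), so translating any
planted interval recovers the protein exactly. Simulated search output
contains one full-length, gapless HSP per planted gene with subject
coordinates equal to the planted interval; its recomputed identity equals
the realized identity by construction. Everything is deterministic per
seed, byte-for-byte.

What the mock data does **not** emulate: alignment gaps and fragmented
HSPs in the simulated search output (those paths are exercised by
hand-built alignments in the unit tests instead), sequencing or assembly
error, annotation noise, compositional heterogeneity, and genuinely remote
homology where alignability itself is in question. Passing the end-to-end
tests therefore shows the bookkeeping and the rules are exact, not that
the cut-off values are optimal for real databases — the cut-offs are
inputs, taken from practice.

## Numerical and degenerate-input conventions

- All thresholds are inclusive (≥); boundary cases are tested at exactly
  25.0/24.9% identity and 80.0/79.9% coverage with 1000-column alignments
  so the boundary values are exactly representable.
- Empty inputs: empty search output → empty hit list; empty HSP list →
  coverage 0; empty co-location input → empty report; a cluster is never
  empty by construction.
- Coordinates are 1-based inclusive throughout, except the BED-like export
  (0-based half-open).
- Identity/coverage are plain floating-point ratios of integers ≤ a few
  thousand; no tolerance issues arise beyond standard float printing,
  and comparisons against cut-offs use the raw values, not rounded ones.

## Problem sizes

The test suite and the acceptance script run on the 20-genome synthetic
database (~50 planted genes), 200 random parsimony instances of up to 12
leaves (where exhaustive enumeration is still exact), and 40-family planted
loss matrices. These sizes are chosen so every check is exact — brute-force
oracles stay feasible and recovery can be demanded to be perfect — while
the whole validation completes in seconds; the implementation itself is
linear in hits and families and handles database-scale input.

## Known limitations

- The screening rules assume the search reports aligned sequence strings;
  plain 12-column output without `qseq`/`sseq` cannot be screened (identity
  would be trusted, coverage ambiguous) and is rejected.
- Identity from a *local* search underestimates global identity for
  partially aligned pairs; the extraction step emits the aligned part only,
  as the workflow intends (terminal variability is discarded at tree
  building anyway).
- Wagner parsimony does not estimate rates and can misplace events under
  heavy homoplasy; the paired/unique-loss logic is only claimed exact for
  low-homoplasy regimes, as property-tested.
- Whole-proteome average amino-acid identity (AAI) is method-dependent
  (reciprocal-hit criteria vary) and is deliberately not implemented.
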