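# Methods

## Problem setting

tRNA genes and tRNA-derived elements (SINEs, pseudogenes, truncations)
form a large, highly repetitive gene family. Many functional tRNAs exist
as several *identical* copies scattered over the genome, while tRNA-like
elements can outnumber real genes by orders of magnitude. Two consequences
drive the design of this pipeline:

1. orthology between genomes must come from genomic *context* (coordinate
   projection through a whole-genome alignment), not from the gene
   sequence itself; and
2. copy identity is an exact-string property of the mature transcript, so
   a single point mutation moves a copy out of its family.

## Coordinate and sequence conventions

All in-memory coordinates are 0-based half-open on the forward strand;
the tRNAscan-SE tabular dialect (1-based inclusive, begin>end encoding the
minus strand, introns in transcription order) and BED6 are converted at
parse/write boundaries only. Intron intervals are stored gene-relative
along the gene's own 5'→3' direction. All sequence comparisons are on
uppercased sequence, so soft-masking cannot split a copy family.

Mature-sequence projection excises introns, appends the non-encoded 3'
CCA, and prepends the post-transcriptional G-1 for His tRNAs; sequences
retaining any non-ACGT base are rejected ("ambiguous") because exact
string identity downstream cannot tolerate wildcards. CCA is appended
unconditionally (no special case for dialects that mark pre-encoded CCA).

## Ortholog sets

Liftover records (gene ± 20 bp flank projected into each other genome)
are grouped per (source locus, destination genome/chrom/strand);
fragments separated by ≤ 10 bp merge into one interval (indel-scale
discontinuities), merged intervals shorter than 50 bp are discarded, and
an interval links to any annotated destination locus it overlaps by
≥ 1 bp. Edges must be supported by projections in both directions.

Each surviving edge is then validated by a local alignment (match +1,
mismatch −1, gap −2) of the two loci extracted with 100 bp flanks: the
alignment must span at least half of the shorter flanked sequence. Two
copies of an identical ~75 bp gene body placed in unrelated flanking
contexts can align only over the body (< half of ~275 bp) and fail, while
true orthologs share flanks and pass — this is the property that lets the
pipeline distinguish orthologs from paralogs in a family of identical
copies. Validation is applied to every edge, not only reference-genome
edges. The "half the total" denominator uses the *minimum* of the two
flanked lengths (configurable); the alternative readings (max,
per-sequence) are stricter or asymmetric and were not needed to reject
any planted paralog pair.

Validated components that are cliques with ≤ 1 locus per genome become
ortholog sets directly; other components are resolved by repeatedly
removing the node of lowest degree (ties broken lexicographically by
locus id, then genome) — the weakest-connected member is the most likely
mis-projection. Removed nodes re-enter as their own candidate components,
so every locus ends up in exactly one emitted set (possibly a singleton).

For a genome with no member, the set is classified **missing** when no
member's projection reaches that genome at all, and **pseudo** when a
projected region exists but overlaps no annotated locus (the scanner
found nothing above its score floor there). A projection overlapping an
annotated locus that is nonetheless outside the set is flagged
**conflict** for QC rather than silently relabelled.

## Scores and thresholds

| parameter | default | meaning |
|---|---|---|
| score floor | 10 bits | scanner minimum; rows below are not loci |
| high-score cutoff | 50 bits | tRNA vs tRNA-like, strictly `>` |
| Pol III cutoff | 2 | occupancy class boundary, `>=` |
| pseudocount / cap | 20 / 6 | occupancy score stabilization and clamp |
| read extension | 50 bp | counting window each side of the locus |
| projection flank | 20 bp | liftover extraction margin |
| validation flank | 100 bp | flank-anchored validation margin |
| min length | 50 bp | shorter projections/extractions dropped |
| merge gap | 10 bp | projection fragments merged across |
| min align fraction | 0.5 | of the shorter flanked sequence |
| multicopy threshold | 2 | copies needed in both genomes for conversion |
| recurrence threshold | 10 | events to call a pair recurrently converted |
| conservation threshold | 16 | strains at single copy to call conserved |

The Pol III score is `clamp(log2((t + p)/(c + p)), 0, cap)` on unique-read
counts; uniqueness is an input flag (the SAM adapter maps "MAPQ > 0 and
no XS-equivalent tie with AS" to it) because read mapping itself is out
of scope. Each read counts once per overlapped window; reads or fragments
is the caller's choice of input.

## Variation statistics

Members of a set are near-identical, so a star alignment anchored on the
longest member (global pairwise alignments under the same +1/−1/−2
scoring, merged with "once a gap, always a gap") is an adequate stand-in
for a covariance-model alignment; its column indices are the positional
proxy for canonical (Sprinzl) tRNA positions, and a user-supplied
column→position map can relabel them for real data. Gap-vs-residue counts
as a mismatch: indels are sequence changes. The per-column variation
frequency of a class of sets is, for each strain, the fraction of sets
whose member in that strain differs from the reference row at the column,
maximized over strains. The reference row is the reference genome's
member, else the lexicographically first.

## Gene conversion

A candidate event is an ortholog set whose members in two genomes carry
different mature sequences, both of which are multicopy (≥ 2) in *both*
genomes — a precise switch between two dispersed families, which
independent point mutation essentially cannot produce (a fresh mutation
is single-copy by construction, which is also why mutation-only panels
yield exactly zero events). Pairs where one sequence is a substring of
the other are removed as truncation artifacts. Direction is not assigned;
an optional parsimony annotation marks the genomes carrying the set's
minority sequence as the likely conversion site. Events are keyed per
set and genome pair, so one biological event seen against many partner
genomes accumulates recurrence counts per unordered sequence pair.

## Mann-Whitney U

Occupancy of fully conserved single-copy tRNAs is compared against less
conserved ones with a two-sided Mann-Whitney U test: U from midrank sums;
for n₁+n₂ ≤ 16 the p-value is exact by full enumeration of the C(n₁+n₂,n₁)
labelings of the pooled sample (ties handled by the enumeration itself),
otherwise a normal approximation with tie and continuity corrections.
Two-sided p doubles the smaller tail, capped at 1. This is implemented
here rather than delegated because the exact-with-ties branch is not
available in standard library routines; the asymptotic branch is
cross-checked against scipy in the tests.

## Synthetic panel generator

The generator emulates a mouse-strain-like panel: 17 strains (a reference
plus 15 close laboratory strains in two clades, one divergent strain) and
one distant outgroup, on a fixed tree with branch lengths 0.2–0.3 within
the clades, 3.0 to the divergent strain and 6.0 to the outgroup.
Ancestral families (24 by default, ~30% low-scoring tRNA-like) of
70–90 bp bodies are placed in 1–6 copies (half single-copy), each copy
with its own fixed 120 bp flanks and 60 bp spacers on a toy chromosome;
flank uniqueness per copy is exactly the property the validation step
relies on. Down each branch, per locus: substitution events at 0.08 per
unit length (giving ~3% changed loci between close strains and ~30% on
the divergent lineage), deletions and pseudogenizations at 0.004 (→
missing / pseudo), conversions at 0.004 (body and annotation overwritten
by another family's ancestral state, flanks preserved). Covariance scores
are class-assigned: high families U(55, 90), tRNA-like U(10, 45);
pseudogenized loci fall below the scanner floor and are not annotated.
Liftover maps come from the true coordinate correspondence with 20%
fragmentation noise (two fragments, ≤ 10 bp gap), plus planted one-way
records and bidirectional paralog-trap records (rate 0.05 per genome
pair) to exercise the safeguards. ChIP counts are negative binomial
(dispersion 5) with treatment mean 640 at active loci versus 20 at silent
loci and in the control, separating the classes by ~4 score units; two
replicates are drawn. All draws come from one seeded generator, and a
fixed seed reproduces every file bit for bit.

What the generator does **not** emulate: assembly errors and unassembled
repetitive regions (so copy counts are exact, unlike real strain
assemblies), SINE amplification dynamics, sequencing reads (counts are
the boundary; a toy SAM adapter covers the read-counting path),
structural rearrangements or inversions (liftover strands are consistent
by construction), and covariance-model scoring itself (scores are truth
assignments, not computed from sequence). Passing tests therefore
demonstrate the correctness of the pipeline's logic under the stated
statistical structure, not robustness to assembly artifacts.

## Problem sizes and numerics

The default test panel is 18 genomes × ~45–60 loci (≈950 loci, ≈7,900
true ortholog pairs, ≈19,000 liftover records) and runs end to end in
~15 s; batch recovery tests use 5-genome panels (100 panels for
copy-matrix recovery, 50 for conversion recall). Alignments use
Biopython's pairwise aligner with integer scores, so results carry no
floating-point ambiguity; alignment ties are resolved by the aligner's
deterministic canonical traceback. Sets, tables and JSON summaries are
emitted in sorted order and logs carry no timestamps, making full reruns
byte-identical.

## Known limitations

* Copy identity defaults to mature-sequence equality; a genomic-body
  switch exists because the correct choice for historical datasets is
  ambiguous, and the two can differ for loci whose introns vary.
* Non-clique orthology components are resolved greedily; a pathological
  component could in principle be split suboptimally, though planted
  panels never produce one.
* Positional variation uses alignment columns, not true canonical tRNA
  numbering; cross-family column comparisons are only as good as the
  star alignment.
* The conversion test is conservative by design: conversions involving
  single-copy families, or families collapsing below two copies, are
  invisible to it.
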