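# Methods

This note records the models, parameter choices and numerical conventions
behind `helikit`, and what the synthetic-data validation does and does not
demonstrate.

## Homology search

Copies are found by seed-and-extend: exact k-mer seeds (word size 11, a
megablast-like choice appropriate for ≥ 80%-identity targets) are located
via a sorted-array index over the forward strand of each contig; minus-strand
hits come from searching the reverse-complemented query. Seeds are clustered
on diagonals (band 25 bp) and a cluster needs **two non-overlapping seeds**
before it is extended, which bounds runtime on repetitive background.
Extension is gapped local alignment (Smith–Waterman via Biopython's C
aligner) of the query against the genomic window around the cluster, scored
match +1, mismatch −2, gap open −4, gap extend −1 — one scoring scheme used
everywhere in the package so identities are comparable across stages.

**Identity is matches / alignment columns, gaps counted as columns.** This
is the strict reading of "80% identity over 100 bp" for gapped alignments;
`aligned_len` is likewise a column count.

Post-processing distinguishes two situations that a naive merge conflates:
hits overlapping by more than half of the shorter one on the genome are
duplicate extensions of one copy (best score kept), while hits close on
**both** the query and the target (< 20 bp) are fragments of one copy split
by an indel and are merged. Adjacent-but-distinct copies overlap on the
query and are therefore never merged. When extracting a copy, the aligned
span is padded by small (≤ 15 bp) unaligned query overhangs: local alignment
trims a mutated terminal base together with its neighbours, and without the
pad the 5′-TC / 3′-CTRY checks would fail on otherwise intact copies.
Truly truncated copies have overhangs far above the cap and are left as
aligned.

Equivalence with an exhaustive affine-gap DP oracle (written independently
in the tests and the acceptance script) is checked on ≤ 100 kb instances:
hit identities agree within ±0.03.

## Structural hallmarks

The 3′ motif defaults to `CTRY` with `CTRR` available as a parameter (both
spellings circulate; `CTRY` is the superset actually used for copy
validation). Positions containing `N` make a check *un-validatable* (flag
`None`) rather than failed. The host-context check is simply
`A` | element | `T` on the element strand — rolling-circle integration
creates no target-site duplication, so there is nothing else to test.

The hairpin finder is a combinatorial inverted-repeat search (no
thermodynamics): best palindrome with total span 16–20 bp, loop 3–10 bp,
within the 50 bp upstream of the 4 bp terminus, ties broken by longer stem
then proximity to the 3′ end. Defaults are stem ≥ 6 with **0** stem
mismatches: Monte-Carlo calibration on random 50-mers gives a 3.7%
false-positive rate at these settings, versus 48% if one mismatch is
allowed (both `stem_min` and `max_mismatch` are parameters; the calibration
lives in the test suite). `distance_to_3prime_terminus` counts bases from
the hairpin's 3′ edge to the element's end.

## Consensus

Center-star progressive alignment: the center is the sequence minimising
total pairwise alignment distance (for > 20 copies the scan is restricted to
the five longest — the center of a star radiation is a full-length copy),
all others are aligned to it pairwise and merged under "once a gap, always a
gap". Majority vote per column; columns with a strict gap majority are
dropped; base ties break A < C < G < T so the output is deterministic. The
consensus stays a plain DNA string (no ambiguity codes) because the 30 bp
end comparisons and the counting rules operate on strings. Sets smaller
than 10 copies still produce a consensus but are flagged low-support. When
more copies are available than needed, the top 200 by consensus coverage
then identity enter the alignment — a documented substitute for a selection
rule that is otherwise unstated. Validation: at d = 0.05 with 10 untruncated
copies the consensus equals the planted master in ≥ 95% of seeded trials
(measured 100%).

## Classification

The ≥ 80% pairwise relation is not transitive; each level (family by 5′
30 bp, subfamily by 3′ 30 bp, exemplar by internal region) is its
single-linkage closure — the minimal partition containing the relation.
Families are numbered by decreasing member count, subfamily letters and
exemplar letters by decreasing copy support, ties by discovery order, so
labels are deterministic and the partition itself is input-order invariant.
A consensus too short to expose a 3′ terminal block is assigned
"family-only". End and internal identities are global-alignment
matches/columns, which lets nested-insertion series share a subfamily while
separating as exemplars.

## Quantification

Copy counting and the divergence set follow the 80%/100 bp and 80%/80%-length
rules. Average percentage divergence is computed **copy-vs-consensus**
(consistent with near-zero values for recently amplified exemplars under a
star-radiation model); an all-pairs mode is available via
`phylo.distance_matrix`. Copies are aligned to the consensus with free end
gaps; end-gap columns are excluded, internal gaps excluded from K2P sites.
"Not determined" (ND) is returned when fewer than 3 copies qualify or
qualifying/counted < 5% — a concrete cutoff for the fragmentation situation
that is otherwise described only qualitatively. The family-only rule labels
copies whose alignment stays within the 5′ head shared between exemplars
(head length located as the first 30-column alignment window under 90%
identity).

## Synthetic data

The generator emulates the genomic situations the analysis assumes:

- i.i.d. background at configurable GC (default 0.40, a typical insect
  value); defaults of 2 × 200 kb contigs, 50 copies per element, element
  length 300 bp, d = 0.05, κ = 2.0.
- **Substitution process:** per-site independent K2P with
  transition:transversion rate ratio κ (default 2.0, a generic metazoan
  value; no empirical estimate was available to inherit), one mutation
  round per copy — a star phylogeny from the master, which makes average
  divergence directly interpretable as copy age.
- **Hallmark protection:** terminal motifs and the hairpin are exempt from
  mutation by default so structural validation is deterministic on
  untruncated copies. The rate on free sites is raised to compensate — the
  free-site distance is solved numerically so that the *whole-element*
  expected K2P estimate equals the nominal d (a linear rescaling leaves a
  −0.16 percentage-point bias at d = 0.15 because the K2P inverse is
  nonlinear in the substitution proportions). Measured bias of the
  generator/estimator pair: < 0.005 at d ∈ {0.01, 0.05, 0.15}.
- Copies insert between existing `A|T` dinucleotides (created as
  `A`+element+`T` only when none remain), on a random strand, never
  overlapping previous insertions; 3′ truncations remove a uniform suffix.
- **Capture series:** nested exemplars built by inserting random fragments;
  the source locus written into the genome shares exactly `junction_len`
  bp with the element on each side of the insertion point, and the bases
  beyond each junction are forced to mismatch so the planted microhomology
  is alignment-unambiguous (microhomology at an ambiguous boundary can
  slide between the two junctions, which is a property of the biology, not
  a detection error — the generator avoids planting that ambiguity).
- **Autonomous element:** a synthetic Rep/helicase protein carrying the
  bundled motif blocks, back-translated with two synonymous codons per
  amino acid chosen at random. The codon pool matters: a fixed codon table
  can leave a shifted or reverse-strand frame systematically stop-free,
  fabricating a spurious long ORF; random synonymous choice (including
  CTA/TTA/TCA, the reverse complements of stop codons) gives every
  non-coding frame its expected stop density.
- Empty sites are the joined 50 bp host flanks of a planted copy written
  elsewhere in the genome.

What passing on this generator does **not** show: behaviour under indels
(the mutation model is substitution-only; the aligner tolerates indels but
recovery rates under them are not benchmarked), nested TE insertions,
segmental duplications, low-complexity background, or assembly artefacts.
Genome-scale copy numbers from real assemblies additionally depend on
assembly completeness, which no simulation here addresses.

## Capture analysis and autonomy

Core inference aligns the consensus set with the *shortest* member as the
center; core columns are those occupied by every member (majority base),
requiring a common block ≥ 50 bp. Insertions are the runs of non-core
columns each member occupies, in its own coordinates. Junctions are
**maximal exact** matches between element and source flanks — the
microhomology concept admits no mismatches; lengths outside 2–13 bp are
reported but flagged, since that range is an empirical observation, not a
definition. When several genomic matches exist, the best alignment score
wins.

ORF reconstruction is majority vote over aligned copies: a frameshifting
deletion carried by a minority of rows is outvoted by the intact rows;
bases are only ever chosen among observed columns, never invented. The
longest ATG-initiated ORF on either strand must reach 1000 aa (the scale of
a Rep/helicase coding region), else "no autonomous partner". The motif scan
aligns bundled blocks (two-His initiator, two catalytic tyrosines, eight
SF1 helicase blocks) to the protein with BLOSUM62 and counts blocks at
≥ 50% exact identity over the block length; the bundled blocks are
synthetic stand-ins written for this package (see
`data/rep_hel_motifs_synthetic.fasta`) — they carry the canonical features
but are not copied from any published element, so motif positions are
meaningful relative to these blocks only. Shuffle-null calibration: 0 block
hits in 50 random 1100-aa proteins.

Empty-site detection searches the joined flanks (50 bp each side) at ≥ 90%
identity, allowing ≤ 2 extra bases at the junction, excluding the copy's
own locus; sites in the copy's own genome are labelled paralogous, in
another genome orthologous.

## Phylogenies

Distances: K2P or p-distance with pairwise gap deletion; saturated pairs
raise an error naming the pair. NJ follows the classical agglomeration
with two determinism guarantees: ties in the Q-criterion break by label
order, and negative branch lengths are clamped to zero with the deficit
moved to the sister branch. Bootstrap resamples alignment columns with
replacement (default 1000 replicates; pipelines use fewer where runtime
matters) and reports per-bipartition support for the tree built on the
original alignment. A > 50%-gap column filter is available for ragged
alignments. NJ is exact on additive matrices, verified against the
generating trees of random additive matrices up to 8 taxa.

## Pipeline

Stages communicate via files (FASTA/GFF3/TSV/Newick) in the output
directory so each stage is independently re-runnable; `manifest.json`
records the config hash, seed, package version and per-stage status.
Internal coordinates are 0-based half-open everywhere; all human-facing
output is 1-based inclusive, with strand written explicitly rather than by
descending coordinates. GFF3 parsing derives introns per transcript
(deduplicated per gene) and UTRs as exon-minus-CDS when not explicit.

## Problem sizes

The validation suite uses 2 Mb genomes with 500 planted copies for
copy-count recovery, 50 copies × 300 bp for divergence recovery,
12-element sets for classification, 3-step capture series, 1467-aa
autonomous elements, and ≤ 8-taxon trees against exhaustive oracles —
sizes at which every recovery check is exact or tightly toleranced while
the whole suite stays fast on a single CPU.
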