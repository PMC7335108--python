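# Methods

This note documents the models, parameter choices and numerical details
behind `hmolocus`, and what the synthetic benchmark does and does not
establish about real genome collections.

## Percent identity and homolog assignment

Family membership is decided by pairwise global protein alignment under a
fixed scoring: match +1, mismatch 0, linear gap −1 (Needleman–Wunsch, via
Biopython's `PairwiseAligner`). Percent identity is

    identity = 100 × identical columns / total alignment columns,

with gap columns in the denominator. The pair is canonicalised
(lexicographically ordered) before alignment, so the function is exactly
symmetric; where several alignments share the optimal score the aligner's
first traceback is used, which is deterministic.

Choices worth stating:

* **Protein-level search.** Family tokens name protein products and the
  synthetic generator controls protein identity directly, so one identity
  definition runs end-to-end. DNA-level search is out of scope.
* **No coverage threshold.** Assignment uses identity alone; a coverage
  cut-off would be a natural extension but is deliberately not applied by
  default.
* **Threshold semantics.** A gene hits family *F* iff its best identity
  against any reference of *F* is ≥ the threshold (default 70%). A gene
  may hit several families, at most once per family; ties between
  references go to the lexicographically smallest reference id.
* **Exact score prefilter.** For an optimal alignment with score *S* and
  *M* matches, identity = 2M/(l_a+l_b+M−S), which is increasing in
  M ≤ min(l_a, l_b). The resulting upper bound
  2·min(l_a,l_b)/(l_a+l_b+min(l_a,l_b)−S) is computed from a score-only
  pass; only pairs whose bound reaches the threshold get a traceback.
  This is a pure speed optimisation — the bound is exact, so no true hit
  is ever discarded.

## Locus rule and degrader categories

A locus is called per GH112 anchor in any genome that also carries ≥ 1
GH136 subunit **anywhere in the genome** — co-occurrence is a genome-level
predicate, not a window-level one. Window-level structure is assessed
separately by `signature_check`, which requires GH112, a GH136 subunit,
an ABC-transporter component (SBP or PP) and a transcriptional regulator
within the landscape. Categories: primary (GH112 ∧ GH136), secondary
(GH112 ∧ ¬GH136), none. Multiple GH112 paralogs each anchor a locus and a
landscape, but a genome contributes at most one count to any prevalence
cell.

## Landscapes

The window is the *n* genes before and after the anchor in coordinate
order on the anchor's contig (ties broken by gene id), truncated at contig
edges with explicit flags. The default *n* = 11 (23 tokens including the
anchor); *n* = 10 is equally reasonable and exposed as a parameter — both
are exercised in tests. Minus-strand anchors have the window reversed and
the truncation flags swapped, so upstream/downstream follow the anchor's
transcription direction and the extraction is invariant under mirroring
the contig (verified over 1000 random planted loci).

Tokenization precedence: family hit (GH112 beats any co-hit; otherwise
highest identity, ties to the alphabetically first family) → ordered,
case-insensitive keyword table on the product string ("solute binding" →
SBP, "permease" → PP, "regulator" → TransR, "histidine kinase" → HisK,
"hypothetical" → HP) → OTHER.

## OSA distance and ordination

Landscape similarity uses the optimal string alignment distance over gene
tokens (never concatenated characters, so multi-character tokens cannot
alias): unit-cost insertions, deletions, substitutions and adjacent
transpositions, no substring edited twice. The kernel is the standard
three-row dynamic programme, numba-compiled; the test suite checks it
exhaustively against an independent 0-1 BFS shortest-path oracle over all
pairs of strings of length ≤ 6 from a 4-token alphabet, including the
classic case where OSA(CA, ABC) = 3 exceeds the unrestricted
Damerau–Levenshtein value of 2. That case also shows OSA violates the
triangle inequality, which has two consequences here: triangle-based
pruning is never used, and classical scaling can produce negative
eigenvalues.

PCoA is classical scaling: B = −½·J·D²·J with J = I − 11ᵀ/n, symmetric
eigendecomposition, coordinates = eigenvectors × √eigenvalue. Negative
eigenvalues are clamped to zero and reported in the ordination object.
Eigenvector signs are fixed by making the largest-magnitude loading of
each axis positive, so runs are reproducible. On genuinely Euclidean
input the embedding reproduces all pairwise distances to < 1e-8
(verified against scikit-bio's implementation in the tests).

Comparisons include OTHER tokens by default (`include_other=False` drops
them), since both membership and position of the flanking genes carry
signal.

The per-SGB representative is the modal token string; ties break by
minimal mean OSA distance to the group, then lexicographically. The
representative is always a member of the group.

## Synthetic cohort generator

The generator emulates an SGB-binned collection of annotated genomes in
which some lineages carry the canonical locus:

* **Templates.** Two default locus templates mirror the canonical gene
  orders: `TransR SBP PP PP HP GH136_I GH136_II GH112 HisK` and the
  fucosidase-extended `... GH29 GH95 GH136_I GH136_II GH112 HisK`;
  SGBs alternate between them unless templates are given explicitly.
* **Study-condition defaults.** 5 SGBs × 24 genomes (120 total), planted
  identities uniform on [80, 95]%, 15% GH112-only genomes, 10% without a
  locus, rearrangement probability 0.3 per locus, 30 background genes per
  genome. The background count guarantees a full ±11 window on both sides
  of a mid-genome locus. The uniform identity distribution is a modelling
  choice — the real identity distribution of above-threshold hits is
  unknown.
* **Category counts are exact**: per SGB of size n, ⌊frac·n⌋ secondary
  and ⌊frac·n⌋ none, the remainder primary; the category list is then
  shuffled within the SGB by a seeded stream.
* **Identity control.** Planted genes are seeded random substitution
  mutants of the family reference, adjusted until measured identity is
  within ±3 points of the target (targets below the random-alignment
  identity floor are rejected). Substitution-only mutation means the
  planted alignment is essentially the diagonal, which is the regime the
  70% filter operates in.
* **References are synthetic**, generated from a fixed constant seed;
  they model the fixed external reference sequences of a real screen
  (three reference-genome labels, within-family references at ~85% mutual
  identity) and are identical in every run.
* **Background genes** are uniform-random proteins of length 150–400 with
  product "hypothetical protein"; their identity to any reference stays
  below 40% (checked empirically over 1000 genes), far under any
  realistic threshold.
* **Geometry.** One contig per genome, non-overlapping genes, 50 bp
  intergenic gaps, 1-based inclusive coordinates, gene length 3·protein+3.
  Locus strand is random per genome; on the − strand the genes are laid
  down in reverse contig order.
* **Rearrangement operator** applies at most one of: delete a non-anchor
  gene, insert an HP gene at a random position, swap two adjacent
  non-anchor genes.
* **Determinism.** One root seed; per-SGB and per-genome substreams are
  `SeedSequence(seed, spawn_key=(sgb, genome))`. Identical designs give
  byte-identical cohorts.

What passing on this benchmark shows — and does not. Perfect recovery on
planted cohorts establishes that the detection, classification,
windowing, orientation normalization and bookkeeping are internally
correct under the stated noise model. It does not establish performance
on real data, where identity distributions are not uniform, loci can
straddle contig breaks (multi-contig fragmentation is deliberately not
modelled), annotation vocabularies vary, paralog structure is richer, and
homologs near the threshold are common. The generator also does not model
phylogenetic correlation of identities within an SGB.

## Pipeline determinism and I/O

All stage outputs are plain text (GFF3, FASTA, TSV, JSON) and re-readable
by the package's own readers. Output ordering is fixed (sorted genomes,
stable sorts, sorted JSON keys) and the run manifest records parameters,
package version and SHA-256 digests of the inputs but no timestamps, so a
rerun with identical inputs and config is byte-identical. Gene tables are
validated on read (positive coordinates, start ≤ end, strand ∈ {+,−},
unique gene ids); TSV errors cite line numbers, GFF3 errors cite the
offending feature and file.

## Problem sizes

The shipped analyses and tests use cohorts of 16–1000 genomes (120 for
the headline recovery run). These sizes were chosen to make every result
cheaply reproducible on a laptop while keeping all counting rules exactly
as they would run at collection scale; nothing in the implementation is
specific to small cohorts (the homolog search is the only
super-linear-cost stage, and it is embarrassingly parallel across genes
if ever needed).
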