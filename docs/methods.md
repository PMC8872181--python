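# Methods

`mitorearr` analyses annotated vertebrate mitochondrial genomes with a focus
on gene-order rearrangement in squamate reptiles, where duplicated control
regions and translocated tRNAs arise repeatedly — including within a single
species. This note documents the models, conventions and numerical choices
behind each stage.

## Coordinate and naming conventions

Internally all features live on a 0-based, half-open, forward-strand
coordinate system. A feature spanning the origin of the circular molecule is
stored *unwrapped* (`end > genome length`, interpreted modulo the length), so
`end - start` is always the true span and no length arithmetic needs special
cases. GenBank flat files (1-based inclusive, origin-spanning `join()`
locations) are converted on input and output; the conversion is an involution,
which the round-trip tests assert field by field.

Gene names form a closed vocabulary: the 13 protein-coding genes (ND1-ND6,
ND4L, COX1-3, ATP6/8, CYTB), 22 tRNAs with the conventional isoacceptor split
(Leu1 = CUN, Leu2 = UUR, Ser1 = AGY, Ser2 = UCN), the two rRNAs (`rrnS`,
`rrnL`), the control region (`CR`) and the light-strand replication origin
(`OL`). A synonym table maps the common annotation dialects ("COI",
"D-loop", "tRNA-Ser (UCN)", "trnL2", ...) case-insensitively onto canonical
labels. Unknown names are never silently kept: on reading they go to a
skipped-features log (deposited annotations are frequently inconsistent,
and one of the genomes this package is modelled on had to be re-annotated
by its authors); the pipeline accepts a JSON annotation-patch file for such
corrections rather than guessing.

Duplicated genes get copy labels `a`, `b`, `c` in genome order starting from
position 0, mirroring the CR I/II/III numbering convention. Copy labels are
positional bookkeeping, not homology claims, so classification and TDRL
search ignore them.

## Composition and skew statistics

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), computed per region:
the whole genome (heavy strand) and the concatenated PCG, tRNA, rRNA and CR
features (each on its coding/feature strand). `N` bases are excluded from
every denominator; a zero denominator yields an explicit null, never 0.
Reports round percentages to 1 decimal and skews to 3, matching the precision
the field publishes at.

## Codon usage and RSCU

Codon statistics use the vertebrate mitochondrial genetic code (NCBI
translation table 2): AGA/AGG are termination codons, ATA is Met, TGA is
Trp. Each gene is read in frame from its annotated first codon. The terminal
complete stop codon and any trailing incomplete codon (`T--`/`TA-`,
completed by polyadenylation in vivo) are tabulated separately and excluded
from amino-acid totals, so the codon total is close to (coding length)/3
minus one stop per gene. Genes shorter than 6 bp are skipped with a warning.

RSCU for codon *c* in synonymous family *F* is `count(c) · |F| / Σ count(F)`.
Families are the amino acids of table 2 — notably a six-codon Leu family and
a six-codon Ser family, and a two-codon Met family (ATA/ATG) — which is the
convention of the widely used MEGA implementation this mirrors. The
Leu1/Leu2 and Ser1/Ser2 split is retained as a display label on codons
(reports print e.g. "UCA-Ser2") but does not partition the RSCU families.
An evenly used family has RSCU 1 for every member, and family RSCU sums
equal the family degeneracy whenever the family is observed; the tests
assert this on randomized genomes.

## Gene order, hotspot and classification

A gene order is the circular token list of a record, canonically rotated so
that 12S rRNA comes first. 12S is the anchor because it is single-copy in
every arrangement handled here, whereas tRNA-Phe (the natural linearization
point of a typical vertebrate mitogenome) is duplicated in some of them.

All rearrangement variation this package classifies is confined to the
*hotspot segment*: the run of tokens strictly between tRNA-Thr and 12S rRNA
(ancestrally tRNA-Pro — CR — tRNA-Phe). Classification matches the hotspot
labels plus the state of the Ile/Gln/Met tRNA cluster (ancestral IQM vs the
QIM state derived in agamids) against a registry of named types. The shipped
registry contains the three orders fully recoverable from published text:

| label   | I/Q/M | hotspot (tRNA-Thr → 12S) |
|---------|-------|---------------------------|
| typical | IQM   | P — CR — F                |
| V       | QIM   | CR — P — F — CR           |
| IX      | QIM   | CR — F — P — CR — F — CR  |

Additional types are supplied through a TSV registry file (bit-exact token
match, first matching entry wins, file order is the tie-break). Strand is
ignored in matching — none of the registered types involve inversions — but
recorded in the diagnostics, so a novel inverted order still surfaces as
"novel". Unmatched orders report their diagnostics rather than failing:
I/Q/M state, tRNA-Phe and CR copy counts, and a tRNA-Pro position class.
The position class is operationalized as: *absent* when tRNA-Pro or tRNA-Phe
is missing from the hotspot; *between-CRs* when both a CR and a tRNA-Phe
occur strictly before **and** strictly after tRNA-Pro (the triplicated-CR
configuration); otherwise *before-F*/*after-F* relative to the first
tRNA-Phe. One published description of the type V order says its tRNA-Pro
is "downstream" of tRNA-Phe while the printed order places it upstream; the
printed order is treated as authoritative throughout.

## The TDRL model

Tandem duplication/random loss events operate on the *linear* hotspot
segment between the fixed anchors, which bounds the combinatorics while
covering every described rearrangement. One event duplicates a contiguous
block `[i, j]` in tandem and deletes a loss set:

* **in-block losses** — any subset (including the empty set) of the 2·L copy
  positions created by the duplication, named `("orig"|"dup", offset)`.
  Empty loss sets are essential: they are how a retained extra tRNA-Phe or a
  supernumerary control region arises.
* **segment-level losses** — optional absolute indices outside the
  duplicated block, available to scenario files only. They exist because the
  published two-duplication pathway's final step deletes a tRNA-Phe copy
  created by the *earlier* duplication; restricting losses to the current
  block cannot express that step literally.

Essentiality: every gene name other than CR present before an event must
retain at least one copy afterwards; CR is freely gained and lost. Scenario
cost is the number of duplication events — losses are free, since the
narrative being modelled counts duplications and treats losses as their
random by-products.

### Minimal-scenario search

`search_min_scenarios` is a breadth-first search over event applications in
a fixed deterministic order (block start ascending, block end ascending,
loss mask as an ascending binary integer), bounded by `max_events`
(default 3) and `max_segment_length` (default 12, applied to every
post-event segment). Scenarios are deduplicated by their sequence of
intermediate states: distinct block/mask choices that produce identical
state sequences are one scenario. "Unreachable within the bound" is an
explicit result, not an error.

At every level but the last the search expands full event enumerations; at
the final level it decides one-step reachability per path with an exact
subsequence-embedding test (the target must factor as prefix +
subsequence-of-doubled-block + suffix for some block). Because the final
state of every minimal scenario is the target itself, this shortcut is
equivalent to enumerating final-step loss masks under the state-sequence
deduplication key; the representative final event is reconstructed from the
leftmost embedding. The test suite verifies the search against a naive
brute-force enumerator (no pruning, no deduplication) on every pair of
shipped hotspot orders and against replayed random 1-2-event histories.

Shipped scenario files `fig6_branch_a.json` / `fig6_branch_b.json` encode
the two-duplication pathway: duplicate P-CR-F, lose P(a); then duplicate
CR(b)-F(b) and either lose F(a), CR(b) and F(c) (branch A, giving the type V
hotspot) or lose F(c) only (branch B, giving type IX). Both branches
comprise 2 events, hence a 3-state trace. The search independently confirms
2 events is minimal for both targets (a single duplication of a one-CR
segment cannot yield three CR copies).

## Synthetic genomes

The generator builds a complete annotated mitogenome from the canonical
vertebrate gene order with a chosen hotspot arrangement substituted (and the
I/Q cluster swapped for QIM types), then lays features out left to right
with small uniform spacers (0-2 bp) and a fixed 13 bp ND5/ND6 overlap — the
longest overlap reported for the genomes this emulates. The light-strand
replication origin is omitted by default (`include_ol=True` restores it),
giving the typical arrangement 38 tokens: 37 genes plus one control region.

Background sequence is i.i.d. from configurable base frequencies; the
defaults (A 0.332, C 0.243, G 0.133, T 0.292) reproduce the reported
composition scale of these genomes — whole-genome A+T ≈ 62.4%, positive
AT-skew, GC-skew ≈ −0.29. On top of the background the generator stamps
what downstream statistics depend on: per-gene start codons (GTG for ATP8,
ND4L, ND6; ATG otherwise), stop codons (AGA for ND2/COX1, AGG for ND6,
incomplete `T--` for COX2/ATP6/COX3/ND3/CYTB, else TAA), the CSB1 motif
`CTTTTCATGCTCAGTAGACATA` verbatim in every control region, and
reverse-complemented content for ND6 and the eight light-strand tRNAs.
Default lengths: tRNAs 70 bp (22 × 70 ≈ the reported tRNA length totals),
rRNAs 867/1485 bp, protein genes ≈ 11.3 kb in total, control regions per
arrangement (893 / 892+334 / 893+804+417 bp), yielding genomes of ~16.2-17.5
kb — the size range of the real records.

A single seeded generator stream drives every random choice, so identical
specs produce byte-identical records. Each record ships with a truth
manifest (intended order, coordinates, parameters) that the round-trip tests
assert against.

What the generator does **not** emulate: codon bias beyond the enforced
start/stop codons (sequences are i.i.d., so RSCU tests on synthetic data
assert formula properties, not empirical codon rankings), tRNA secondary
structure, realistic substitution processes (`mutate_copy` is an
independent per-site uniform substitution, expected p-distance equal to the
rate), and within-genome regional heterogeneity. Passing tests therefore
demonstrate correctness of the statistics and of the order/TDRL machinery,
not biological realism of the sequence content.

## Pipeline

`analyze` runs every statistic per record, classifies each order, counts
distinct arrangement types across records, and searches minimal TDRL
scenarios from the ancestral hotspot to each observed hotspot (the natural
framing against the ancestral order; record-to-record search is available
behind a flag). Per-record failures are excluded with a reason rather than
aborting a multi-record run; the run fails only if every record fails.
Reports are JSON (machine surface, schema-versioned) plus TSV tables (human
surface); output is deterministic for fixed inputs.

p-distance is the uncorrected proportion of differing columns among columns
where both aligned sequences carry a non-gap, non-N base. The pipeline takes
pre-built alignments as input (alignment construction is out of scope); the
published intraspecific figure of ~1.5% corresponds to a concatenated
13-gene protein-coding alignment.

## Problem sizes and reproduction

`scripts/acceptance.py` regenerates every reported number from scratch at a
given seed: scenario validation on the 3-6 token hotspots, minimal-event
searches from the 3-token ancestral hotspot, classification of three
generated ~17 kb genomes (one type V, two type IX), the tRNA/CR census of a
type IX genome, and p-distance recovery from a 1.5%-mutated ~17.5 kb copy.
All stages complete in seconds; the search spaces involved (hotspots of at
most 6 tokens, at most 3 events) are exact enumerations, not samples.

## Known limitations

* Types VI-VIII and X of the agamid arrangement scheme are not shipped
  (their full orders are published only in figure form); the registry file
  format exists precisely so users can add them.
* The TDRL search treats each event as a single duplication; amplifications
  that copy a block more than once per event are out of scope.
* Inversions, transpositions and likelihood-based rearrangement models are
  not modelled.
* De novo annotation, alignment construction, phylogenetic inference and
  divergence dating are out of scope; the package consumes annotations and
  alignments produced elsewhere.
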