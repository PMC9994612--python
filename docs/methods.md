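# Methods

This note records the models and conventions behind `mitorder`: what each
stage computes, the parameters that matter, what the synthetic generator
does and does not emulate, and the numerical/design choices made where the
design was genuinely open.

## Coordinates and the circular genome

All coordinates are 1-based inclusive, the convention of published
mitogenome annotation tables.  Genomes are circular by default; the origin
lies between position *L* and position 1, and a feature with `end < start`
wraps the origin.  A feature's length is the number of circular positions
it covers (`end − start + 1`, adding *L* across the origin); this is
verified in the tests against brute-force position enumeration.

Published tables occasionally print a stated length that disagrees with
the coordinates (the bundled *S. wushanense* table prints 60 bp for trnL1
whose coordinates span 66 bp).  Coordinates win everywhere in this
package — coordinate arithmetic is self-consistent across the rest of the
table, including the printed category totals — and the validator surfaces
every such disagreement as a `length-mismatch` issue rather than silently
repairing it.  The same validator flags out-of-range coordinates and
protein-coding genes whose length is not a codon multiple yet carry no
truncated stop codon.

Spacers are computed between genomically **adjacent** features only
(`downstream.start − upstream.end − 1`, negative = overlap), matching the
single-column bookkeeping of published tables; a feature nested in another
is therefore counted once, against its neighbour.  The origin-spanning
pair is included, and can only overlap when the last feature itself wraps
the origin.  Intergenic totals count positive spacers and exclude the
unannotated stretch at the origin, mirroring how such tables leave the
first gene's intergenic cell empty.  The control region participates in
spacer accounting but carries no strand and is excluded from strand
tallies.

## Composition and codon statistics

Strand asymmetry is summarized as AT skew = (A−T)/(A+T) and GC skew =
(G−C)/(G+C).  Skews are scale-invariant (percentages, fractions and raw
counts give identical values) and undefined — reported as `None`, never a
number — when the denominator is zero.  Ambiguity codes count toward
sequence length but not toward base tallies.  Per-gene composition tables
profile genome-strand slices by default, so minus-strand genes show
sign-flipped skews, as in published per-gene tables; a strand-aware mode
reverse-complements minus-strand features first.

Codon statistics use the invertebrate mitochondrial genetic code
(translation table 5; configurable).  Stop codons are excluded from
counts; a truncated final codon of 1–2 nt is ignored for counting and
rendered as `T--`/`TA-` by the codon classifier, with a completeness flag
(such stops are completed to UAA by post-transcriptional polyadenylation).
An internal stop triggers a warning entry but counting continues.  RSCU is
computed over the code's full merged synonymous families — leucine has 6
members and serine 8 (AGA/AGG encode serine in this code); the two
isoacceptor subfamilies are not split, matching the convention of standard
codon-usage software.  Families with zero total get RSCU 0 and are
flagged.  Reported statistics are unrounded; fixture comparisons against
printed 3-decimal skews use an absolute tolerance of 0.0015, one rounding
unit of the printed 1-decimal percentages propagated through the skew
formula.

## Signed gene orders

A genome is abstracted as a circular sequence of signed gene symbols over
a closed 38-symbol vocabulary (unknown symbols fail fast; common synonyms
such as 12S/16S/D-loop are normalized).  Two orders describe the same
molecule when one is a rotation of the other or a reflection with all
orientations flipped (reading the other strand); every comparison works
modulo that equivalence.  The public canonical form anchors on cox1
(rotate to front; reflect first if cox1 is minus); an internal fallback
uses the lexicographically minimal rotation when cox1 is absent from a
restricted order.

*Breakpoint distance* counts signed adjacencies of one order absent from
the other, after restriction to the shared gene set; adjacency (x, y) is
identified with (−y, −x) so the distance is reading-independent.  It is a
pseudometric: symmetric, zero exactly on circularly equal orders, and
satisfying the triangle inequality (property-tested against random
orders).

*Pattern grouping* clusters orders with identical canonical forms after
restricting all inputs to their common gene set (configurable), so nearly
complete genomes — e.g. one missing tRNA — can join a pattern.  Groups are
labeled with roman numerals by descending size, ties broken by canonical
string, so the output is deterministic for a given input set.

*Displaced-block decomposition* finds the minimum number of blocks whose
excision from both orders leaves identical circular orders, where a block
must be a contiguous signed run in **both** orders.  The observed order is
first segmented at every adjacency absent from the reference
(common-synteny segments); each segment is by construction a common run,
and a union of segments across a broken adjacency is not, so the segments
are exactly the candidate blocks.  Subsets of segments are enumerated
exhaustively up to the block budget (default 4); beyond 18 segments a
documented greedy fallback removes smallest segments first.  Ties are
broken by fewest displaced genes, then lexicographically.  If no removal
within budget works the result says so explicitly (`budget_exceeded`)
rather than guessing.  A replay method re-inserts the blocks at their
observed positions and must reproduce the observed order; the tests
enforce this on every decomposition.

## Rearrangement events

Three mechanisms act on signed circular orders:

- **TDRL** (tandem duplication–random loss): a contiguous block is
  duplicated head-to-tail and one redundant copy of each gene is lost.
  With each gene assigned to copy 1 or copy 2, the survivors read as
  (copy-1 keepers in block order) then (copy-2 keepers in block order) —
  an interleaving of two order-preserving subsequences.  Orientations
  never change.  Consequently a span permutation is reachable by exactly
  one TDRL iff its source positions split into two increasing
  subsequences; this closure is checked exhaustively against a brute-force
  two-riffle enumerator for all span permutations up to length 6.
- **Inversion**: a block is reversed with all orientations flipped; the
  only orientation-changing event.
- **Translocation** (accepted synonym: transposition): a block is excised
  and re-inserted after a named destination gene, orientations preserved.
  Because "after X" depends on which strand the circle is read on, events
  record the destination gene's orientation, and application selects the
  matching reading — the same physical operation regardless of
  representation.

Event spans are named in one reading of the circle; `apply_event` is
reading-tolerant (it reflects, applies, and reflects back when the span is
phrased on the other strand).  A scenario is an ordered event list; its
verifier replays the events from the source and accepts only an exact
circular match, returning a diagnostic otherwise.

### Scenario inference

`infer_scenarios` returns **all** minimal-cost scenarios up to a depth cap
(default 3), deduplicated by their sequence of intermediate circular
orders; each step also records every single event realizing it.  Event
costs default to 1 per event with optional per-kind weights.

Single-event reachability is decided exactly rather than by enumeration:
the broken adjacencies between the two orders constrain where an event can
sit.  A TDRL or inversion confines its breaks to one span window, so
candidate spans are the windows (up to the span cap, default 8 genes)
covering every broken adjacency; a translocation's ≤ 3 breaks cut the
circle into arcs, and the moved span must be one whole arc.  Every
candidate is applied and checked, and for TDRLs every valid riffle cut is
reported, so within the span cap the test suite can hold this equivalent
to brute force.  Multi-event search grows successor states breadth-first
(deduplicated by canonical form) and uses the exact single-event test as
the goal check at the last level.  On full 38-gene orders a depth-2 search
takes on the order of a second; depth 3 is exhaustive only for small
orders and is impractical on full-size genomes — restrict the event kinds
or the span cap there.  The span cap also bounds the TDRL assignment
blow-up (2^span per span); 8 genes covers every mechanism discussed for
these genomes except the 11-gene TDRL of the derivation example, which is
applied and verified directly rather than searched for.

## The synthetic generator

The generator produces the inputs the analysis assumes, with known ground
truth, and nothing more:

- **Histories** start from the pancrustacean ground pattern and apply *k*
  events (default 2) sampled by kind weights with uniform valid
  parameters: TDRL spans of 2–6 genes with a uniform nontrivial copy
  assignment, inversion/translocation spans of 1–6 genes, uniform
  destinations excluding the no-op slot.  Spans are kept in the range
  observed for real mitogenome rearrangements and within the inference
  span cap, so simulated histories are recoverable in principle.
- **Genomes** draw per-category lengths (PCGs near their typical crab
  lengths, jittered in codon multiples; tRNAs 60–75 bp; rRNAs ~0.8/1.3 kb;
  CR 0.7–1.3 kb), place genes with geometric spacers (mean 35 bp) and,
  with probability 0.15, overlaps of 1–47 bp — 47 bp being the largest
  overlap in the bundled genomes — yielding ~16–18 kb circles.
- **Sequence** targets the genome-strand base composition
  A/T/G/C = 0.355/0.381/0.090/0.175 (the whole-genome composition of the
  bundled complete genome) everywhere: background and RNA/CR features are
  i.i.d. draws; PCG bodies are codon draws on the coding strand from a
  weight table.  The default table is derived from the composition target
  with a fixed-point correction so that the marginal of sense-codon draws
  (stops excluded) reproduces the target exactly; minus-strand genes use
  the mirrored target so their genome-strand slices match too.  PCGs get
  weighted ATN starts and TAA/TAG stops.  One seeded generator drives all
  draws in a fixed order (history, lengths, placement, sequence), so
  identical configs give identical outputs.

Where features overlap, the later-stamped feature wins the shared bases
(PCGs are stamped last), so an overlapped RNA gene's sequence is partly
coding; annotation metadata remains self-consistent and the validator
stays clean, but sequence-level codon classification of overlapped genes
is only guaranteed with overlaps disabled.

What passing tests on synthetic data do **not** show: real mitogenomes
have position-dependent composition, secondary-structure constraints in
RNAs, replication-driven skew gradients and repeat-laden control regions;
none of these are emulated, because no stage under test consumes them.

### Sampling tolerances

Codon-wise drawing correlates the three bases within a triplet, so the
single-genome standard error of a base fraction is ≈ 0.006 (not the
i.i.d. 0.0037) and of AT skew ≈ 0.013 at 17 kb.  Recovery tests therefore
check the mean over ten seeded genomes at four standard errors of that
estimator (base fractions ±0.0075, AT skew ±0.017), and the fixed-seed
single-genome unit test uses the single-draw 4-SE bounds.  The RSCU
uniformity check likewise bounds the worst of 62 codons at ~3.5 SE of the
family-ratio estimator.  All bounds were derived from the sampling
distributions before the tests were frozen.

## Known limitations

- Scenario search beyond depth 2 on full-size (38-gene) orders is
  exponential; it is intended for restricted kinds, small orders, or
  verification of user-supplied scenarios.
- Tandem duplication–non-random loss and recombination are not inference
  mechanisms; histories using them can only be expressed as user-supplied
  scenarios for the verifier.
- The displaced-block search is exact over common-synteny segments, which
  covers every difference explainable by relocating internally intact
  blocks; adversarial cases where a *partial* segment removal would do
  better are not explored.
- No ancestral-order reconstruction over a phylogeny: comparisons are
  pairwise or against a fixed reference.
- The GenBank writer emits minimal records (no references or taxonomy
  lineage) with a fixed date stamp so outputs are reproducible.
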