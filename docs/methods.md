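# Methods

## Model

svforge models a structural variant as a rewrite of contiguous reference
intervals. A rearrangement rule `SRC→TGT` names reference intervals with
uppercase letters on the source side; the target side describes the alternate
allele as a sequence of those letters (possibly inverted, duplicated,
reordered, or dropped), dispersion intervals (`_`) that separate distant
loci, and novel letters (insertions). A simulation configuration is a list of
SV categories, each the 4-tuple (type, breakend-distance ranges, placement
constraints, count), plus global parameters (reference, ROI/blacklist BED
files, minimum inter-SV distance, cross-haplotype overlap flag, seed).

Simulation proceeds in three stages: (1) instantiate each category's n SVs by
sampling every symbol's length uniformly from its range (or deriving it from
another symbol's sampled length) and drawing zygosity per SV; (2) assign
reference coordinates to every breakend, uniformly over the positions
satisfying the constraints, rejecting overlaps and minimum-distance
violations; (3) edit the reference into the two haplotypes, tracking block
provenance.

## Operation derivation

Parsing a rule yields tokens with identity, orientation, dispersion segment
(number of dispersions to the token's left — segments are positionally
matched between the two sides), multiplicity (`+`), and anchor membership
(`()`). Deriving edit operations requires deciding which target occurrence of
each letter is the *in-place* one. svforge selects a maximum-length chain of
target tokens with strictly increasing source order whose dispersion segment
matches the letter's source segment, tie-broken toward the leftmost target
positions. Consequences that match the intended readings of the worked
expressions: in `ABC→ACB` the chain is A,C so B is the translocated letter
(CUT_PASTE); in `ABC→AABCC` each duplicated letter keeps one in-place copy
(IDENTITY) plus adjacent TANDEM_COPYs; in `A_→A_A` the second A sits in a
different segment, hence DISPERSED_COPY. Letters absent from the target
become DELETE; target letters absent from the source become NOVEL_INSERT.
A copy is TANDEM only when it lies in the contiguous same-letter run around
the in-place occurrence within the same segment; all cross-segment copies are
DISPERSED even when the letter also appears in place. Every target token maps
to exactly one operation and every source letter is consumed exactly once —
this completeness property is enforced by an exhaustive enumeration test
(all rules with ≤3 source letters and ≤4–5 target tokens) against both a
set-arithmetic classifier and a direct string-rewrite oracle.

## Placement

Categories are expanded to SV instances up front (lengths, copy counts, novel
sequences, zygosity), then placed greedily, most restrictive first: fixed
(VCF-imported), exact, partial, containing, contained,
terminal/whole-chromosome, then blacklist-only and unconstrained. Ties break
by descending SV span, then stable input order. Terminal and whole-chromosome
SVs are slotted between contained and unconstrained: they constrain few
coordinates but cannot be satisfied late on a crowded chromosome.

Candidate generation is mode-specific rather than genome-wide rejection:
ROI-bound modes enumerate admissible ROIs (by label and feasible length) and
sample positions within the chosen ROI directly; unconstrained and
blacklist-only modes sample genome-wide, weighting chromosomes by the number
of feasible start positions. Exact and whole-chromosome modes refit the
anchored symbols' lengths (each kept within its configured range) so their
sum equals the ROI or chromosome length. Every candidate must then clear:
interval overlap against already-committed SV footprints (per haplotype;
both haplotypes are booked unless cross-haplotype overlap is enabled),
breakend-to-breakend minimum distance against all previously placed
breakends (applied across haplotypes regardless of the overlap flag — the
overlap flag is scoped to overlap only), and blacklist membership (a breakend
is "inside" an ROI only strictly between its bounds, so boundary-coincident
breakends — e.g. exact-mode placements — do not count as violations).
Placement failure after `max_placement_attempts` candidates (default 100;
a bounded rejection sampler needs a cap) raises an error naming the SV, its
category, and the binding constraint; an exact constraint with no
length-compatible ROI is diagnosed before any sampling.

Inter-chromosomal dispersions are supported for rules with exactly one
dispersion: the pre-dispersion segment is placed normally and the
post-dispersion segment lands at a uniformly drawn position on a uniformly
drawn other chromosome. "Partial" requires exactly one anchored breakend
strictly inside the ROI. Homozygous SVs occupy identical coordinates on both
haplotypes (single placement, double booking); heterozygous SVs take one
haplotype uniformly. The homozygosity probability defaults to 0.5.

Tandem-repeat events act on ROIs whose BED label encodes the motif
(`TR_<motif>`): an expansion inserts k extra motif copies at the locus, a
contraction deletes k copies and fails when k exceeds the copies present;
k is drawn from the category's `copy_delta` range. SNPs are placed through
the same machinery as 1 bp events, with the alternate base drawn uniformly
from the three non-reference bases after the site is fixed.

## Haplotype synthesis and outputs

Each haplotype is built per chromosome by a single left-to-right walk:
deleted (and cut) intervals are skipped, inverted intervals emit minus-strand
blocks, and copies/novel sequences are inserted at their resolved target
points (at a shared point, insertions order deterministically by SV id and
target slot, before any interval edit starting there). The resulting block
list — (haplotype interval, reference interval or novel, strand, SV id) —
tiles the haplotype exactly and is serialized as PAF (one line per
reference-origin block; novel blocks are omitted by default since PAF models
query→target homology). Coordinates are 0-based half-open internally, BED is
read natively, and conversion to 1-based happens only at VCF emission.

The VCF uses symbolic ALTs with a pad-base POS, one record per atomic
operation; multi-breakpoint SVs are linked by `PARENT_SVID` and annotated
with the rule string, symbol, and operation. Insertion-like records carry the
0-based insertion point (`TPOS`), the copied source interval and strand
(`SRC`, `SRC_STRAND`), copy count (`NCOPIES`), or the literal inserted
sequence (`INSSEQ`). CUT_PASTE is a single `<INS>` record whose `SRC`
interval implies the source deletion. This makes the VCF self-contained: the
test suite's replay oracle — a deliberately naive string editor that applies
records to mutable per-chromosome strings in descending coordinate order,
fetching copy content from the original reference — reconstructs both
haplotypes byte-for-byte, independently of the assembly bookkeeping.

All randomness flows from one `numpy.random.Generator` seeded by the config
(CLI `--seed` overrides), and every processing order is deterministic, so
identical config bytes and seed give byte-identical outputs.

## Synthetic data generator

The fixture generator emulates the placement-relevant structure of an
annotated reference: i.i.d. bases at a configurable GC fraction (default
0.41, a genome-wide human-like value), non-overlapping labelled ROI tracks
laid out with random gaps, and tandem-repeat loci whose sequence is the
literal motif array. The bundled repeat-context deletion scenario uses a
10 Mb single chromosome with a LINE-1-like track (intervals of 1–8 kbp, so
exact-boundary placement is feasible for 1–10 kbp deletions) and a shorter
satellite-like track (200–900 bp, so deletions can contain them), 1.2× as
many intervals per track as deletions, and a 1 kbp minimum inter-SV
distance; the deletion count is 500 at full scale and is reduced only in
fast-running unit tests. What the fixtures do **not** emulate: real repeat
sequence content (the "L1HS" intervals are random sequence, not LINE-1
consensus), mappability structure, GC heterogeneity, and chromosome-scale
features — so passing tests demonstrate correct constraint handling and
sequence editing, not caller behaviour on real repeats; read simulation and
alignment are out of scope.

## Numerical and design choices

- Lengths are drawn on closed integer ranges `[min, max]`; derived lengths
  (`k*length(X)`) round to the nearest integer with a 1 bp floor; derivation
  graphs must be acyclic (validated at load).
- Exact/whole-chromosome length refitting assigns each symbol its minimum and
  distributes the remainder left to right, keeping every symbol in range.
- Edits are applied via a coordinate-sorted walk, so earlier edits never
  invalidate later coordinates; the replay oracle instead applies edits in
  descending coordinate order — two independent routes to the same sequence.
- The `+` copy count is drawn once per operation instance, independently per
  `+`-marked token.
- Empty-parenthesis anchors denote a single breakend; for span modes
  (exact/contained/containing) an empty anchor falls back to the whole SV
  span, since a zero-width span cannot satisfy them.
- The 26-type registry completes the symmetric variants of the documented
  class families (e.g. both `A→Aa` and `A→aA` inverted-duplication forms,
  intra- and inter-chromosomal reciprocal translocation) to reach the
  catalogue size.
- VCF import supports per-record operations (DEL, INV, DUP, INS, SNP, or a
  grammar-annotated record); imported SVs are placed first, verbatim, and
  bypass constraint checks.

## Problem sizes

The test suite runs entirely on generated fixtures: toy 10 bp sequences for
splice-level checks, 20–100 kb genomes for randomized oracle-equivalence
sweeps (100 genomes, ≤20 SVs each, cycling through every registry type),
a 5 Mb two-chromosome reference for the 1,000-SV constraint audit, and the
10 Mb scenario for the 500-deletion run. These sizes were chosen as the
smallest that exercise every constraint regime with realistic SV densities.

## Known limitations

- Ploidy is fixed at 2; no somatic copy-number amplification beyond
  grammar-expressible duplications; no BND breakend notation.
- Inter-chromosomal rules are limited to a single dispersion, and a
  ROI-anchored constraint on such a rule must bind the pre-dispersion
  segment.
- No nested parentheses, multi-character symbols, or arithmetic in rules.
- The greedy placement heuristic can fail on near-saturated references where
  a global optimizer would succeed; failures are explicit, never silent.
- No per-chromosome count quotas or GC-conditioned placement.
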