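# svforge

Grammar-based structural variant (SV) simulation: given a reference genome
and a YAML configuration, svforge generates a synthetic **diploid** genome
containing user-specified simple, complex, and fully custom SVs, with
fine-grained control over SV sizes and genomic placement. It emits the two
haplotype FASTAs, a linked truthset VCF, per-haplotype PAF liftover files,
and a statistics summary — everything needed to benchmark SV callers, study
aligner behaviour near breakpoints, or train learning-based SV detectors on
balanced, fully-labelled data.

## The rearrangement grammar

Each SV category is the 4-tuple *(t, D, C, n)*: an SV type *t*, breakend
distance ranges *D*, optional placement constraints *C*, and a count *n*.
The type is either one of **26 predefined classes** (`DEL`, `INV`, `dDUP`,
`delINVdel`, `dupINVdup`, tandem-repeat expansions/contractions, SNPs, …)
or a rearrangement expression mapping reference intervals to the alternate
allele structure:

| expression | meaning |
|---|---|
| `ABC→AC` | deletion of B |
| `A→a` | inversion (lowercase = reverse complement) |
| `ABC→AABCC` | tandem duplication of A and C |
| `ABC→ACB` | translocation of B |
| `A_→A_A` | dispersed duplication across the `_` dispersion interval |
| `A→AB` | novel insertion (letters only on the right) |
| `A→AA+` | variable copy number, drawn from a configured range |
| `A(B)C→b` | `()` anchors B for placement constraints |

Placement constraints tie anchored breakends to labelled regions of
interest (BED): **partial** (exactly one breakend inside an ROI), **exact**
(breakends coincide with ROI boundaries), **contained** (SV inside the ROI),
**containing** (ROI inside the SV), **terminal**, **whole_chromosome**, and
**blacklist** (no breakend may fall in the ROI set), plus a global minimum
inter-SV breakend distance. Placement is greedy, most restrictive first:
VCF-imported fixed SVs, then exact, partial, containing, contained, and
unconstrained categories.

## Worked example

```bash
svforge list-types            # 26 predefined classes with their rules
python examples/03_context_aware_placement.py
```

prints

```
blacklist        placed=40 audit_violations=0
exact_L1HS       placed=40 audit_violations=0
containing_ALR   placed=40 audit_violations=0
```

i.e. the same 40-deletion category placed in three genomic contexts on a
synthetic reference with LINE-1-like and satellite-like ROI tracks —
breakends excluded from all repeats, breakends exactly at L1HS boundaries,
and deletions spanning an ALR interval — and an independent coordinate-level
audit confirms every placement satisfies its declared constraint.

A minimal end-to-end run from Python:

```python
from svforge import run_simulation
result = run_simulation("config.yaml", "out/", seed=7)
```

with a config such as

```yaml
reference: ref.fa
overlap_regions: [repeats.bed]
min_intersv_dist: 1000
variant_sets:
  - type: DEL
    number: 500
    length: [1000, 10000]
  - type: AB_C→b_AA          # custom complex SV, sizes per symbol
    number: 10
    length_ranges: {A: [200, 400], B: [300, 300], C: [100, 200], _1: [2000, 5000]}
```

Outputs: `sim.hapA.fa` / `sim.hapB.fa` (haplotypes, contigs suffixed
`_hapA`/`_hapB`), `sim.vcf` (one record per atomic operation; records of a
multi-breakpoint SV share `PARENT_SVID` and carry the grammar string, symbol
and operation), `sim.hapA.paf` / `sim.hapB.paf` (block-level correspondence
between haplotype and reference, usable for coordinate liftover), and
`sim.stats.tsv` (per-type counts/sizes and per-chromosome length deltas).
Identical config and seed reproduce every output byte-for-byte.

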