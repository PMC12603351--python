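"""Define a custom rearrangement with the SV grammar and simulate it.

The rule "AB_C→b_AA" deletes C, inverts B in place, moves A past the
dispersion and tandem-duplicates it there — a bespoke complex SV with no
standard name. The printed operations are what the simulator will apply;
the VCF records share one PARENT_SVID and carry the rule string.
"""

import os
import tempfile

from svforge.grammar import derive_operations, parse_rule
from svforge.fixtures import FixtureSpec, make_reference
from svforge.simulate import run_simulation

rule = parse_rule("AB_C→b_AA")
print("canonical rule:", rule.canonical_string)
for op in derive_operations(rule):
    print(f"  {op.kind.value:<15} symbol={op.source_symbol or op.novel_letter}"
          f" slot={op.target_slot} inverted={op.inverted}")

with tempfile.TemporaryDirectory() as work:
    make_reference(FixtureSpec(chromosomes=(("chr1", 200_000),), seed=2), work)
    config = os.path.join(work, "config.yaml")
    with open(config, "w") as fh:
        fh.write(
            "reference: ref.fa\n"
            "random_seed: 9\n"
            "variant_sets:\n"
            "  - type: AB_C→b_AA\n"
            "    number: 1\n"
            "    length_ranges: {A: [200, 400], B: [300, 300], "
            "C: [100, 200], _1: [2000, 5000]}\n"
        )
    result = run_simulation(config, os.path.join(work, "out"))
    with open(result.paths["vcf"]) as fh:
        for line in fh:
            if not line.startswith("#"):
                print(line.rstrip()[:140], "...")
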