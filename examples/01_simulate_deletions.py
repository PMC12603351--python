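"""Simulate a diploid genome with 50 deletions and inspect the truthset.

Builds a 1 Mb synthetic reference, places 50 deletions of 1-10 kbp at least
1 kbp apart, and prints the per-type statistics. The chromosome length delta
equals the summed deleted bases on each haplotype.
"""

import os
import tempfile

from svforge.fixtures import FixtureSpec, make_reference
from svforge.simulate import run_simulation

with tempfile.TemporaryDirectory() as work:
    make_reference(FixtureSpec(chromosomes=(("chr1", 1_000_000),), seed=1), work)
    config = os.path.join(work, "config.yaml")
    with open(config, "w") as fh:
        fh.write(
            "reference: ref.fa\n"
            "min_intersv_dist: 1000\n"
            "random_seed: 4\n"
            "variant_sets:\n"
            "  - type: DEL\n"
            "    number: 50\n"
            "    length: [1000, 10000]\n"
        )
    result = run_simulation(config, os.path.join(work, "out"))
    print(f"placed {len(result.placed)} SVs; outputs: {sorted(result.paths)}")
    print(open(result.paths["stats"]).read())
    print("hapA/hapB lengths:",
          len(result.sequences[0]["chr1_hapA"]),
          len(result.sequences[1]["chr1_hapB"]))
    # Each haplotype is shorter than 1 Mb by exactly the bases deleted on it.
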