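"""Use the PAF files to lift synthetic-haplotype coordinates to the reference.

Simulates one inversion, then maps haplotype positions back through the PAF:
plus-strand blocks map linearly, the inverted block maps with orientation
flipped, so the lifted reference base is the complement of the haplotype
base inside the inversion.
"""

import os
import tempfile

from svforge.fixtures import FixtureSpec, make_reference
from svforge.reference import Reference
from svforge.simulate import run_simulation
from svforge.synthesis import reverse_complement

with tempfile.TemporaryDirectory() as work:
    fixture = make_reference(
        FixtureSpec(chromosomes=(("chr1", 100_000),), seed=3), work
    )
    config = os.path.join(work, "config.yaml")
    with open(config, "w") as fh:
        fh.write(
            "reference: ref.fa\nrandom_seed: 6\n"
            "variant_sets:\n"
            "  - {type: INV, number: 1, length: [5000, 5000], "
            "homozygous_prob: 1.0}\n"
        )
    result = run_simulation(config, os.path.join(work, "out"))
    reference = Reference(fixture["fasta"])
    hap = result.sequences[0]["chr1_hapA"]
    for line in open(result.paths["hapA_paf"]):
        f = line.rstrip("\n").split("\t")
        qs, qe, strand, ts, te = int(f[2]), int(f[3]), f[4], int(f[7]), int(f[8])
        q = (qs + qe) // 2  # midpoint of the block
        t = ts + (q - qs) if strand == "+" else te - 1 - (q - qs)
        ref_base = reference.fetch("chr1", t, t + 1)
        shown = ref_base if strand == "+" else reverse_complement(ref_base)
        status = "match" if shown == hap[q] else "MISMATCH"
        print(f"block {qs}-{qe} strand {strand}: hap[{q}]={hap[q]} "
              f"lifts to ref[{t}]={ref_base} -> {status}")
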