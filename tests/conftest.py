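import os

import numpy as np
import pytest
import yaml
from hypothesis import settings

from svforge.grammar import OpKind, parse_rule, derive_operations
from svforge.placement import PlacedSV, resolve_layout
from svforge.reference import Reference

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.asarray(list(BASES))[rng.integers(0, 4, size=length)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(sequences: dict[str, str], name: str = "ref.fa") -> str:
        path = tmp_path / name
        with open(path, "w") as fh:
            for contig, seq in sequences.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        return str(path)

    return _write


@pytest.fixture
def make_config(tmp_path):
    """Write a YAML config next to its reference and return its path."""

    def _make(reference_path: str, variant_sets: list, name="config.yaml",
              **global_params) -> str:
        cfg = {
            "reference": os.path.relpath(reference_path, tmp_path),
            "variant_sets": variant_sets,
        }
        cfg.update(global_params)
        path = tmp_path / name
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh)
        return str(path)

    return _make


def manual_sv(
    rule_string: str,
    lengths: dict[str, int],
    chrom: str,
    start: int,
    reference: Reference,
    copy_counts: dict[int, int] | None = None,
    novel_seqs: dict[int, str] | None = None,
    haplotypes=(0, 1),
    sv_id: str = "sv0",
) -> PlacedSV:
    """Place a rule at fixed coordinates, bypassing the sampling machinery."""
    rule = parse_rule(rule_string)
    sv = PlacedSV(
        sv_id=sv_id,
        sv_type=rule_string,
        rule=rule,
        category_index=0,
        haplotypes=tuple(haplotypes),
        lengths=dict(lengths),
        copy_counts=dict(copy_counts or {}),
        novel_seqs=dict(novel_seqs or {}),
    )
    for op in derive_operations(rule):
        if op.kind is OpKind.NOVEL_INSERT and op.target_slot not in sv.novel_seqs:
            raise AssertionError(
                f"manual_sv: provide novel_seqs[{op.target_slot}] for {rule_string}"
            )
    return resolve_layout(sv, chrom, start, reference)
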