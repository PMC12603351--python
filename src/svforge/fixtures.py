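"""Synthetic references, ROI BEDs and configs for self-contained runs.

The generator writes a random reference genome with planted, labeled ROI
tracks (repeat-family analogues, tandem-repeat loci with known motifs) so
every simulation scenario — including the scaled-down repeat-context case
study — runs without any downloads. All outputs are reproducible from the
fixture spec and its seed alone.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .emitters import write_fasta
from .errors import FixtureError
from .regions import ROI

__all__ = ["ROIPlan", "RepeatPlan", "FixtureSpec", "make_reference",
           "case_study_configs"]

_BASES = np.asarray(list("ACGT"))


@dataclass(frozen=True)
class ROIPlan:
    label: str
    count: int
    length_range: tuple[int, int]


@dataclass(frozen=True)
class RepeatPlan:
    """Tandem-repeat loci: the reference holds ``copies`` of ``motif`` and the
    BED label encodes the motif as ``TR_<motif>``."""

    motif: str
    count: int
    copies_range: tuple[int, int]

    @property
    def label(self) -> str:
        return f"TR_{self.motif}"


@dataclass(frozen=True)
class FixtureSpec:
    chromosomes: tuple[tuple[str, int], ...]
    gc: float = 0.41
    roi_plan: tuple[ROIPlan, ...] = ()
    repeat_plan: tuple[RepeatPlan, ...] = ()
    gap_range: tuple[int, int] = (1000, 4000)
    seed: int = 0


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def make_reference(spec: FixtureSpec, out_dir: str) -> dict[str, object]:
    """Write ``ref.fa`` plus one BED per ROI label (and a combined
    ``rois.bed``); deterministic given the spec's seed.

    Planned intervals are laid out left to right with random gaps drawn from
    ``gap_range``; an infeasible plan raises before any file is written.
    """
    rng = np.random.default_rng(spec.seed)
    items: list[tuple[str, int, Optional[str]]] = []  # (label, length, seq)
    for plan in spec.roi_plan:
        lo, hi = plan.length_range
        for length in rng.integers(lo, hi + 1, size=plan.count):
            items.append((plan.label, int(length), None))
    for plan in spec.repeat_plan:
        lo, hi = plan.copies_range
        for copies in rng.integers(lo, hi + 1, size=plan.count):
            seq = plan.motif * int(copies)
            items.append((plan.label, len(seq), seq))
    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    # dry-run layout so infeasibility surfaces before any file is written
    rois: list[ROI] = []
    overrides: list[tuple[str, int, str]] = []
    queue = list(items)
    for chrom, clen in spec.chromosomes:
        pos = int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
        while queue:
            label, length, seq = queue[0]
            gap = int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
            if pos + length + gap > clen:
                break
            rois.append(ROI(chrom, pos, pos + length, label))
            if seq is not None:
                overrides.append((chrom, pos, seq))
            pos += length + gap
            queue.pop(0)
    if queue:
        raise FixtureError(
            f"ROI plan infeasible: {len(queue)} of {len(items)} planned "
            "intervals do not fit in the chromosomes"
        )

    os.makedirs(out_dir, exist_ok=True)
    sequences: dict[str, str] = {}
    for chrom, clen in spec.chromosomes:
        codes = _random_sequence(clen, spec.gc, rng)
        seq = np.asarray(list("ACGT"))[codes]
        sequences[chrom] = "".join(seq)
    for chrom, pos, seq in overrides:
        s = sequences[chrom]
        sequences[chrom] = s[:pos] + seq + s[pos + len(seq):]

    fasta_path = os.path.join(out_dir, "ref.fa")
    write_fasta(sequences, fasta_path)
    bed_paths: dict[str, str] = {}
    labels = sorted({r.label for r in rois})
    for label in labels:
        path = os.path.join(out_dir, f"{label}.bed")
        with open(path, "w") as fh:
            for r in sorted(
                (r for r in rois if r.label == label),
                key=lambda r: (r.chrom, r.start),
            ):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")
        bed_paths[label] = path
    combined = os.path.join(out_dir, "rois.bed")
    with open(combined, "w") as fh:
        for r in sorted(rois, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")
    return {
        "fasta": fasta_path,
        "beds": bed_paths,
        "combined_bed": combined,
        "rois": rois,
        "sequences": sequences,
    }


_CASE_STUDY_YAML = """\
reference: ref.fa
overlap_regions: [rois.bed]
min_intersv_dist: {min_dist}
random_seed: {seed}
max_placement_attempts: 200
variant_sets:
  - type: DEL
    number: {n}
    length: [{lmin}, {lmax}]
    overlap_mode: {mode}
{label_line}"""


def case_study_configs(
    out_dir: str,
    seed: int = 0,
    n_dels: int = 500,
    chrom_length: int = 10_000_000,
    length_range: tuple[int, int] = (1000, 10_000),
    min_dist: int = 1000,
) -> dict[str, str]:
    """Build the repeat-context deletion scenario on a synthetic reference.

    A single-chromosome reference carries a LINE-1-like track ("L1HS", sized
    so exact-boundary placement is feasible for the deletion length range)
    and a shorter satellite-like track ("ALR"). Three configs place the same
    deletion category (i) with both breakends outside all ROIs (blacklist
    mode), (ii) exactly at L1HS interval boundaries (exact mode), and
    (iii) containing an ALR interval (containing mode), each with the given
    minimum inter-SV distance.
    """
    spec = FixtureSpec(
        chromosomes=(("chr1", chrom_length),),
        gc=0.41,
        roi_plan=(
            ROIPlan("L1HS", max(120, int(n_dels * 1.2)), (1000, 8000)),
            ROIPlan("ALR", max(120, int(n_dels * 1.2)), (200, 900)),
        ),
        gap_range=(min_dist, 4 * min_dist),
        seed=seed,
    )
    fixture = make_reference(spec, out_dir)
    configs: dict[str, str] = {}
    recipes = {
        "blacklist": ("blacklist", None),
        "exact_L1HS": ("exact", "L1HS"),
        "containing_ALR": ("containing", "ALR"),
    }
    for name, (mode, label) in recipes.items():
        label_line = (
            f"    overlap_region_type: [{label}]\n" if label is not None else ""
        )
        text = _CASE_STUDY_YAML.format(
            min_dist=min_dist,
            seed=seed + 1,
            n=n_dels,
            lmin=length_range[0],
            lmax=length_range[1],
            mode=mode,
            label_line=label_line,
        )
        path = os.path.join(out_dir, f"config_{name}.yaml")
        with open(path, "w") as fh:
            fh.write(text)
        configs[name] = path
    configs["fixture_fasta"] = fixture["fasta"]
    configs["combined_bed"] = fixture["combined_bed"]
    return configs
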