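"""End-to-end simulation: config → placed SVs → haplotypes → truthset files."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import GlobalParams, SVCategory, load_config
from .emitters import write_fasta, write_paf, write_stats, write_vcf
from .library import import_vcf_svs
from .placement import PlacedSV, place_all
from .reference import Reference
from .regions import ROISet, read_bed
from .synthesis import HaplotypeAssembly, build_haplotype

__all__ = ["SimulationResult", "run_simulation"]


@dataclass
class SimulationResult:
    params: GlobalParams
    categories: list[SVCategory]
    placed: list[PlacedSV]
    sequences: tuple[dict[str, str], dict[str, str]]
    assemblies: tuple[HaplotypeAssembly, HaplotypeAssembly]
    paths: dict[str, str] = field(default_factory=dict)


def run_simulation(
    config_path: str,
    output_dir: str,
    seed: Optional[int] = None,
    prefix: str = "sim",
) -> SimulationResult:
    """Run a full simulation and write hapA/hapB FASTAs, the truthset VCF,
    per-haplotype PAFs, and the statistics file into ``output_dir``.

    ``seed`` overrides the config's random_seed; identical config bytes and
    seed produce byte-identical outputs.
    """
    params, categories = load_config(config_path)
    if seed is not None:
        params.random_seed = seed
    os.makedirs(output_dir, exist_ok=True)

    reference = Reference(params.reference_path)
    rois = ROISet([r for p in params.roi_files for r in read_bed(p)])
    blacklist = ROISet([r for p in params.blacklist_files for r in read_bed(p)])
    imported = []
    for cat in categories:
        if cat.is_import:
            imported.extend(import_vcf_svs(cat.vcf_path, reference.lengths))

    rng = np.random.default_rng(params.random_seed)
    placed = place_all(
        [c for c in categories if not c.is_import],
        reference,
        rois,
        blacklist,
        params,
        rng,
        imported=imported,
    )

    seqs = []
    assemblies = []
    for hap in (0, 1):
        hap_svs = [sv for sv in placed if hap in sv.haplotypes]
        s, a = build_haplotype(reference, hap_svs, hap)
        seqs.append(s)
        assemblies.append(a)

    paths = {
        "hapA_fasta": write_fasta(seqs[0], os.path.join(output_dir, f"{prefix}.hapA.fa")),
        "hapB_fasta": write_fasta(seqs[1], os.path.join(output_dir, f"{prefix}.hapB.fa")),
        "vcf": write_vcf(placed, reference, os.path.join(output_dir, f"{prefix}.vcf")),
        "hapA_paf": write_paf(
            assemblies[0], seqs[0], reference, os.path.join(output_dir, f"{prefix}.hapA.paf")
        ),
        "hapB_paf": write_paf(
            assemblies[1], seqs[1], reference, os.path.join(output_dir, f"{prefix}.hapB.paf")
        ),
        "stats": write_stats(
            placed, (seqs[0], seqs[1]), reference,
            os.path.join(output_dir, f"{prefix}.stats.tsv"),
        ),
    }
    result = SimulationResult(
        params=params,
        categories=categories,
        placed=placed,
        sequences=(seqs[0], seqs[1]),
        assemblies=(assemblies[0], assemblies[1]),
        paths=paths,
    )
    reference.close()
    return result
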