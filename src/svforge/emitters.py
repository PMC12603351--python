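"""Truthset serialization: linked multi-record VCF, PAF liftover, statistics.

VCF dialect: symbolic ALT alleles with a pad-base POS. One record per atomic
edit operation; records of a multi-breakpoint SV share a PARENT_SVID and each
carries the SV's grammar string plus the symbol and operation it represents.
Insertion-like records (copies, cut-and-paste, novel insertions) carry the
0-based insertion point in TPOS and, for copies, the 0-based half-open source
interval in SRC — enough information to replay the genome from the VCF alone.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import pysam

from .grammar import OpKind
from .placement import PlacedSV
from .reference import Reference
from .synthesis import HaplotypeAssembly

__all__ = ["write_vcf", "write_paf", "write_stats", "write_fasta"]

_INFO_LINES = [
    ('SVTYPE', '1', 'String', 'Variant class of this record'),
    ('END', '1', 'Integer', 'End position (1-based inclusive) of the edited interval'),
    ('SVLEN', '1', 'Integer', 'Signed length change contributed by this record'),
    ('PARENT_SVID', '1', 'String', 'Identifier linking all records of one SV'),
    ('GRAMMAR', '1', 'String', 'Rearrangement expression of the parent SV'),
    ('SYMBOL', '1', 'String', 'Grammar symbol this record operates on'),
    ('OPERATION', '1', 'String', 'Edit operation kind'),
    ('SLOT', '1', 'Integer', 'Target-side slot index of the operation'),
    ('TPOS', '1', 'String', 'Insertion point as chrom:pos, 0-based'),
    ('SRC', '1', 'String',
     'Copied/moved source interval as chrom:start-end, 0-based half-open'),
    ('SRC_STRAND', '1', 'String', 'Orientation of copied content (+ or -)'),
    ('NCOPIES', '1', 'Integer', 'Number of inserted copies'),
    ('INSSEQ', '1', 'String', 'Novel inserted sequence'),
]


def _header(reference: Reference) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in reference.contigs:
        header.contigs.add(chrom, length=reference.lengths[chrom])
    for ident, number, typ, desc in _INFO_LINES:
        header.info.add(ident, number, typ, desc)
    header.formats.add('GT', '1', 'String', 'Genotype')
    for alt, desc in (
        ('DEL', 'Deletion'),
        ('INV', 'Inversion'),
        ('DUP', 'Duplication'),
        ('INS', 'Insertion'),
    ):
        header.add_meta('ALT', items=[('ID', alt), ('Description', desc)])
    header.add_sample('SYNTH')
    return header


def _gt(sv: PlacedSV) -> tuple[int, int]:
    return (1 if 0 in sv.haplotypes else 0, 1 if 1 in sv.haplotypes else 0)


def _pad(reference: Reference, chrom: str, pos: int) -> tuple[int, str]:
    """(0-based POS, REF base): the base before `pos`, or the first base when
    the event touches the chromosome start."""
    p = max(0, pos - 1)
    return p, reference.fetch(chrom, p, p + 1)


def _records_for_sv(sv: PlacedSV, reference: Reference):
    """Yield (chrom, pos0, ref, alt, stop, info, id_suffix) per operation."""
    if sv.special == "SNP":
        chrom, s, _ = sv.placements["A"]
        alt = next(
            op.seq for op in sv.operations if op.kind is OpKind.NOVEL_INSERT
        )
        ref = reference.fetch(chrom, s, s + 1)
        info = {
            "SVTYPE": "SNP",
            "SVLEN": 0,
            "PARENT_SVID": sv.sv_id,
            "GRAMMAR": sv.grammar,
            "SYMBOL": "A",
            "OPERATION": "SNP",
        }
        yield chrom, s, ref, alt, s + 1, info, "0"
        return
    for i, op in enumerate(sv.operations):
        if op.kind is OpKind.IDENTITY:
            continue
        info = {
            "PARENT_SVID": sv.sv_id,
            "GRAMMAR": sv.grammar,
            "SYMBOL": op.symbol or "",
            "OPERATION": op.kind.value,
            "SLOT": op.target_slot if op.target_slot is not None else -1,
        }
        if op.kind is OpKind.DELETE:
            c, s, e = op.src
            pos0, ref = _pad(reference, c, s)
            info.update(SVTYPE="DEL", SVLEN=-(e - s))
            yield c, pos0, ref, "<DEL>", e, info, str(i)
        elif op.kind is OpKind.INVERT_IN_PLACE:
            c, s, e = op.src
            pos0, ref = _pad(reference, c, s)
            info.update(SVTYPE="INV", SVLEN=e - s)
            yield c, pos0, ref, "<INV>", e, info, str(i)
        elif op.kind is OpKind.TANDEM_COPY:
            c, s, e = op.src
            tc, tp = op.target
            pos0, ref = _pad(reference, c, s)
            info.update(
                SVTYPE="DUP",
                SVLEN=(e - s) * op.copy_count,
                TPOS=f"{tc}:{tp}",
                SRC=f"{c}:{s}-{e}",
                SRC_STRAND="-" if op.inverted else "+",
                NCOPIES=op.copy_count,
            )
            yield c, pos0, ref, "<DUP>", e, info, str(i)
        elif op.kind in (OpKind.DISPERSED_COPY, OpKind.CUT_PASTE):
            c, s, e = op.src
            tc, tp = op.target
            pos0, ref = _pad(reference, tc, tp)
            info.update(
                SVTYPE="INS",
                SVLEN=(e - s) * op.copy_count if op.kind is OpKind.DISPERSED_COPY
                else 0,
                TPOS=f"{tc}:{tp}",
                SRC=f"{c}:{s}-{e}",
                SRC_STRAND="-" if op.inverted else "+",
                NCOPIES=op.copy_count,
            )
            yield tc, pos0, ref, "<INS>", pos0 + 1, info, str(i)
        elif op.kind is OpKind.NOVEL_INSERT:
            tc, tp = op.target
            pos0, ref = _pad(reference, tc, tp)
            info.update(
                SVTYPE="INS",
                SVLEN=len(op.seq) * op.copy_count,
                TPOS=f"{tc}:{tp}",
                INSSEQ=op.seq,
                NCOPIES=op.copy_count,
            )
            yield tc, pos0, ref, "<INS>", pos0 + 1, info, str(i)
        else:  # pragma: no cover
            raise AssertionError(f"unhandled op kind {op.kind}")


def write_vcf(svs: Sequence[PlacedSV], reference: Reference, path: str) -> str:
    """Write the coordinate-sorted truthset VCF (one record per atomic
    operation; complex SVs linked via PARENT_SVID)."""
    header = _header(reference)
    rows = []
    for sv in svs:
        gt = _gt(sv)
        for chrom, pos0, ref, alt, stop, info, suffix in _records_for_sv(
            sv, reference
        ):
            rows.append((chrom, pos0, ref, alt, stop, info, f"{sv.sv_id}_{suffix}", gt))
    rank = {c: i for i, c in enumerate(reference.contigs)}
    rows.sort(key=lambda r: (rank[r[0]], r[1], r[6]))
    with pysam.VariantFile(path, "w", header=header) as out:
        for chrom, pos0, ref, alt, stop, info, rid, gt in rows:
            rec = out.new_record(
                contig=chrom,
                start=pos0,
                stop=stop,
                alleles=(ref, alt),
                id=rid,
            )
            for key, value in info.items():
                rec.info[key] = value
            rec.stop = stop  # symbolic-allele records keep END explicit
            rec.samples["SYNTH"]["GT"] = gt
            rec.samples["SYNTH"].phased = True
            out.write(rec)
    return path


def write_paf(
    assembly: HaplotypeAssembly,
    sequences: dict[str, str],
    reference: Reference,
    path: str,
    include_novel: bool = False,
) -> str:
    """One PAF line per reference-origin block: query = synthetic haplotype,
    target = reference, strand from block orientation, SV id in a sv:Z tag."""
    with open(path, "w") as out:
        for block in assembly.blocks:
            qlen = len(sequences[block.query_chrom])
            if block.origin == "novel":
                if not include_novel:
                    continue
                fields = [
                    block.query_chrom, qlen, block.query_start, block.query_end,
                    "+", "*", 0, 0, 0, 0, block.length, 0,
                ]
            else:
                fields = [
                    block.query_chrom, qlen, block.query_start, block.query_end,
                    block.strand, block.ref_chrom,
                    reference.lengths[block.ref_chrom],
                    block.ref_start, block.ref_end,
                    block.length, block.length, 60,
                ]
            tags = ["tp:A:P"]
            if block.sv_id:
                tags.append(f"sv:Z:{block.sv_id}")
            out.write("\t".join(map(str, fields + tags)) + "\n")
    return path


def _sv_size(sv: PlacedSV) -> int:
    letters = [t.symbol for t in sv.rule.source if not t.dispersion]
    if letters:
        return sum(sv.lengths.get(sym, 0) for sym in letters)
    return sum(
        len(op.seq or "") * op.copy_count
        for op in sv.operations
        if op.kind is OpKind.NOVEL_INSERT
    )


def write_stats(
    svs: Sequence[PlacedSV],
    hap_sequences: tuple[dict[str, str], dict[str, str]],
    reference: Reference,
    path: str,
) -> str:
    """Tab-separated summary: per-type counts and size ranges, and the total
    length difference of each chromosome on each haplotype."""
    by_type: dict[str, list[int]] = defaultdict(list)
    for sv in svs:
        by_type[sv.sv_type].append(_sv_size(sv))
    with open(path, "w") as out:
        out.write("#section=sv_counts\n")
        out.write("type\tcount\tmin_size\tmean_size\tmax_size\n")
        for name in sorted(by_type):
            sizes = by_type[name]
            out.write(
                f"{name}\t{len(sizes)}\t{min(sizes)}\t"
                f"{sum(sizes) / len(sizes):.1f}\t{max(sizes)}\n"
            )
        out.write("#section=chromosome_length_delta\n")
        out.write("chrom\thaplotype\tref_length\thap_length\tdelta\n")
        from .synthesis import HAP_SUFFIX

        for hap in (0, 1):
            seqs = hap_sequences[hap]
            for chrom in reference.contigs:
                qname = chrom + HAP_SUFFIX[hap]
                hlen = len(seqs[qname])
                rlen = reference.lengths[chrom]
                out.write(f"{chrom}\t{hap}\t{rlen}\t{hlen}\t{hlen - rlen}\n")
    return path


def write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> str:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")
            if not seq:
                out.write("\n")
    return path
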