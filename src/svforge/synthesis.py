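"""Haplotype construction: apply placed SVs to the reference.

Each haplotype is assembled per chromosome as an ordered list of blocks, each
block recording where its sequence came from (a reference interval on either
strand, or novel sequence) and which SV produced it. The block list is the
source of truth for the PAF liftover files, and its concatenated sequence is
exactly the emitted haplotype FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence, Union

import numpy as np

from .errors import SVForgeError
from .grammar import OpKind
from .reference import Reference

if TYPE_CHECKING:  # pragma: no cover
    from .placement import PlacedSV

__all__ = [
    "Block",
    "HaplotypeAssembly",
    "build_haplotype",
    "generate_insertion_sequence",
    "replay_oracle",
    "reverse_complement",
    "HAP_SUFFIX",
]

HAP_SUFFIX = ("_hapA", "_hapB")

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Block:
    query_chrom: str
    query_start: int
    query_end: int
    ref_chrom: Optional[str]
    ref_start: Optional[int]
    ref_end: Optional[int]
    strand: str = "+"  # '-' blocks carry reverse-complemented reference
    origin: str = "reference"  # or "novel"
    sv_id: Optional[str] = None

    @property
    def length(self) -> int:
        return self.query_end - self.query_start


@dataclass
class HaplotypeAssembly:
    haplotype: int
    blocks: list[Block] = field(default_factory=list)

    def blocks_for(self, query_chrom: str) -> list[Block]:
        return [b for b in self.blocks if b.query_chrom == query_chrom]

    def validate(self, sequences: dict[str, str], reference: Reference) -> None:
        """Check the tiling invariant and that block sequences concatenate to
        the emitted haplotype exactly."""
        for qname, seq in sequences.items():
            blocks = self.blocks_for(qname)
            pos = 0
            parts = []
            for b in blocks:
                if b.query_start != pos:
                    raise SVForgeError(
                        f"{qname}: block starts at {b.query_start}, expected {pos}"
                    )
                pos = b.query_end
                if b.origin == "reference":
                    s = reference.fetch(b.ref_chrom, b.ref_start, b.ref_end)
                    parts.append(reverse_complement(s) if b.strand == "-" else s)
                else:
                    parts.append(seq[b.query_start:b.query_end])
            if pos != len(seq):
                raise SVForgeError(
                    f"{qname}: blocks tile [0,{pos}) but haplotype has "
                    f"length {len(seq)}"
                )
            if "".join(parts) != seq:
                raise SVForgeError(f"{qname}: block sequences disagree with FASTA")


def generate_insertion_sequence(
    length: int,
    source: Union[str, Sequence[str]],
    rng: np.random.Generator,
) -> str:
    """Novel insertion content: i.i.d. uniform A/C/G/T in random mode, or a
    record/subsequence of the requested length drawn from a sequence pool
    (a pre-loaded list of records, or "random")."""
    if length < 1:
        raise ValueError(f"insertion length must be >= 1, got {length}")
    if isinstance(source, str):
        if source != "random":
            raise ValueError(
                "generate_insertion_sequence expects 'random' or a sequence pool"
            )
        return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, size=length)])
    exact = [s for s in source if len(s) == length]
    if exact:
        return exact[int(rng.integers(len(exact)))]
    longer = [s for s in source if len(s) > length]
    if not longer:
        raise SVForgeError(
            f"no insertion-source record of length >= {length} available"
        )
    rec = longer[int(rng.integers(len(longer)))]
    off = int(rng.integers(len(rec) - length + 1))
    return rec[off:off + length]


# ---------------------------------------------------------------------------
# block-walk construction

@dataclass(frozen=True)
class _Insertion:
    pos: int
    sv_id: str
    slot: int
    origin: str  # 'reference' | 'novel'
    src: Optional[tuple[str, int, int]] = None
    strand: str = "+"
    copies: int = 1
    seq: Optional[str] = None


@dataclass(frozen=True)
class _IntervalEdit:
    start: int
    end: int
    kind: str  # 'skip' | 'invert'
    sv_id: str


def _directives(svs: Sequence["PlacedSV"]):
    intervals: dict[str, list[_IntervalEdit]] = {}
    insertions: dict[str, list[_Insertion]] = {}
    for sv in svs:
        for op in sv.operations:
            if op.kind is OpKind.DELETE:
                c, s, e = op.src
                intervals.setdefault(c, []).append(_IntervalEdit(s, e, "skip", sv.sv_id))
            elif op.kind is OpKind.INVERT_IN_PLACE:
                c, s, e = op.src
                intervals.setdefault(c, []).append(
                    _IntervalEdit(s, e, "invert", sv.sv_id)
                )
            elif op.kind in (OpKind.TANDEM_COPY, OpKind.DISPERSED_COPY, OpKind.CUT_PASTE):
                tc, tp = op.target
                insertions.setdefault(tc, []).append(
                    _Insertion(
                        pos=tp,
                        sv_id=sv.sv_id,
                        slot=op.target_slot,
                        origin="reference",
                        src=op.src,
                        strand="-" if op.inverted else "+",
                        copies=op.copy_count,
                    )
                )
                if op.kind is OpKind.CUT_PASTE:
                    c, s, e = op.src
                    intervals.setdefault(c, []).append(
                        _IntervalEdit(s, e, "skip", sv.sv_id)
                    )
            elif op.kind is OpKind.NOVEL_INSERT:
                if op.seq is None:
                    raise SVForgeError(
                        f"{sv.sv_id}: novel insertion without generated sequence"
                    )
                tc, tp = op.target
                insertions.setdefault(tc, []).append(
                    _Insertion(
                        pos=tp,
                        sv_id=sv.sv_id,
                        slot=op.target_slot,
                        origin="novel",
                        seq=op.seq * op.copy_count,
                    )
                )
            # IDENTITY: no directive
    return intervals, insertions


def build_haplotype(
    reference: Reference,
    svs: Sequence["PlacedSV"],
    haplotype: int,
) -> tuple[dict[str, str], HaplotypeAssembly]:
    """Build one haplotype: walk each chromosome left to right, skipping
    deleted intervals, reverse-complementing inverted ones, and emitting
    copy/novel blocks at their insertion points.

    Returns ``(sequences keyed by suffixed contig name, assembly)``. Only SVs
    assigned to ``haplotype`` should be passed in.
    """
    suffix = HAP_SUFFIX[haplotype]
    intervals, insertions = _directives(svs)
    sequences: dict[str, str] = {}
    assembly = HaplotypeAssembly(haplotype=haplotype)
    for chrom in reference.contigs:
        qname = chrom + suffix
        clen = reference.lengths[chrom]
        ivs = sorted(intervals.get(chrom, []), key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise SVForgeError(
                    f"{chrom}: overlapping edits [{a.start},{a.end}) and "
                    f"[{b.start},{b.end}) on haplotype {haplotype}"
                )
        ins = sorted(
            insertions.get(chrom, []), key=lambda i: (i.pos, i.sv_id, i.slot)
        )
        events: list[tuple[int, int, object]] = [
            (i.pos, 0, i) for i in ins
        ] + [(iv.start, 1, iv) for iv in ivs]
        events.sort(key=lambda e: (e[0], e[1]))
        parts: list[str] = []
        raw_blocks: list[tuple] = []  # (seq, ref info...) before q-coords
        cursor = 0

        def emit_ref(start: int, end: int, strand: str = "+", sv_id=None):
            if start >= end:
                return
            seq = reference.fetch(chrom, start, end)
            if strand == "-":
                seq = reverse_complement(seq)
            raw_blocks.append((seq, chrom, start, end, strand, "reference", sv_id))

        for pos, _, payload in events:
            if pos < cursor:
                raise SVForgeError(
                    f"{chrom}: edit at {pos} inside an already-consumed region"
                )
            emit_ref(cursor, pos)
            cursor = pos
            if isinstance(payload, _Insertion):
                if payload.origin == "novel":
                    raw_blocks.append(
                        (payload.seq, None, None, None, "+", "novel", payload.sv_id)
                    )
                else:
                    sc, ss, se = payload.src
                    seq = reference.fetch(sc, ss, se)
                    if payload.strand == "-":
                        seq = reverse_complement(seq)
                    for _ in range(payload.copies):
                        raw_blocks.append(
                            (seq, sc, ss, se, payload.strand, "reference",
                             payload.sv_id)
                        )
            else:
                if payload.kind == "invert":
                    emit_ref(payload.start, payload.end, "-", payload.sv_id)
                cursor = payload.end
        emit_ref(cursor, clen)

        qpos = 0
        seq_parts = []
        for seq, rc, rs, re_, strand, origin, sv_id in raw_blocks:
            if not seq:
                continue
            assembly.blocks.append(
                Block(
                    query_chrom=qname,
                    query_start=qpos,
                    query_end=qpos + len(seq),
                    ref_chrom=rc,
                    ref_start=rs,
                    ref_end=re_,
                    strand=strand,
                    origin=origin,
                    sv_id=sv_id,
                )
            )
            qpos += len(seq)
            seq_parts.append(seq)
        sequences[qname] = "".join(seq_parts)
    return sequences, assembly


# ---------------------------------------------------------------------------
# independent replay oracle (tests only): a deliberately naive string editor

def replay_oracle(reference: Reference, vcf_path: str) -> dict[tuple[int, str], str]:
    """Reconstruct both haplotypes from an emitted VCF, operation by
    operation, with no assembly bookkeeping.

    Edits are applied to mutable per-chromosome strings in descending
    coordinate order (interval edits before same-position insertions), with
    copy content always fetched from the original reference.
    """
    import pysam

    # (hap, chrom) -> list of primitive edits
    prims: dict[tuple[int, str], list[tuple]] = {}

    def add(haps, chrom, edit):
        for hap in haps:
            prims.setdefault((hap, chrom), []).append(edit)

    def parse_point(text):  # "chrom:pos", 0-based insertion point
        c, p = str(text).rsplit(":", 1)
        return c, int(p)

    def parse_interval(text):  # "chrom:start-end", 0-based half-open
        c, rest = str(text).rsplit(":", 1)
        s, e = rest.split("-")
        return c, int(s), int(e)

    with pysam.VariantFile(vcf_path) as vf:
        for rec in vf:
            gt = rec.samples[0]["GT"]
            haps = tuple(i for i, a in enumerate(gt) if a == 1)
            if not haps:
                continue
            op = rec.info.get("OPERATION", rec.info.get("SVTYPE"))
            end = rec.stop
            svlen = rec.info.get("SVLEN", 0)
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            svlen = abs(int(svlen))
            sv_id = rec.info.get("PARENT_SVID", rec.id or "")
            slot = int(rec.info.get("SLOT", 0))

            def insertion_content():
                seq = rec.info.get("INSSEQ")
                if seq is not None:
                    return str(seq)
                c, s, e = parse_interval(rec.info["SRC"])
                content = reference.fetch(c, s, e)
                if rec.info.get("SRC_STRAND") == "-":
                    content = reverse_complement(content)
                return content * int(rec.info.get("NCOPIES", 1))

            if op == "DELETE":
                add(haps, rec.chrom, ("iv", end - svlen, ("D", end - svlen, end)))
            elif op == "INVERT_IN_PLACE":
                add(haps, rec.chrom, ("iv", end - svlen, ("V", end - svlen, end)))
            elif op == "SNP":
                add(haps, rec.chrom, ("iv", rec.start, ("D", rec.start, rec.start + 1)))
                add(haps, rec.chrom,
                    ("ins", rec.start, (sv_id, slot), str(rec.alts[0])))
            elif op == "CUT_PASTE":
                tc, tp = parse_point(rec.info["TPOS"])
                sc, ss, se = parse_interval(rec.info["SRC"])
                add(haps, tc, ("ins", tp, (sv_id, slot), insertion_content()))
                add(haps, sc, ("iv", ss, ("D", ss, se)))
            elif op in ("TANDEM_COPY", "DISPERSED_COPY", "NOVEL_INSERT"):
                tc, tp = parse_point(rec.info["TPOS"])
                add(haps, tc, ("ins", tp, (sv_id, slot), insertion_content()))
            else:
                raise SVForgeError(f"replay: unknown operation {op!r}")

    out: dict[tuple[int, str], str] = {}
    for hap in (0, 1):
        for chrom in reference.contigs:
            seq = reference.fetch(chrom, 0, reference.lengths[chrom])
            edits = prims.get((hap, chrom), [])
            # ascending (pos, insertions-before-intervals, sv order), applied
            # in reverse so edits never disturb lower coordinates
            def key(edit):
                kind, pos = edit[0], edit[1]
                if kind == "ins":
                    return (pos, 0, edit[2])
                return (pos, 1, ("", 0))
            for edit in reversed(sorted(edits, key=key)):
                if edit[0] == "ins":
                    _, pos, _, content = edit
                    seq = seq[:pos] + content + seq[pos:]
                else:
                    _, _, (k, s, e) = edit
                    if k == "D":
                        seq = seq[:s] + seq[e:]
                    else:
                        seq = seq[:s] + reverse_complement(seq[s:e]) + seq[e:]
            out[(hap, chrom)] = seq
    return out
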