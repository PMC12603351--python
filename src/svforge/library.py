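"""Registry of the 26 predefined SV types, plus VCF import of fixed SVs.

Each entry names a rearrangement rule from the grammar. A handful of entries
carry extra behaviour: SNP is a one-base substitution (1 bp deletion plus a
1 bp novel base drawn from the three non-reference bases), trEXP/trCON act on
tandem-repeat loci annotated with their motif, and the ``*_INTER`` entries
default the dispersion to a different chromosome.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from typing import Optional

import pysam

from .errors import ImportError_, SVForgeError
from .grammar import RearrangementRule, derive_operations, parse_rule

__all__ = [
    "SVTypeEntry",
    "ImportedSV",
    "lookup_type",
    "registry_size",
    "registry_names",
    "all_entries",
    "import_vcf_svs",
    "expand_small_variants",
    "tandem_repeat_event",
]


@dataclass(frozen=True)
class SVTypeEntry:
    name: str
    rule_string: str
    symbol_roles: dict[str, str] = field(default_factory=dict)
    interchromosomal: bool = False
    # trEXP/trCON operate on motif-annotated repeat loci rather than on the
    # placeholder rule; SNP substitutes a base.
    special: Optional[str] = None  # "SNP" | "trEXP" | "trCON"

    @property
    def rule(self) -> RearrangementRule:
        return parse_rule(self.rule_string)


_ENTRIES: tuple[SVTypeEntry, ...] = (
    # --- simple events ---
    SVTypeEntry("DEL", "A→", {"A": "deleted segment"}),
    SVTypeEntry("INS", "→A", {"A": "novel inserted sequence"}),
    SVTypeEntry("INV", "A→a", {"A": "inverted segment"}),
    SVTypeEntry("DUP", "A→AA", {"A": "tandem-duplicated segment"}),
    SVTypeEntry("mCNV", "A→AA+", {"A": "multi-copy duplicated segment"}),
    SVTypeEntry("SNP", "A→B", {"A": "reference base", "B": "alternate base"},
                special="SNP"),
    # --- dispersion-based events ---
    SVTypeEntry("dDUP", "A_→A_A",
                {"A": "duplicated segment", "_1": "dispersion"}),
    SVTypeEntry("INV_dDUP", "A_→A_a",
                {"A": "segment copied in inverted orientation",
                 "_1": "dispersion"}),
    SVTypeEntry("dDUP_INTER", "A_→A_A",
                {"A": "duplicated segment",
                 "_1": "inter-chromosomal dispersion"},
                interchromosomal=True),
    SVTypeEntry("nrTRA", "A_→_A",
                {"A": "translocated segment", "_1": "dispersion"}),
    SVTypeEntry("rTRA", "A_B→B_A",
                {"A": "exchanged segment", "B": "exchanged segment",
                 "_1": "dispersion"}),
    SVTypeEntry("rTRA_INTER", "A_B→B_A",
                {"A": "exchanged segment", "B": "exchanged segment",
                 "_1": "inter-chromosomal dispersion"},
                interchromosomal=True),
    # --- flanked inversions ---
    SVTypeEntry("delINV", "AB→b",
                {"A": "deleted flank", "B": "inverted segment"}),
    SVTypeEntry("INVdel", "AB→a",
                {"A": "inverted segment", "B": "deleted flank"}),
    SVTypeEntry("delINVdel", "ABC→b",
                {"A": "deleted flank", "B": "inverted segment",
                 "C": "deleted flank"}),
    SVTypeEntry("dupINV", "AB→Aba",
                {"A": "flank duplicated in inverted orientation",
                 "B": "inverted segment"}),
    SVTypeEntry("INVdup", "AB→baB",
                {"A": "inverted segment",
                 "B": "flank duplicated in inverted orientation"}),
    SVTypeEntry("dupINVdup", "ABC→AcbaC",
                {"A": "left duplicated flank", "B": "inverted segment",
                 "C": "right duplicated flank"}),
    SVTypeEntry("delINVdup", "ABC→cbC",
                {"A": "deleted flank", "B": "inverted segment",
                 "C": "flank duplicated in inverted orientation"}),
    SVTypeEntry("dupINVdel", "ABC→Aba",
                {"A": "flank duplicated in inverted orientation",
                 "B": "inverted segment", "C": "deleted flank"}),
    # --- dispersions with deletion at the distal locus ---
    SVTypeEntry("dDUP_iDEL", "A_B→A_A",
                {"A": "duplicated segment", "B": "deleted distal segment",
                 "_1": "dispersion"}),
    SVTypeEntry("INS_iDEL", "A_B→A_C",
                {"A": "context segment", "B": "deleted distal segment",
                 "C": "novel inserted sequence", "_1": "dispersion"}),
    # --- in-place inverted duplications (both symmetric forms) ---
    SVTypeEntry("INV_DUP", "A→Aa",
                {"A": "segment with trailing inverted copy"}),
    SVTypeEntry("INV_DUP5", "A→aA",
                {"A": "segment with leading inverted copy"}),
    # --- tandem-repeat copy-number events ---
    SVTypeEntry("trEXP", "A→AA+",
                {"A": "repeat motif unit"}, special="trEXP"),
    SVTypeEntry("trCON", "A→",
                {"A": "removed repeat copies"}, special="trCON"),
)

_BY_NAME: dict[str, SVTypeEntry] = {e.name: e for e in _ENTRIES}
assert len(_BY_NAME) == len(_ENTRIES)


def registry_size() -> int:
    """Number of predefined SV types."""
    return len(_ENTRIES)


def registry_names() -> tuple[str, ...]:
    return tuple(e.name for e in _ENTRIES)


def lookup_type(name: str) -> SVTypeEntry:
    """Return the registry entry for ``name`` (case-sensitive).

    Unknown names raise with near-miss suggestions and the full list of
    valid names.
    """
    try:
        return _BY_NAME[name]
    except KeyError:
        close = difflib.get_close_matches(name, _BY_NAME, n=3, cutoff=0.5)
        hint = f" Did you mean: {', '.join(close)}?" if close else ""
        raise SVForgeError(
            f"unknown SV type {name!r}.{hint} Valid names: "
            + ", ".join(sorted(_BY_NAME))
        ) from None


def all_entries() -> tuple[SVTypeEntry, ...]:
    return _ENTRIES


_SIMPLE_IMPORT_RULES = {
    "DEL": "A→",
    "INV": "A→a",
    "DUP": "A→AA",
    "INS": "→A",
    "SNP": "A→B",
}


@dataclass(frozen=True)
class ImportedSV:
    chrom: str
    start: int  # 0-based half-open
    end: int
    type_name: Optional[str]  # registry name when resolvable
    rule_string: str
    genotype: tuple[int, ...]  # haplotypes carrying the SV, subset of {0,1}
    record_id: str
    inserted_sequence: Optional[str] = None
    alt_base: Optional[str] = None  # SNP


def _info_get(rec, key, default=None):
    # pysam raises on keys missing from the header; treat those as absent
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def _genotype_from_record(rec) -> tuple[int, ...]:
    if rec.samples:
        gt = rec.samples[0].get("GT")
        if gt and any(a for a in gt if a):
            haps = tuple(i for i, a in enumerate(gt[:2]) if a == 1)
            if haps:
                return haps
    return (0, 1)  # unannotated records default to homozygous


def import_vcf_svs(path: str, contig_lengths: dict[str, int]) -> list[ImportedSV]:
    """Read pre-specified SVs from a VCF; they bypass random placement.

    Records must carry SVTYPE (a simple type or registry name) or a GRAMMAR
    INFO key; coordinates are validated against ``contig_lengths``.
    """
    out: list[ImportedSV] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            rid = rec.id or f"{rec.chrom}:{rec.pos}"
            svtype = _info_get(rec, "SVTYPE")
            grammar = _info_get(rec, "GRAMMAR")
            if rec.chrom not in contig_lengths:
                raise ImportError_(
                    f"record {rid}: contig {rec.chrom!r} not in reference"
                )
            clen = contig_lengths[rec.chrom]
            if svtype is None and grammar is None and len(rec.ref) != len(rec.alts[0]):
                # plain indel-style record
                svtype = "DEL" if len(rec.ref) > len(rec.alts[0]) else "INS"
            if svtype is None and grammar is None:
                if len(rec.ref) == 1 and len(rec.alts[0]) == 1:
                    svtype = "SNP"
                else:
                    raise ImportError_(
                        f"record {rid}: no SVTYPE or GRAMMAR information"
                    )
            if grammar is not None:
                try:
                    rule_string = parse_rule(str(grammar)).canonical_string
                except SVForgeError as exc:
                    raise ImportError_(
                        f"record {rid}: unparseable GRAMMAR {grammar!r}: {exc}"
                    ) from exc
                type_name = str(svtype) if svtype in _BY_NAME else None
            elif svtype in _BY_NAME:
                type_name = str(svtype)
                rule_string = _BY_NAME[type_name].rule_string
            elif svtype in _SIMPLE_IMPORT_RULES:
                type_name = str(svtype)
                rule_string = _SIMPLE_IMPORT_RULES[type_name]
            else:
                raise ImportError_(
                    f"record {rid}: unparseable SVTYPE {svtype!r} "
                    "(not a registry name, simple type, or grammar rule)"
                )
            end = rec.stop  # pysam: 0-based exclusive end from END or ref len
            start = rec.start
            svlen = _info_get(rec, "SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if svtype == "SNP":
                start, end = rec.start, rec.start + 1
            elif svtype in ("DEL", "INV", "DUP") and svlen is not None:
                start = end - abs(int(svlen))
            elif svtype == "INS":
                end = start
            if not (0 <= start <= end <= clen):
                raise ImportError_(
                    f"record {rid}: interval [{start},{end}) outside contig "
                    f"{rec.chrom} of length {clen}"
                )
            ins_seq = _info_get(rec, "INSSEQ")
            alt = rec.alts[0] if rec.alts else None
            if svtype == "INS" and ins_seq is None and alt and not alt.startswith("<"):
                ins_seq = alt[1:] if alt[0] == rec.ref[0] else alt
            out.append(
                ImportedSV(
                    chrom=rec.chrom,
                    start=start,
                    end=end,
                    type_name=type_name,
                    rule_string=rule_string,
                    genotype=_genotype_from_record(rec),
                    record_id=str(rid),
                    inserted_sequence=str(ins_seq) if ins_seq else None,
                    alt_base=str(alt) if svtype == "SNP" and alt else None,
                )
            )
    return out


def expand_small_variants(category, reference, rng, rois=None, blacklist=None,
                          params=None):
    """Place a small-variant (SNP) category: one single-base substitution per
    instance, ALT drawn uniformly from the three non-reference bases, honoring
    the same occupancy/blacklist machinery as SVs."""
    from .config import GlobalParams
    from .placement import place_all
    from .regions import ROISet

    if params is None:
        params = GlobalParams(reference_path="")
    return place_all(
        [category], reference, rois or ROISet(), blacklist or ROISet(),
        params, rng,
    )


def tandem_repeat_event(category, roi, reference, rng, params=None):
    """Place one tandem-repeat expansion/contraction on a specific repeat
    locus. The ROI label must encode the motif as ``TR_<motif>``; expansion
    inserts the sampled number of extra motif copies, contraction removes
    them (failing when it would exceed the copies present)."""
    from .config import GlobalParams
    from .placement import OccupancyIndex, _place_tandem_repeat
    from .placement import instantiate_category
    from .regions import ROISet

    if params is None:
        params = GlobalParams(reference_path="")
    (sv,) = instantiate_category(category, rng, 0)
    return _place_tandem_repeat(
        sv, category.constraints[0] if category.constraints else None,
        OccupancyIndex(), ROISet([roi]), ROISet(), reference, params, rng,
    )


def _registry_self_check() -> None:
    for entry in _ENTRIES:
        derive_operations(entry.rule)


_registry_self_check()
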