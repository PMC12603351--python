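"""Constraint-based SV placement.

Breakend distances are sampled uniformly from each category's ranges (or
derived from other symbols), zygosity is drawn per SV, and reference
coordinates are chosen subject to the placement constraints: ROI overlap
modes, blacklists, a minimum inter-SV breakend distance, and per-haplotype
non-overlap. Categories are placed greedily, most restrictive first: fixed
(VCF-imported), exact, partial, containing, contained, terminal/whole
chromosome, then unconstrained.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .config import Derivation, GlobalParams, LengthRange, SVCategory
from .errors import PlacementError, SVForgeError
from .grammar import OpKind, RearrangementRule, derive_operations, parse_rule
from .library import ImportedSV
from .reference import Reference
from .regions import ROI, OverlapMode, PlacementConstraint, ROISet
from .synthesis import generate_insertion_sequence

__all__ = [
    "ResolvedOp",
    "PlacedSV",
    "OccupancyIndex",
    "sample_lengths",
    "assign_zygosity",
    "order_queue",
    "place_sv",
    "place_all",
    "audit_placement",
    "sv_breakends",
    "from_imported",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class ResolvedOp:
    """An edit operation with resolved reference coordinates."""

    kind: OpKind
    symbol: Optional[str]
    target_slot: Optional[int]
    inverted: bool = False
    copy_count: int = 1
    src: Optional[tuple[str, int, int]] = None  # (chrom, start, end) 0-based
    target: Optional[tuple[str, int]] = None  # (chrom, insertion point)
    seq: Optional[str] = None  # novel insertion content / SNP alternate base


@dataclass
class PlacedSV:
    sv_id: str
    sv_type: str
    rule: RearrangementRule
    category_index: int
    haplotypes: tuple[int, ...] = (0, 1)
    lengths: dict[str, int] = field(default_factory=dict)
    copy_counts: dict[int, int] = field(default_factory=dict)  # slot -> copies
    novel_seqs: dict[int, str] = field(default_factory=dict)  # slot -> seq
    constraints: list[PlacementConstraint] = field(default_factory=list)
    interchromosomal: bool = False
    special: Optional[str] = None
    fixed: bool = False
    tr_delta: int = 0
    placements: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    operations: list[ResolvedOp] = field(default_factory=list)
    extra_occupancy: list[tuple[str, int, int]] = field(default_factory=list)
    roi_used: Optional[ROI] = None
    # category distance spec captured at instantiation (exact/whole-chromosome
    # modes refit lengths against it)
    distance_spec: dict = field(default_factory=dict)

    @property
    def grammar(self) -> str:
        return self.rule.canonical_string

    @property
    def total_span(self) -> int:
        return sum(
            self.lengths.get(t.symbol, 0) for t in self.rule.source
        )


# ---------------------------------------------------------------------------
# length sampling and zygosity

def _resolve_derivations(category: SVCategory, lengths: dict[str, int]) -> dict[str, int]:
    pending = {
        sym: d for sym, d in category.distances.items() if isinstance(d, Derivation)
    }
    for _ in range(len(pending) + 1):
        progressed = False
        for sym, deriv in list(pending.items()):
            if deriv.symbol in lengths:
                lengths[sym] = max(1, round(deriv.factor * lengths[deriv.symbol]))
                del pending[sym]
                progressed = True
        if not pending:
            break
        if not progressed:  # pragma: no cover - cycles rejected at validation
            raise SVForgeError(
                f"unresolvable length derivations: {sorted(pending)}"
            )
    return lengths


def sample_lengths(category: SVCategory, rng: np.random.Generator) -> dict[str, int]:
    """Draw one length per symbol: uniform on [min, max] for independent
    symbols, then derived symbols from the already-sampled lengths (rounded
    to the nearest integer, minimum 1 bp)."""
    lengths: dict[str, int] = {}
    for sym, dist in category.distances.items():
        if isinstance(dist, LengthRange):
            lengths[sym] = int(rng.integers(dist.min, dist.max + 1))
    return _resolve_derivations(category, lengths)


def assign_zygosity(
    svs: Sequence[PlacedSV], policy: float, rng: np.random.Generator
) -> list[PlacedSV]:
    """Homozygous with probability ``policy`` (both haplotypes, identical
    coordinates); otherwise heterozygous on a uniformly chosen haplotype."""
    out = []
    for sv in svs:
        if rng.random() < policy:
            sv.haplotypes = (0, 1)
        else:
            sv.haplotypes = (int(rng.integers(2)),)
        out.append(sv)
    return out


# ---------------------------------------------------------------------------
# layout: symbol intervals and resolved operations from a footprint position

def _fit_lengths_to_total(
    symbols: Sequence[str], category: SVCategory, total: int
) -> Optional[dict[str, int]]:
    """Pick a length in range for each symbol so they sum to ``total``;
    None when infeasible. Used by exact and whole-chromosome modes."""
    ranges = []
    for sym in symbols:
        dist = category.distances.get(sym)
        if isinstance(dist, LengthRange):
            ranges.append((sym, dist.min, dist.max))
        else:  # derived or missing: treat current behaviour as inflexible
            return None
    lo = sum(r[1] for r in ranges)
    hi = sum(r[2] for r in ranges)
    if not (lo <= total <= hi):
        return None
    out = {sym: mn for sym, mn, _ in ranges}
    remaining = total - lo
    for sym, mn, mx in ranges:
        add = min(remaining, mx - mn)
        out[sym] += add
        remaining -= add
    return out


def _anchor_geometry(
    rule: RearrangementRule, lengths: dict[str, int]
) -> tuple[int, int, tuple[str, ...]]:
    """(offset of anchored span within the footprint, anchored span length,
    anchored symbols). With no '()' anchor the whole SV span is anchored."""
    offsets: dict[int, int] = {}
    cur = 0
    for i, tok in enumerate(rule.source):
        offsets[i] = cur
        cur += lengths[tok.symbol]
    total = cur
    if rule.anchor is None:
        return 0, total, tuple(t.symbol for t in rule.source)
    if rule.anchor == ():
        bk = rule.anchor_breakend or 0
        pos = offsets.get(bk, total)
        return pos, 0, ()
    first, last = min(rule.anchor), max(rule.anchor)
    ao = offsets[first]
    alen = sum(lengths[rule.source[i].symbol] for i in rule.anchor)
    return ao, alen, tuple(rule.source[i].symbol for i in rule.anchor)


def resolve_layout(
    sv: PlacedSV,
    chrom: str,
    start: int,
    reference: Reference,
    inter: Optional[tuple[str, int]] = None,
) -> PlacedSV:
    """Resolve symbol intervals and edit operations for a footprint placed at
    ``(chrom, start)``. ``inter`` gives the landing position of the single
    dispersion for inter-chromosomal SVs."""
    rule = sv.rule
    placements: dict[str, tuple[str, int, int]] = {}
    cur_chrom, cur = chrom, start
    jumped = False
    for tok in rule.source:
        if tok.dispersion and sv.interchromosomal:
            if inter is None:
                raise PlacementError(
                    f"{sv.sv_id}: inter-chromosomal SV placed without a "
                    "dispersion target"
                )
            placements[tok.symbol] = (inter[0], inter[1], inter[1])
            cur_chrom, cur = inter
            jumped = True
            continue
        length = sv.lengths[tok.symbol]
        placements[tok.symbol] = (cur_chrom, cur, cur + length)
        cur += length
    for letter in rule.novel_letters:
        if letter not in sv.lengths:
            raise PlacementError(f"{sv.sv_id}: no length for novel symbol {letter}")

    ops: list[ResolvedOp] = []
    walk_chrom, walk_pos = chrom, start
    for op in derive_operations(rule):
        if op.kind is OpKind.DELETE:
            ops.append(
                ResolvedOp(
                    kind=op.kind,
                    symbol=op.source_symbol,
                    target_slot=None,
                    src=placements[op.source_symbol],
                )
            )
            continue
        slot = op.target_slot
        if op.kind in (OpKind.IDENTITY, OpKind.INVERT_IN_PLACE):
            c, s, e = placements[op.source_symbol]
            ops.append(
                ResolvedOp(
                    kind=op.kind,
                    symbol=op.source_symbol,
                    target_slot=slot,
                    inverted=op.inverted,
                    src=(c, s, e),
                )
            )
            walk_chrom, walk_pos = c, e
            continue
        if op.kind is OpKind.NOVEL_INSERT:
            seq = sv.novel_seqs.get(slot)
            length = sv.lengths[op.novel_letter]
            ops.append(
                ResolvedOp(
                    kind=op.kind,
                    symbol=op.novel_letter,
                    target_slot=slot,
                    inverted=op.inverted,
                    copy_count=sv.copy_counts.get(slot, 1),
                    target=(walk_chrom, walk_pos),
                    seq=seq,
                )
            )
            continue
        # copies and cut-paste reference the source interval
        ops.append(
            ResolvedOp(
                kind=op.kind,
                symbol=op.source_symbol,
                target_slot=slot,
                inverted=op.inverted,
                copy_count=sv.copy_counts.get(slot, 1),
                src=placements[op.source_symbol],
                target=(walk_chrom, walk_pos),
            )
        )
    sv.placements = placements
    sv.operations = ops
    # bounds check (should hold by construction)
    for c, s, e in placements.values():
        if not (0 <= s <= e <= reference.lengths[c]):
            raise PlacementError(
                f"{sv.sv_id}: interval [{s},{e}) outside contig {c}"
            )
    return sv


def sv_breakends(sv: PlacedSV) -> list[tuple[str, int]]:
    """All breakend positions of a placed SV (symbol interval boundaries and
    insertion target points), deduplicated."""
    points: set[tuple[str, int]] = set()
    for c, s, e in sv.placements.values():
        points.add((c, s))
        points.add((c, e))
    for op in sv.operations:
        if op.target is not None:
            points.add(op.target)
    return sorted(points)


# ---------------------------------------------------------------------------
# occupancy bookkeeping

class OccupancyIndex:
    """Per-haplotype interval index of committed SV footprints plus the
    global breakend registry used for the minimum inter-SV distance."""

    def __init__(self):
        self._trees: dict[tuple[int, str], IntervalTree] = {}
        self._breakends: dict[str, list[int]] = {}

    def _tree(self, hap: int, chrom: str) -> IntervalTree:
        return self._trees.setdefault((hap, chrom), IntervalTree())

    def overlaps(self, hap: int, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get((hap, chrom))
        if tree is None:
            return False
        if start == end:
            return any(iv.begin < start < iv.end for iv in tree.at(start))
        return bool(tree.overlap(start, end))

    def min_breakend_gap(self, chrom: str, pos: int) -> Optional[int]:
        points = self._breakends.get(chrom)
        if not points:
            return None
        i = bisect.bisect_left(points, pos)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(points):
                d = abs(points[j] - pos)
                best = d if best is None else min(best, d)
        return best

    def commit(self, sv: PlacedSV, allow_cross_haplotype: bool) -> None:
        intervals = [
            (c, s, e)
            for tok in sv.rule.source
            if not tok.dispersion
            for (c, s, e) in [sv.placements[tok.symbol]]
        ] + sv.extra_occupancy
        haps = (0, 1) if not allow_cross_haplotype else sv.haplotypes
        # booking both haplotypes when cross-haplotype overlap is disabled
        for hap in haps:
            for c, s, e in intervals:
                if s < e:
                    self._tree(hap, c).addi(s, e, sv.sv_id)
        for c, p in sv_breakends(sv):
            bisect.insort(self._breakends.setdefault(c, []), p)


def _check_candidate(
    sv: PlacedSV,
    occupied: OccupancyIndex,
    blacklist: ROISet,
    params: GlobalParams,
) -> bool:
    haps = sv.haplotypes if params.allow_cross_haplotype_overlap else (0, 1)
    for tok in sv.rule.source:
        if tok.dispersion:
            continue
        c, s, e = sv.placements[tok.symbol]
        for hap in haps:
            if occupied.overlaps(hap, c, s, e):
                return False
    breakends = sv_breakends(sv)
    for c, p in breakends:
        for hap in haps:
            if occupied.overlaps(hap, c, p, p):
                return False
    if params.min_inter_sv_distance > 0:
        for c, p in breakends:
            gap = occupied.min_breakend_gap(c, p)
            if gap is not None and gap < params.min_inter_sv_distance:
                return False
    if len(blacklist):
        for c, p in breakends:
            if blacklist.containing_point(c, p, strict=True):
                return False
    return True


# ---------------------------------------------------------------------------
# ordering

_STAGE = {
    OverlapMode.EXACT: 1,
    OverlapMode.PARTIAL: 2,
    OverlapMode.CONTAINING: 3,
    OverlapMode.CONTAINED: 4,
    OverlapMode.TERMINAL: 5,
    OverlapMode.WHOLE_CHROMOSOME: 5,
    OverlapMode.BLACKLIST: 6,
}


def _stage(sv: PlacedSV) -> int:
    if sv.fixed:
        return 0
    stages = [_STAGE[c.mode] for c in sv.constraints] or [6]
    return min(stages)


def order_queue(svs: Sequence[PlacedSV]) -> list[PlacedSV]:
    """Most-restrictive-first placement queue: fixed, exact, partial,
    containing, contained, terminal/whole-chromosome, unconstrained;
    ties broken by descending SV span, then stable input order."""
    return sorted(
        svs, key=lambda sv: (_stage(sv), -sv.total_span)
    )


# ---------------------------------------------------------------------------
# candidate sampling per mode

def _uniform_genome_position(
    footprint: int, reference: Reference, rng: np.random.Generator
) -> Optional[tuple[str, int]]:
    weights = [
        max(0, reference.lengths[c] - footprint + 1) for c in reference.contigs
    ]
    total = sum(weights)
    if total == 0:
        return None
    k = int(rng.integers(total))
    for chrom, w in zip(reference.contigs, weights):
        if k < w:
            return chrom, k
        k -= w
    raise AssertionError("unreachable")


def _split_footprint(sv: PlacedSV) -> tuple[int, int]:
    """(pre-dispersion length, post-dispersion length) for inter-chromosomal
    SVs with a single dispersion."""
    pre = post = 0
    seen = False
    for tok in sv.rule.source:
        if tok.dispersion:
            seen = True
            continue
        if seen:
            post += sv.lengths[tok.symbol]
        else:
            pre += sv.lengths[tok.symbol]
    return pre, post


def _sample_inter_target(
    sv: PlacedSV, chrom: str, reference: Reference, rng: np.random.Generator
) -> Optional[tuple[str, int]]:
    _, post = _split_footprint(sv)
    others = [
        c
        for c in reference.contigs
        if c != chrom and reference.lengths[c] >= post
    ]
    if not others:
        return None
    c2 = others[int(rng.integers(len(others)))]
    p2 = int(rng.integers(reference.lengths[c2] - post + 1))
    return c2, p2


def _anchor_to_start(sv: PlacedSV, anchor_start: int) -> int:
    ao, _, _ = _anchor_geometry(sv.rule, sv.lengths)
    return anchor_start - ao


def _candidate_rois(
    constraint: PlacementConstraint, rois: ROISet
) -> list[ROI]:
    return rois.with_labels(
        sorted(constraint.roi_labels) if constraint.roi_labels is not None else None
    )


def _sample_mode_position(
    sv: PlacedSV,
    constraint: Optional[PlacementConstraint],
    rois: ROISet,
    reference: Reference,
    rng: np.random.Generator,
) -> Optional[tuple[str, int]]:
    """One candidate footprint start per attempt (None = draw failed)."""
    ao, alen, _ = _anchor_geometry(sv.rule, sv.lengths)
    footprint = sv.total_span
    if sv.interchromosomal:
        footprint, _ = _split_footprint(sv)

    if constraint is None or constraint.mode is OverlapMode.BLACKLIST:
        return _uniform_genome_position(footprint, reference, rng)

    mode = constraint.mode
    if mode is OverlapMode.TERMINAL:
        chroms = [c for c in reference.contigs if reference.lengths[c] >= footprint]
        if not chroms:
            return None
        chrom = chroms[int(rng.integers(len(chroms)))]
        if rng.random() < 0.5:
            return chrom, 0
        return chrom, reference.lengths[chrom] - footprint

    if mode is OverlapMode.WHOLE_CHROMOSOME:
        feasible = []
        for chrom in reference.contigs:
            fitted = _fit_lengths_to_total(
                [t.symbol for t in sv.rule.source],
                _cat_stub(sv),
                reference.lengths[chrom],
            )
            if fitted is not None:
                feasible.append((chrom, fitted))
        if not feasible:
            return None
        chrom, fitted = feasible[int(rng.integers(len(feasible)))]
        sv.lengths.update(fitted)
        _resolve_derivations(_cat_stub(sv), sv.lengths)
        return chrom, 0

    candidates = [
        r for r in _candidate_rois(constraint, rois) if r.chrom in reference.lengths
    ]
    if mode is OverlapMode.EXACT:
        anchored = constraint.anchored_symbols or tuple(
            t.symbol for t in sv.rule.source
        )
        feasible = []
        for roi in candidates:
            fitted = _fit_lengths_to_total(anchored, _cat_stub(sv), roi.length)
            if fitted is not None:
                feasible.append((roi, fitted))
        if not feasible:
            return None
        roi, fitted = feasible[int(rng.integers(len(feasible)))]
        sv.lengths.update(fitted)
        _resolve_derivations(_cat_stub(sv), sv.lengths)
        sv.roi_used = roi
        return roi.chrom, _anchor_to_start(sv, roi.start)

    if mode is OverlapMode.CONTAINED:
        feasible = [r for r in candidates if r.length >= alen]
        if not feasible:
            return None
        roi = feasible[int(rng.integers(len(feasible)))]
        a_start = roi.start + int(rng.integers(roi.length - alen + 1))
        sv.roi_used = roi
        return roi.chrom, _anchor_to_start(sv, a_start)

    if mode is OverlapMode.CONTAINING:
        feasible = [r for r in candidates if r.length <= alen]
        if not feasible:
            return None
        roi = feasible[int(rng.integers(len(feasible)))]
        lo = max(0, roi.end - alen)
        hi = roi.start
        if hi < lo:
            return None
        a_start = lo + int(rng.integers(hi - lo + 1))
        sv.roi_used = roi
        return roi.chrom, _anchor_to_start(sv, a_start)

    if mode is OverlapMode.PARTIAL:
        if not candidates:
            return None
        roi = candidates[int(rng.integers(len(candidates)))]
        choices = []
        if alen == 0:
            if roi.length > 1:
                choices.append(("point", roi.start + 1, roi.end - 1))
        else:
            # anchor start strictly inside, end at/after ROI end
            lo = max(roi.start + 1, roi.end - alen)
            hi = roi.end - 1
            if lo <= hi:
                choices.append(("start_in", lo, hi))
            # anchor end strictly inside, start at/before ROI start
            lo = roi.start + 1
            hi = min(roi.end - 1, roi.start + alen)
            if lo <= hi:
                choices.append(("end_in", lo, hi))
        if not choices:
            return None
        which, lo, hi = choices[int(rng.integers(len(choices)))]
        pos = lo + int(rng.integers(hi - lo + 1))
        sv.roi_used = roi
        if which in ("point", "start_in"):
            return roi.chrom, _anchor_to_start(sv, pos)
        return roi.chrom, _anchor_to_start(sv, pos - alen)

    raise AssertionError(f"unhandled mode {mode}")  # pragma: no cover


class _CatStub:
    """Adapter letting length-fitting helpers work from a placed SV, whose
    category distances were captured at instantiation."""

    def __init__(self, distances):
        self.distances = distances


def _cat_stub(sv: PlacedSV) -> _CatStub:
    return _CatStub(sv.distance_spec)


# ---------------------------------------------------------------------------
# instantiation

def instantiate_category(
    category: SVCategory,
    rng: np.random.Generator,
    start_index: int,
    insertion_pool: Optional[list[str]] = None,
) -> list[PlacedSV]:
    """Create the category's n SV instances: lengths, copy counts, novel
    sequences and zygosity sampled; coordinates unresolved."""
    entry = category.entry
    svs: list[PlacedSV] = []
    for i in range(category.count):
        sv = PlacedSV(
            sv_id=f"sv{start_index + i}",
            sv_type=category.sv_type,
            rule=category.rule,
            category_index=category.index,
            constraints=list(category.constraints),
            interchromosomal=category.interchromosomal,
            special=category.special,
        )
        sv.distance_spec = dict(category.distances)
        if category.special == "SNP":
            sv.lengths = {"A": 1, "B": 1}
        elif category.special in ("trEXP", "trCON"):
            sv.tr_delta = int(
                rng.integers(category.copy_delta[0], category.copy_delta[1] + 1)
            )
        else:
            sv.lengths = sample_lengths(category, rng)
        for op in derive_operations(category.rule):
            if op.variable_copies and op.target_slot is not None:
                sv.copy_counts[op.target_slot] = int(
                    rng.integers(category.copy_range[0], category.copy_range[1] + 1)
                )
            if op.kind is OpKind.NOVEL_INSERT and category.special != "SNP":
                length = sv.lengths.get(op.novel_letter)
                if length:
                    sv.novel_seqs[op.target_slot] = generate_insertion_sequence(
                        length,
                        "random" if insertion_pool is None else insertion_pool,
                        rng,
                    )
        svs.append(sv)
    assign_zygosity(svs, category.zygosity_policy, rng)
    return svs


def from_imported(
    imported: ImportedSV, reference: Reference, sv_id: str, category_index: int
) -> PlacedSV:
    """Convert a VCF-imported SV into a fixed, fully-resolved PlacedSV."""
    sv = PlacedSV(
        sv_id=sv_id,
        sv_type=imported.type_name or imported.rule_string,
        rule=parse_rule(imported.rule_string),
        category_index=category_index,
        haplotypes=imported.genotype,
        fixed=True,
    )
    sv.distance_spec = {}
    chrom, s, e = imported.chrom, imported.start, imported.end
    t = imported.type_name
    if t == "DEL":
        sv.lengths = {"A": e - s}
        sv.placements = {"A": (chrom, s, e)}
        sv.operations = [ResolvedOp(OpKind.DELETE, "A", None, src=(chrom, s, e))]
    elif t == "INV":
        sv.lengths = {"A": e - s}
        sv.placements = {"A": (chrom, s, e)}
        sv.operations = [
            ResolvedOp(
                OpKind.INVERT_IN_PLACE, "A", 0, inverted=True, src=(chrom, s, e)
            )
        ]
    elif t == "DUP":
        sv.lengths = {"A": e - s}
        sv.placements = {"A": (chrom, s, e)}
        sv.operations = [
            ResolvedOp(OpKind.IDENTITY, "A", 0, src=(chrom, s, e)),
            ResolvedOp(
                OpKind.TANDEM_COPY, "A", 1, src=(chrom, s, e), target=(chrom, e)
            ),
        ]
    elif t == "INS":
        if not imported.inserted_sequence:
            raise SVForgeError(
                f"record {imported.record_id}: INS import requires the "
                "inserted sequence (ALT bases or INSSEQ)"
            )
        seq = imported.inserted_sequence
        sv.lengths = {"A": len(seq)}
        sv.placements = {}
        sv.operations = [
            ResolvedOp(
                OpKind.NOVEL_INSERT, "A", 0, target=(chrom, s), seq=seq
            )
        ]
    elif t == "SNP":
        alt = imported.alt_base or "N"
        sv.lengths = {"A": 1, "B": 1}
        sv.placements = {"A": (chrom, s, s + 1)}
        sv.operations = [
            ResolvedOp(OpKind.NOVEL_INSERT, "B", 0, target=(chrom, s), seq=alt),
            ResolvedOp(OpKind.DELETE, "A", None, src=(chrom, s, s + 1)),
        ]
        sv.special = "SNP"
    else:
        raise SVForgeError(
            f"record {imported.record_id}: import of type "
            f"{imported.type_name or imported.rule_string!r} is not supported; "
            "supported types: DEL, INV, DUP, INS, SNP"
        )
    if sv.placements:
        for c, ps, pe in sv.placements.values():
            if not (0 <= ps <= pe <= reference.lengths[c]):
                raise SVForgeError(
                    f"record {imported.record_id}: interval outside contig {c}"
                )
    return sv


# ---------------------------------------------------------------------------
# placement proper

def _binding_constraint(sv: PlacedSV) -> Optional[PlacementConstraint]:
    for c in sv.constraints:
        if c.mode is not OverlapMode.BLACKLIST:
            return c
    return None


def _category_blacklist(
    sv: PlacedSV, rois: ROISet, global_blacklist: ROISet
) -> ROISet:
    extra = []
    for c in sv.constraints:
        if c.mode is OverlapMode.BLACKLIST:
            extra.extend(rois.with_labels(
                sorted(c.roi_labels) if c.roi_labels is not None else None
            ))
    if not extra:
        return global_blacklist
    return ROISet(list(global_blacklist) + extra)


def _place_tandem_repeat(
    sv: PlacedSV,
    constraint: Optional[PlacementConstraint],
    occupied: OccupancyIndex,
    rois: ROISet,
    blacklist: ROISet,
    reference: Reference,
    params: GlobalParams,
    rng: np.random.Generator,
) -> PlacedSV:
    labels = constraint.roi_labels if constraint else None
    candidates = [
        r
        for r in rois.with_labels(sorted(labels) if labels is not None else None)
        if r.label.startswith("TR_") and r.chrom in reference.lengths
    ]
    if not candidates:
        raise PlacementError(
            f"{sv.sv_id} ({sv.sv_type}): no tandem-repeat ROIs "
            "(labels 'TR_<motif>') available"
        )
    k = sv.tr_delta
    for _ in range(params.max_placement_attempts):
        roi = candidates[int(rng.integers(len(candidates)))]
        motif = roi.label.split("TR_", 1)[1]
        unit = len(motif)
        copies = roi.length // unit
        if sv.special == "trCON" and k > copies:
            continue
        if sv.special == "trEXP":
            sv.lengths = {"A": unit}
            sv.copy_counts = {1: k}
        else:
            sv.lengths = {"A": k * unit}
        resolve_layout(sv, roi.chrom, roi.start, reference)
        sv.extra_occupancy = [(roi.chrom, roi.start, roi.end)]
        sv.roi_used = roi
        if _check_candidate(sv, occupied, blacklist, params):
            return sv
    raise PlacementError(
        f"{sv.sv_id} ({sv.sv_type}): no feasible tandem-repeat locus after "
        f"{params.max_placement_attempts} attempts (copy delta {k})"
    )


def place_sv(
    sv: PlacedSV,
    occupied: OccupancyIndex,
    rois: ROISet,
    global_blacklist: ROISet,
    reference: Reference,
    params: GlobalParams,
    rng: np.random.Generator,
) -> PlacedSV:
    """Choose coordinates for one SV by bounded rejection sampling; raises
    :class:`PlacementError` naming the SV, category and binding constraint
    once ``max_placement_attempts`` candidates have been rejected."""
    blacklist = _category_blacklist(sv, rois, global_blacklist)
    constraint = _binding_constraint(sv)
    if sv.special in ("trEXP", "trCON"):
        return _place_tandem_repeat(
            sv, constraint, occupied, rois, blacklist, reference, params, rng
        )
    for _ in range(params.max_placement_attempts):
        pos = _sample_mode_position(sv, constraint, rois, reference, rng)
        if pos is None:
            continue
        chrom, start = pos
        footprint = sv.total_span
        inter = None
        if sv.interchromosomal:
            pre, _ = _split_footprint(sv)
            footprint = pre
            inter = _sample_inter_target(sv, chrom, reference, rng)
            if inter is None:
                continue
        if start < 0 or start + footprint > reference.lengths[chrom]:
            continue
        resolve_layout(sv, chrom, start, reference, inter=inter)
        if _check_candidate(sv, occupied, blacklist, params):
            return sv
    cname = constraint.mode.value if constraint else (
        "blacklist" if sv.constraints else "unconstrained"
    )
    raise PlacementError(
        f"failed to place {sv.sv_id} (type {sv.sv_type}, category "
        f"{sv.category_index}) after {params.max_placement_attempts} attempts; "
        f"binding constraint: {cname}"
    )


def _assign_snp_alt(sv: PlacedSV, reference: Reference, rng: np.random.Generator):
    chrom, s, e = sv.placements["A"]
    ref_base = reference.fetch(chrom, s, s + 1)
    alts = [b for b in _BASES if b != ref_base]
    alt = alts[int(rng.integers(len(alts)))]
    sv.novel_seqs = {0: alt}
    sv.operations = [
        replace(op, seq=alt) if op.kind is OpKind.NOVEL_INSERT else op
        for op in sv.operations
    ]


def _load_insertion_pool(path: str) -> list[str]:
    import pyfaidx

    fa = pyfaidx.Fasta(path)
    pool = [str(fa[name][:]).upper() for name in fa.keys()]
    fa.close()
    if not pool:
        raise SVForgeError(f"insertion sequence file {path} holds no records")
    return pool


def place_all(
    categories: Sequence[SVCategory],
    reference: Reference,
    rois: ROISet,
    blacklist: ROISet,
    params: GlobalParams,
    rng: np.random.Generator,
    imported: Sequence[ImportedSV] = (),
) -> list[PlacedSV]:
    """Instantiate and place every SV; deterministic given config and seed.

    Returns exactly sum(n) + len(imported) placed SVs or raises a
    placement failure.
    """
    # early feasibility diagnostic for exact constraints
    for cat in categories:
        if cat.is_import or cat.special in ("trEXP", "trCON"):
            continue
        for constraint in cat.constraints:
            if constraint.mode is not OverlapMode.EXACT:
                continue
            anchored = constraint.anchored_symbols or tuple(
                t.symbol for t in cat.rule.source
            )
            ranges = [
                cat.distances[s]
                for s in anchored
                if isinstance(cat.distances.get(s), LengthRange)
            ]
            if len(ranges) != len(anchored):
                continue
            lo = sum(r.min for r in ranges)
            hi = sum(r.max for r in ranges)
            admissible = [
                r
                for r in _candidate_rois(constraint, rois)
                if lo <= r.length <= hi
            ]
            if not admissible:
                raise PlacementError(
                    f"variant_sets[{cat.index}] ({cat.sv_type}): exact "
                    f"constraint is infeasible — no ROI has a length in "
                    f"[{lo},{hi}]"
                )

    instances: list[PlacedSV] = []
    counter = 0
    for imp in imported:
        instances.append(from_imported(imp, reference, f"sv{counter}", -1))
        counter += 1
    for cat in categories:
        if cat.is_import:
            continue
        pool = (
            None
            if cat.insertion_source == "random"
            else _load_insertion_pool(cat.insertion_source)
        )
        batch = instantiate_category(cat, rng, counter, insertion_pool=pool)
        counter += len(batch)
        instances.extend(batch)

    occupied = OccupancyIndex()
    placed: list[PlacedSV] = []
    for sv in order_queue(instances):
        if not sv.fixed:
            place_sv(sv, occupied, rois, blacklist, reference, params, rng)
            if sv.special == "SNP":
                _assign_snp_alt(sv, reference, rng)
        occupied.commit(sv, params.allow_cross_haplotype_overlap)
        placed.append(sv)
    return placed


# ---------------------------------------------------------------------------
# standalone constraint audit

def _anchored_span(sv: PlacedSV, constraint: PlacementConstraint
                   ) -> Optional[tuple[str, int, int]]:
    symbols = constraint.anchored_symbols
    if symbols is None:
        symbols = tuple(t.symbol for t in sv.rule.source)
    if symbols == ():
        bk = sv.rule.anchor_breakend or 0
        # breakend anchor: position between source tokens
        offsets = []
        cur = None
        for i, tok in enumerate(sv.rule.source):
            c, s, e = sv.placements[tok.symbol]
            if i == bk:
                return (c, s, s)
            cur = (c, e, e)
        return cur
    ivals = [sv.placements[s] for s in symbols]
    chroms = {c for c, _, _ in ivals}
    if len(chroms) != 1:
        return None
    c = chroms.pop()
    return (c, min(s for _, s, _ in ivals), max(e for _, _, e in ivals))


def audit_placement(
    sv: PlacedSV,
    rois: ROISet,
    global_blacklist: Optional[ROISet] = None,
    contig_lengths: Optional[dict[str, int]] = None,
) -> list[str]:
    """Re-verify a placed SV's declared constraint modes from its final
    coordinates alone; returns violations (empty list = compliant)."""
    problems: list[str] = []
    breakends = sv_breakends(sv)
    for constraint in sv.constraints:
        mode = constraint.mode
        if mode is OverlapMode.BLACKLIST:
            banned = rois.with_labels(
                sorted(constraint.roi_labels)
                if constraint.roi_labels is not None
                else None
            )
            banned_set = ROISet(banned)
            for c, p in breakends:
                if banned_set.containing_point(c, p, strict=True):
                    problems.append(
                        f"{sv.sv_id}: breakend {c}:{p} inside blacklist ROI"
                    )
            continue
        if mode is OverlapMode.TERMINAL:
            if contig_lengths is None:
                continue
            ok = any(
                p == 0 or p == contig_lengths.get(c)
                for c, p in breakends
            )
            if not ok:
                problems.append(f"{sv.sv_id}: no breakend at a chromosome end")
            continue
        if mode is OverlapMode.WHOLE_CHROMOSOME:
            if contig_lengths is None:
                continue
            span = _anchored_span(sv, PlacementConstraint(mode, None, None))
            if span is None or not (
                span[1] == 0 and span[2] == contig_lengths.get(span[0])
            ):
                problems.append(f"{sv.sv_id}: span does not cover a chromosome")
            continue
        span = _anchored_span(sv, constraint)
        if span is None:
            problems.append(f"{sv.sv_id}: anchored span crosses chromosomes")
            continue
        c, s, e = span
        admissible = [
            r
            for r in rois.with_labels(
                sorted(constraint.roi_labels)
                if constraint.roi_labels is not None
                else None
            )
            if r.chrom == c
        ]
        if mode is OverlapMode.EXACT:
            if not any(r.start == s and r.end == e for r in admissible):
                problems.append(
                    f"{sv.sv_id}: span {c}:{s}-{e} does not coincide with an ROI"
                )
        elif mode is OverlapMode.CONTAINED:
            if not any(r.start <= s and e <= r.end for r in admissible):
                problems.append(
                    f"{sv.sv_id}: span {c}:{s}-{e} not contained in an ROI"
                )
        elif mode is OverlapMode.CONTAINING:
            if not any(s <= r.start and r.end <= e for r in admissible):
                problems.append(
                    f"{sv.sv_id}: span {c}:{s}-{e} contains no ROI"
                )
        elif mode is OverlapMode.PARTIAL:
            def inside(p, r):
                return r.start < p < r.end
            if s == e:  # single-breakend anchor
                ok = any(inside(s, r) for r in admissible)
            else:
                ok = any(inside(s, r) != inside(e, r) and
                         (inside(s, r) or inside(e, r))
                         for r in admissible)
            if not ok:
                problems.append(
                    f"{sv.sv_id}: span {c}:{s}-{e} lacks exactly-one-breakend "
                    "ROI overlap"
                )
    return problems
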