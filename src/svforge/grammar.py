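"""Rearrangement grammar: parsing and edit-operation derivation.

A structural rearrangement is written as ``SOURCE→TARGET`` where uppercase
letters name reference intervals, lowercase letters on the target side denote
inversion, ``_`` is a dispersion interval separating distant loci, a ``+``
suffix marks a variable copy number, and ``()`` on the source side anchors a
sub-span (or, when empty, a single breakend) for placement constraints.

Examples: ``ABC→AC`` deletes B; ``A→a`` inverts A; ``ABC→AABCC`` tandem
duplicates A and C; ``ABC→ACB`` translocates B; ``A_→A_A`` makes a dispersed
duplication of A; ``A→AB`` inserts a novel sequence B.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import GrammarError

ARROW = "→"  # canonical arrow in normalized rule strings
_ASCII_ARROW = "->"

__all__ = [
    "SymbolToken",
    "RearrangementRule",
    "EditOperation",
    "OpKind",
    "parse_rule",
    "derive_operations",
    "rule_identifier",
]


class OpKind(str, Enum):
    DELETE = "DELETE"
    INVERT_IN_PLACE = "INVERT_IN_PLACE"
    TANDEM_COPY = "TANDEM_COPY"
    DISPERSED_COPY = "DISPERSED_COPY"
    CUT_PASTE = "CUT_PASTE"
    NOVEL_INSERT = "NOVEL_INSERT"
    IDENTITY = "IDENTITY"


@dataclass(frozen=True)
class SymbolToken:
    """One token of a rule side.

    ``letter`` is the uppercase identity (``None`` for dispersions);
    ``symbol`` is the canonical symbol id used to key length ranges and
    placements: the letter itself, or ``_1``, ``_2``, ... for dispersions
    numbered left to right on their side.
    """

    letter: Optional[str]
    inverted: bool = False
    dispersion: bool = False
    dispersion_index: int = 0  # 1-based, among dispersions on this side
    multiplicity_marker: bool = False
    anchor_member: bool = False
    segment: int = 0  # number of dispersions strictly to the left

    @property
    def symbol(self) -> str:
        if self.dispersion:
            return f"_{self.dispersion_index}"
        assert self.letter is not None
        return self.letter


@dataclass(frozen=True)
class RearrangementRule:
    source: tuple[SymbolToken, ...]
    target: tuple[SymbolToken, ...]
    canonical_string: str
    # Anchored source sub-span: indices into `source` (empty tuple with
    # anchor_breakend set = single-breakend anchor at that source position).
    anchor: Optional[tuple[int, ...]] = None
    anchor_breakend: Optional[int] = None  # token index the '()' sits before

    @property
    def source_letters(self) -> tuple[str, ...]:
        return tuple(t.letter for t in self.source if not t.dispersion)

    @property
    def novel_letters(self) -> tuple[str, ...]:
        src = set(self.source_letters)
        seen: list[str] = []
        for t in self.target:
            if not t.dispersion and t.letter not in src and t.letter not in seen:
                seen.append(t.letter)
        return tuple(seen)

    @property
    def dispersions(self) -> tuple[str, ...]:
        return tuple(t.symbol for t in self.source if t.dispersion)

    @property
    def symbols_needing_length(self) -> tuple[str, ...]:
        """Source letters, dispersions, then novel letters, in rule order."""
        out = [t.symbol for t in self.source]
        out.extend(self.novel_letters)
        return tuple(out)


@dataclass(frozen=True)
class EditOperation:
    kind: OpKind
    source_symbol: Optional[str]  # letter, '_k', or None for NOVEL_INSERT
    target_slot: Optional[int]  # index into rule.target; None for DELETE
    inverted: bool = False
    copy_count: int = 1
    variable_copies: bool = False  # '+' marker: count drawn from copy_range
    novel_letter: Optional[str] = None  # for NOVEL_INSERT


def _split_arrow(expression: str) -> tuple[str, str]:
    expr = expression.strip()
    for arrow in (ARROW, _ASCII_ARROW):
        if arrow in expr:
            parts = expr.split(arrow)
            if len(parts) != 2:
                raise GrammarError(
                    f"expression {expression!r} must contain exactly one arrow"
                )
            if ARROW in parts[0] or ARROW in parts[1] or _ASCII_ARROW in parts[1]:
                raise GrammarError(
                    f"expression {expression!r} must contain exactly one arrow"
                )
            return parts[0].strip(), parts[1].strip()
    raise GrammarError(f"expression {expression!r} has no '→' or '->' separator")


def _tokenize_source(side: str, expr: str) -> tuple[list[SymbolToken], Optional[tuple[int, ...]], Optional[int]]:
    tokens: list[SymbolToken] = []
    anchor_indices: list[int] = []
    anchor_breakend: Optional[int] = None
    in_paren = False
    saw_paren = False
    ndisp = 0
    seen_letters: set[str] = set()
    for ch in side:
        if ch.isspace():
            continue
        if ch == "(":
            if saw_paren:
                raise GrammarError(f"{expr!r}: only one '()' anchor is allowed")
            in_paren = True
            saw_paren = True
            continue
        if ch == ")":
            if not in_paren:
                raise GrammarError(f"{expr!r}: ')' without matching '('")
            in_paren = False
            if not anchor_indices:
                anchor_breakend = len(tokens)
            continue
        if ch == "_":
            ndisp += 1
            tokens.append(
                SymbolToken(
                    letter=None,
                    dispersion=True,
                    dispersion_index=ndisp,
                    anchor_member=in_paren,
                    segment=ndisp - 1,
                )
            )
        elif ch.isalpha() and ch.isupper():
            if ch in seen_letters:
                raise GrammarError(f"{expr!r}: source letter {ch!r} repeats")
            seen_letters.add(ch)
            tokens.append(
                SymbolToken(letter=ch, anchor_member=in_paren, segment=ndisp)
            )
        elif ch.isalpha():
            raise GrammarError(
                f"{expr!r}: lowercase {ch!r} not allowed on the source side"
            )
        elif ch == "+":
            raise GrammarError(f"{expr!r}: '+' not allowed on the source side")
        else:
            raise GrammarError(f"{expr!r}: unexpected character {ch!r}")
        if in_paren:
            anchor_indices.append(len(tokens) - 1)
    if in_paren:
        raise GrammarError(f"{expr!r}: '(' without matching ')'")
    anchor = tuple(anchor_indices) if saw_paren else None
    if saw_paren and not anchor_indices:
        anchor = ()
    return tokens, anchor, anchor_breakend


def _tokenize_target(side: str, expr: str) -> list[SymbolToken]:
    tokens: list[SymbolToken] = []
    ndisp = 0
    for ch in side:
        if ch.isspace():
            continue
        if ch == "_":
            ndisp += 1
            tokens.append(
                SymbolToken(
                    letter=None,
                    dispersion=True,
                    dispersion_index=ndisp,
                    segment=ndisp - 1,
                )
            )
        elif ch == "+":
            if not tokens or tokens[-1].dispersion:
                raise GrammarError(
                    f"{expr!r}: '+' must follow a letter on the target side"
                )
            last = tokens[-1]
            if last.multiplicity_marker:
                raise GrammarError(f"{expr!r}: duplicate '+' marker")
            tokens[-1] = SymbolToken(
                letter=last.letter,
                inverted=last.inverted,
                multiplicity_marker=True,
                segment=last.segment,
            )
        elif ch.isalpha():
            tokens.append(
                SymbolToken(
                    letter=ch.upper(),
                    inverted=ch.islower(),
                    segment=ndisp,
                )
            )
        elif ch in "()":
            raise GrammarError(f"{expr!r}: '()' anchors belong on the source side")
        else:
            raise GrammarError(f"{expr!r}: unexpected character {ch!r}")
    return tokens


def parse_rule(expression: str) -> RearrangementRule:
    """Parse a rearrangement expression into a validated rule.

    Both ``->`` and ``→`` arrows are accepted; the canonical form uses ``→``.
    Target letters absent from the source are treated as novel insertions,
    not errors.
    """
    src_str, tgt_str = _split_arrow(expression)
    source, anchor, anchor_breakend = _tokenize_source(src_str, expression)
    target = _tokenize_target(tgt_str, expression)

    n_src_disp = sum(1 for t in source if t.dispersion)
    n_tgt_disp = sum(1 for t in target if t.dispersion)
    if n_src_disp != n_tgt_disp:
        raise GrammarError(
            f"{expression!r}: dispersion count differs between sides "
            f"({n_src_disp} vs {n_tgt_disp}); dispersions are positionally "
            "matched and must appear on both sides"
        )
    rule = RearrangementRule(
        source=tuple(source),
        target=tuple(target),
        canonical_string="",  # filled below
        anchor=anchor,
        anchor_breakend=anchor_breakend,
    )
    canonical = _render(rule)
    return RearrangementRule(
        source=rule.source,
        target=rule.target,
        canonical_string=canonical,
        anchor=anchor,
        anchor_breakend=anchor_breakend,
    )


def _render(rule: RearrangementRule) -> str:
    src_parts: list[str] = []
    anchor = set(rule.anchor or ())
    for i, t in enumerate(rule.source):
        if rule.anchor is not None:
            if rule.anchor == () and rule.anchor_breakend == i:
                src_parts.append("()")
            if anchor and i == min(anchor):
                src_parts.append("(")
        src_parts.append("_" if t.dispersion else t.letter)
        if anchor and i == max(anchor):
            src_parts.append(")")
    if rule.anchor == () and rule.anchor_breakend == len(rule.source):
        src_parts.append("()")
    tgt_parts: list[str] = []
    for t in rule.target:
        if t.dispersion:
            tgt_parts.append("_")
        else:
            c = t.letter.lower() if t.inverted else t.letter
            tgt_parts.append(c + ("+" if t.multiplicity_marker else ""))
    return "".join(src_parts) + ARROW + "".join(tgt_parts)


def rule_identifier(rule: RearrangementRule) -> str:
    """Deterministic normalized rule string; round-trips through parse_rule."""
    return rule.canonical_string


def _select_in_place_chain(rule: RearrangementRule) -> dict[int, int]:
    """Choose the in-place target occurrence for each source letter.

    Returns a mapping target index → source letter index for the chain of
    tokens considered unmoved. Eligible tokens keep their letter's dispersion
    segment; among them the maximum-length strictly increasing (by source
    order) subsequence with the leftmost target positions wins, so e.g. in
    ``ABC→ACB`` the chain is A,C and B is the translocated letter.
    """
    src_index: dict[str, int] = {}
    src_segment: dict[str, int] = {}
    for i, t in enumerate(rule.source):
        if not t.dispersion:
            src_index[t.letter] = i
            src_segment[t.letter] = t.segment
    eligible: list[tuple[int, int]] = []  # (target pos, source index)
    for j, t in enumerate(rule.target):
        if t.dispersion or t.letter not in src_index:
            continue
        if t.segment != src_segment[t.letter]:
            continue
        eligible.append((j, src_index[t.letter]))
    if not eligible:
        return {}
    # Longest strictly-increasing subsequence on source index over target
    # positions; O(n^2) is fine at grammar scale. best[i] = max chain length
    # ending at eligible[i]; reconstruct preferring smallest target positions.
    n = len(eligible)
    best = [1] * n
    for i in range(n):
        for k in range(i):
            if eligible[k][1] < eligible[i][1]:
                best[i] = max(best[i], best[k] + 1)
    length = max(best)
    # Greedy left-to-right reconstruction of a maximum chain with smallest
    # target positions: pick the leftmost token that can start a chain of the
    # remaining length.
    suffix = [1] * n  # longest chain starting at i
    for i in range(n - 1, -1, -1):
        for k in range(i + 1, n):
            if eligible[i][1] < eligible[k][1]:
                suffix[i] = max(suffix[i], suffix[k] + 1)
    chain: dict[int, int] = {}
    need = length
    last_src = -1
    pos = 0
    while need > 0:
        for i in range(pos, n):
            j, s = eligible[i]
            if s > last_src and suffix[i] >= need:
                chain[j] = s
                last_src = s
                pos = i + 1
                need -= 1
                break
    return chain


def derive_operations(rule: RearrangementRule) -> list[EditOperation]:
    """Derive the ordered edit operations a rule implies.

    One operation per target token (IDENTITY for dispersions), plus one
    DELETE per source letter absent from the target.
    """
    chain = _select_in_place_chain(rule)
    src_letters = rule.source_letters
    tgt_letters = {t.letter for t in rule.target if not t.dispersion}
    chain_slot: dict[str, int] = {
        rule.target[j].letter: j for j in chain
    }
    # Primary occurrence for moved letters: leftmost target occurrence.
    primary_slot: dict[str, int] = {}
    for letter in src_letters:
        if letter in tgt_letters and letter not in chain_slot:
            primary_slot[letter] = next(
                j
                for j, t in enumerate(rule.target)
                if not t.dispersion and t.letter == letter
            )

    def _adjacent_run(slot: int, anchor_slot: int) -> bool:
        """True if `slot` is in the contiguous same-letter run containing
        `anchor_slot` (tandem adjacency, case-insensitive)."""
        letter = rule.target[anchor_slot].letter
        lo = hi = anchor_slot
        while lo > 0 and not rule.target[lo - 1].dispersion and rule.target[lo - 1].letter == letter:
            lo -= 1
        while (
            hi + 1 < len(rule.target)
            and not rule.target[hi + 1].dispersion
            and rule.target[hi + 1].letter == letter
        ):
            hi += 1
        return lo <= slot <= hi

    ops: list[EditOperation] = []
    for j, t in enumerate(rule.target):
        if t.dispersion:
            ops.append(
                EditOperation(
                    kind=OpKind.IDENTITY, source_symbol=t.symbol, target_slot=j
                )
            )
            continue
        letter = t.letter
        if letter not in src_letters:
            ops.append(
                EditOperation(
                    kind=OpKind.NOVEL_INSERT,
                    source_symbol=None,
                    target_slot=j,
                    inverted=t.inverted,
                    variable_copies=t.multiplicity_marker,
                    novel_letter=letter,
                )
            )
            continue
        if j in chain:
            kind = OpKind.INVERT_IN_PLACE if t.inverted else OpKind.IDENTITY
            ops.append(
                EditOperation(
                    kind=kind,
                    source_symbol=letter,
                    target_slot=j,
                    inverted=t.inverted,
                    variable_copies=t.multiplicity_marker,
                )
            )
            continue
        if letter in primary_slot and primary_slot[letter] == j:
            ops.append(
                EditOperation(
                    kind=OpKind.CUT_PASTE,
                    source_symbol=letter,
                    target_slot=j,
                    inverted=t.inverted,
                    variable_copies=t.multiplicity_marker,
                )
            )
            continue
        anchor_slot = chain_slot.get(letter, primary_slot.get(letter))
        src_seg = next(
            s.segment for s in rule.source if not s.dispersion and s.letter == letter
        )
        tandem = (
            t.segment == rule.target[anchor_slot].segment
            and t.segment == src_seg
            and _adjacent_run(j, anchor_slot)
        )
        ops.append(
            EditOperation(
                kind=OpKind.TANDEM_COPY if tandem else OpKind.DISPERSED_COPY,
                source_symbol=letter,
                target_slot=j,
                inverted=t.inverted,
                variable_copies=t.multiplicity_marker,
            )
        )
    for letter in src_letters:
        if letter not in tgt_letters:
            ops.append(
                EditOperation(
                    kind=OpKind.DELETE, source_symbol=letter, target_slot=None
                )
            )
    return ops
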