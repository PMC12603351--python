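"""YAML simulation configuration: parsing, defaults, validation.

A configuration defines one or more SV categories, each the 4-tuple of an SV
type (registry name or grammar expression), breakend-distance ranges, optional
placement constraints, and a count — plus global parameters such as the
reference path, ROI/blacklist BED files, the minimum inter-SV distance and the
random seed. All paths are resolved relative to the config file's directory.

Schema sketch::

    reference: ref.fa
    overlap_regions: [repeats.bed]      # ROI files for constrained placement
    blacklist_regions: [exclude.bed]    # global blacklist (all categories)
    min_intersv_dist: 1000
    allow_cross_haplotype_overlap: false
    homozygous_prob: 0.5
    random_seed: 7
    max_placement_attempts: 100
    variant_sets:
      - type: DEL                       # registry name or e.g. "ABC→b"
        number: 500
        length: [1000, 10000]           # or length_ranges: {A: [..], ...}
        overlap_mode: exact             # partial|exact|contained|containing|
                                        # terminal|whole_chromosome|blacklist
        overlap_region_type: [L1HS]     # admissible ROI labels
      - vcf: known_svs.vcf              # fixed SVs imported verbatim
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Any, Optional, Union

import yaml

from .errors import ConfigError, GrammarError, SVForgeError
from .grammar import RearrangementRule, derive_operations, parse_rule
from .library import SVTypeEntry, lookup_type
from .regions import OverlapMode, PlacementConstraint

__all__ = ["SVCategory", "GlobalParams", "load_config", "validate_category",
           "LengthRange", "Derivation"]

_DERIVATION_RE = re.compile(
    r"^\s*(?P<k>\d+(?:\.\d+)?|\.\d+)\s*\*\s*length\(\s*(?P<sym>[A-Z]|_\d+)\s*\)\s*$"
)


@dataclass(frozen=True)
class LengthRange:
    min: int
    max: int


@dataclass(frozen=True)
class Derivation:
    """Length derived from another symbol's sampled length: ``k*length(X)``."""

    factor: float
    symbol: str
    text: str


@dataclass
class GlobalParams:
    reference_path: str
    roi_files: list[str] = field(default_factory=list)
    blacklist_files: list[str] = field(default_factory=list)
    min_inter_sv_distance: int = 0
    allow_cross_haplotype_overlap: bool = False
    random_seed: int = 0
    max_placement_attempts: int = 100
    homozygous_prob: float = 0.5


@dataclass
class SVCategory:
    """One simulation unit: (type, distance ranges, constraints, count)."""

    sv_type: str
    rule: RearrangementRule
    count: int
    distances: dict[str, Union[LengthRange, Derivation]] = field(default_factory=dict)
    constraints: list[PlacementConstraint] = field(default_factory=list)
    zygosity_policy: float = 0.5
    interchromosomal: bool = False
    insertion_source: str = "random"
    copy_range: tuple[int, int] = (2, 2)
    copy_delta: tuple[int, int] = (1, 5)
    entry: Optional[SVTypeEntry] = None
    vcf_path: Optional[str] = None
    index: int = 0

    @property
    def is_import(self) -> bool:
        return self.vcf_path is not None

    @property
    def special(self) -> Optional[str]:
        return self.entry.special if self.entry else None


def _as_range(value: Any, where: str) -> LengthRange:
    if (
        not isinstance(value, (list, tuple))
        or len(value) != 2
        or not all(isinstance(v, (int, float)) for v in value)
    ):
        raise ConfigError(f"{where}: expected a [min, max] pair, got {value!r}")
    lo, hi = int(value[0]), int(value[1])
    if not (0 < lo <= hi):
        raise ConfigError(f"{where}: range must satisfy 0 < min <= max, got {value!r}")
    return LengthRange(lo, hi)


def _parse_distance(value: Any, where: str) -> Union[LengthRange, Derivation]:
    if isinstance(value, str):
        m = _DERIVATION_RE.match(value)
        if not m:
            raise ConfigError(
                f"{where}: bad length derivation {value!r} "
                "(expected \"k*length(X)\")"
            )
        return Derivation(float(m.group("k")), m.group("sym"), value.strip())
    return _as_range(value, where)


def _resolve_type(raw: str, where: str) -> tuple[RearrangementRule, Optional[SVTypeEntry]]:
    try:
        entry = lookup_type(raw)
        return entry.rule, entry
    except SVForgeError as name_err:
        try:
            return parse_rule(raw), None
        except GrammarError as gram_err:
            raise ConfigError(
                f"{where}: type {raw!r} is neither a registry name "
                f"({name_err}) nor a parseable expression ({gram_err})"
            ) from gram_err


def _anchor_symbols(rule: RearrangementRule) -> Optional[tuple[str, ...]]:
    if rule.anchor is None:
        return None  # whole-SV span
    return tuple(rule.source[i].symbol for i in rule.anchor)


def _parse_category(raw: dict, idx: int, base_dir: str,
                    defaults: GlobalParams) -> SVCategory:
    where = f"variant_sets[{idx}]"
    if not isinstance(raw, dict):
        raise ConfigError(f"{where}: expected a mapping")
    if "vcf" in raw:
        path = os.path.join(base_dir, raw["vcf"])
        return SVCategory(
            sv_type="vcf_import", rule=parse_rule("A→A"), count=0,
            vcf_path=path, index=idx,
        )
    for key in ("type", "number"):
        if key not in raw:
            raise ConfigError(f"{where}: missing required field {key!r}")
    rule, entry = _resolve_type(str(raw["type"]), where)
    count = raw["number"]
    if not isinstance(count, int) or count < 1:
        raise ConfigError(f"{where}: number must be a positive integer, got {count!r}")

    distances: dict[str, Union[LengthRange, Derivation]] = {}
    symbols = rule.symbols_needing_length
    if "length_ranges" in raw:
        lr = raw["length_ranges"]
        if not isinstance(lr, dict):
            raise ConfigError(f"{where}: length_ranges must be a mapping")
        for sym, value in lr.items():
            distances[str(sym)] = _parse_distance(value, f"{where}.length_ranges[{sym}]")
    elif "length" in raw:
        value = raw["length"]
        if isinstance(value, (list, tuple)) and value and isinstance(value[0], (list, tuple)):
            if len(value) != len(symbols):
                raise ConfigError(
                    f"{where}: length gives {len(value)} ranges but the rule "
                    f"has {len(symbols)} symbols ({', '.join(symbols)})"
                )
            for sym, v in zip(symbols, value):
                distances[sym] = _parse_distance(v, f"{where}.length[{sym}]")
        else:
            rng = _as_range(value, f"{where}.length")
            for sym in symbols:
                distances[sym] = rng

    constraints: list[PlacementConstraint] = []
    mode_raw = raw.get("overlap_mode")
    labels_raw = raw.get("overlap_region_type")
    if labels_raw is not None and not isinstance(labels_raw, (list, tuple)):
        labels_raw = [labels_raw]
    if mode_raw is not None:
        try:
            mode = OverlapMode(str(mode_raw))
        except ValueError:
            raise ConfigError(
                f"{where}: unknown overlap_mode {mode_raw!r}; valid modes: "
                + ", ".join(m.value for m in OverlapMode)
            ) from None
        anchored = None if mode is OverlapMode.BLACKLIST else _anchor_symbols(rule)
        constraints.append(
            PlacementConstraint(
                mode=mode,
                roi_labels=frozenset(map(str, labels_raw)) if labels_raw else None,
                anchored_symbols=anchored,
            )
        )
    elif labels_raw is not None:
        raise ConfigError(f"{where}: overlap_region_type given without overlap_mode")

    insertion_source = raw.get("insertion_source", "random")
    if insertion_source != "random":
        insertion_source = os.path.join(base_dir, insertion_source)

    category = SVCategory(
        sv_type=str(raw["type"]),
        rule=rule,
        count=count,
        distances=distances,
        constraints=constraints,
        zygosity_policy=float(raw.get("homozygous_prob", defaults.homozygous_prob)),
        interchromosomal=bool(
            raw.get("interchromosomal", entry.interchromosomal if entry else False)
        ),
        insertion_source=insertion_source,
        copy_range=tuple(raw.get("copy_range", (2, 2))),
        copy_delta=tuple(raw.get("copy_delta", (1, 5))),
        entry=entry,
        index=idx,
    )
    return category


def validate_category(category: SVCategory, params: Optional[GlobalParams] = None
                      ) -> list[str]:
    """Return ordered human-readable diagnostics; empty iff simulable."""
    diags: list[str] = []
    where = f"variant_sets[{category.index}]"
    if category.is_import:
        return diags
    if category.count < 1:
        diags.append(f"{where}: count must be >= 1, got {category.count}")
    if not 0.0 <= category.zygosity_policy <= 1.0:
        diags.append(
            f"{where}: homozygous probability must be in [0,1], "
            f"got {category.zygosity_policy}"
        )
    special = category.special
    needed = () if special in ("SNP", "trEXP", "trCON") else category.rule.symbols_needing_length
    for sym in needed:
        if sym not in category.distances:
            diags.append(f"{where}: missing distance for symbol {sym}")
    for sym in category.distances:
        if sym not in category.rule.symbols_needing_length:
            diags.append(f"{where}: distance given for unknown symbol {sym}")
    # derivation graph: referenced symbols must exist; no cycles
    graph = {
        sym: d.symbol
        for sym, d in category.distances.items()
        if isinstance(d, Derivation)
    }
    for sym, ref in graph.items():
        if ref not in category.distances:
            diags.append(
                f"{where}: derivation for {sym} references undefined symbol {ref}"
            )
        elif ref == sym:
            diags.append(f"{where}: derivation for {sym} references itself")
    for start in graph:
        seen = {start}
        cur = graph.get(start)
        while cur is not None:
            if cur in seen:
                diags.append(
                    f"{where}: derivation cycle involving symbol {start}"
                )
                break
            seen.add(cur)
            cur = graph.get(cur)
    if category.interchromosomal and len(category.rule.dispersions) != 1:
        diags.append(
            f"{where}: interchromosomal requires exactly one dispersion in the "
            f"rule, found {len(category.rule.dispersions)}"
        )
    if special in ("trEXP", "trCON"):
        lo, hi = category.copy_delta
        if not (0 < lo <= hi):
            diags.append(f"{where}: copy_delta must satisfy 0 < min <= max")
        if not category.constraints:
            diags.append(
                f"{where}: {category.sv_type} requires overlap_mode: exact on a "
                "tandem-repeat ROI track (labels starting with 'TR_')"
            )
    lo, hi = category.copy_range
    if not (1 <= lo <= hi):
        diags.append(f"{where}: copy_range must satisfy 1 <= min <= max")
    if params is not None:
        needs_roi = any(
            c.mode not in (OverlapMode.TERMINAL, OverlapMode.WHOLE_CHROMOSOME)
            for c in category.constraints
        )
        roi_sources = list(params.roi_files)
        if category.constraints and needs_roi and not roi_sources and not (
            params.blacklist_files
            and all(c.mode is OverlapMode.BLACKLIST for c in category.constraints)
        ):
            modes = ",".join(c.mode.value for c in category.constraints)
            diags.append(
                f"{where}: constraint ({modes}) requires ROI files, but the "
                "config declares no overlap_regions/blacklist_regions"
            )
    try:
        derive_operations(category.rule)
    except GrammarError as exc:  # pragma: no cover - parse happens earlier
        diags.append(f"{where}: {exc}")
    return diags


def load_config(path: str) -> tuple[GlobalParams, list[SVCategory]]:
    """Parse and validate a YAML simulation configuration.

    Rule expressions are parsed eagerly so grammar errors surface at load
    time; defaults are filled for omitted optional fields. Raises
    :class:`ConfigError` with every diagnostic found.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    base_dir = os.path.dirname(os.path.abspath(path))

    def _paths(key: str) -> list[str]:
        value = raw.get(key, [])
        if isinstance(value, str):
            value = [value]
        return [os.path.join(base_dir, p) for p in value]

    if "reference" not in raw:
        raise ConfigError(f"{path}: missing required field 'reference'")
    params = GlobalParams(
        reference_path=os.path.join(base_dir, raw["reference"]),
        roi_files=_paths("overlap_regions"),
        blacklist_files=_paths("blacklist_regions"),
        min_inter_sv_distance=int(raw.get("min_intersv_dist", 0)),
        allow_cross_haplotype_overlap=bool(
            raw.get("allow_cross_haplotype_overlap", False)
        ),
        random_seed=int(raw.get("random_seed", 0)),
        max_placement_attempts=int(raw.get("max_placement_attempts", 100)),
        homozygous_prob=float(raw.get("homozygous_prob", 0.5)),
    )
    if params.min_inter_sv_distance < 0:
        raise ConfigError("min_intersv_dist must be non-negative")
    if params.max_placement_attempts < 1:
        raise ConfigError("max_placement_attempts must be positive")

    raw_sets = raw.get("variant_sets", [])
    if raw_sets is None:
        raw_sets = []
    if not isinstance(raw_sets, list):
        raise ConfigError(f"{path}: variant_sets must be a list")
    categories = [
        _parse_category(entry, i, base_dir, params) for i, entry in enumerate(raw_sets)
    ]
    diagnostics: list[str] = []
    for cat in categories:
        diagnostics.extend(validate_category(cat, params))
    if diagnostics:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(diagnostics))
    return params, categories
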