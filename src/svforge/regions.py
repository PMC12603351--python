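"""ROIs (BED intervals with labels) and placement constraints."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .errors import ConfigError

__all__ = ["ROI", "ROISet", "OverlapMode", "PlacementConstraint", "read_bed"]


class OverlapMode(str, Enum):
    PARTIAL = "partial"
    EXACT = "exact"
    CONTAINED = "contained"
    CONTAINING = "containing"
    TERMINAL = "terminal"
    WHOLE_CHROMOSOME = "whole_chromosome"
    BLACKLIST = "blacklist"


@dataclass(frozen=True)
class ROI:
    chrom: str
    start: int  # 0-based half-open
    end: int
    label: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ConfigError(
                f"ROI {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PlacementConstraint:
    mode: OverlapMode
    roi_labels: Optional[frozenset[str]] = None  # None = any label
    # Which rule symbols the constraint binds; None = whole SV span
    # (taken from a '()' anchor when the rule has one).
    anchored_symbols: Optional[tuple[str, ...]] = None

    def admits_label(self, label: str) -> bool:
        return self.roi_labels is None or label in self.roi_labels


class ROISet:
    """Labeled genomic intervals with per-chromosome interval indexes."""

    def __init__(self, rois: Iterable[ROI] = ()):
        self.rois: list[ROI] = list(rois)
        self._trees: dict[str, IntervalTree] = {}
        for roi in self.rois:
            self._trees.setdefault(roi.chrom, IntervalTree()).addi(
                roi.start, roi.end, roi
            )

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def labels(self) -> set[str]:
        return {r.label for r in self.rois}

    def with_labels(self, labels: Optional[Iterable[str]]) -> list[ROI]:
        if labels is None:
            return list(self.rois)
        wanted = set(labels)
        return [r for r in self.rois if r.label in wanted]

    def containing_point(self, chrom: str, pos: int, strict: bool = True) -> list[ROI]:
        """ROIs containing breakend position ``pos``.

        With ``strict`` (the default) the ROI boundaries themselves do not
        count as inside, matching the breakend-in-region semantics used by
        partial and blacklist modes.
        """
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        if strict:
            hits = [r for r in hits if r.start < pos < r.end]
        return hits

    def overlapping(self, chrom: str, start: int, end: int) -> list[ROI]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def read_bed(path: str) -> list[ROI]:
    """Read a BED3+ file; column 4, when present, is the region label."""
    rois: list[ROI] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ConfigError(f"{path}:{lineno}: BED line has <3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else ""
            rois.append(ROI(chrom, start, end, label))
    return rois
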