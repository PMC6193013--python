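"""Genomic interval primitives.

All coordinates in this package are 0-based half-open ``[start, end)``;
GTF/GFF input (1-based inclusive) is converted at parse time. The length of
an interval is ``end - start`` and two intervals overlap iff they share at
least one base under this convention — book-ended intervals do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 base (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of integer half-open spans, merging any that share >= 1 base.

    Book-ended spans ([0,50) and [50,80)) are NOT merged: the union of
    overlapping spans is wanted, not the union of touching spans.
    """
    spans = sorted(spans)
    if not spans:
        return []
    out = [list(spans[0])]
    for s, e in spans[1:]:
        if s < out[-1][1]:  # strict: >= 1 shared base
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def merge_touching(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of spans merging overlapping *or* book-ended spans (base-set union)."""
    spans = sorted(spans)
    if not spans:
        return []
    out = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract_intervals(
    span: tuple[int, int], holes: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Maximal sub-spans of ``span`` not covered by ``holes``."""
    start, end = span
    out: list[tuple[int, int]] = []
    pos = start
    for hs, he in merge_touching(holes):
        if he <= start or hs >= end:
            continue
        if hs > pos:
            out.append((pos, min(hs, end)))
        pos = max(pos, he)
        if pos >= end:
            break
    if pos < end:
        out.append((pos, end))
    return out


def spans_contained(
    inner: list[tuple[int, int]], outer: list[tuple[int, int]]
) -> bool:
    """True iff every base of ``inner`` (merged spans) lies inside ``outer``."""
    for s, e in inner:
        if subtract_intervals((s, e), outer):
            return False
    return True
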