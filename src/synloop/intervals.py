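"""Genomic interval primitives shared by every pipeline stage.

All coordinates are 0-based half-open (BED convention).  Intervals are
strandless unless a strand is explicitly attached; every overlap operation
in the pipeline ignores strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open coordinate span ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """Smaller of the two overlap fractions (0 when disjoint)."""
        ov = self.overlap_bp(other)
        if ov == 0:
            return 0.0
        return min(ov / self.length, ov / other.length)

    def span_with(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.chrom != other.chrom:
            raise ValueError("cannot span intervals on different chromosomes")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end)
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class GenomeIntervalIndex:
    """Per-chromosome interval tree for ``O(log n)`` overlap queries.

    Values stored alongside intervals are opaque payloads (row indices,
    records, ...) returned by :meth:`query`.
    """

    def __init__(self, items: Iterable[tuple[GenomicInterval, object]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv, payload in items:
            self.add(iv, payload)

    def add(self, iv: GenomicInterval, payload: object = None) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, iv: GenomicInterval) -> list[tuple[GenomicInterval, object]]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(iv.start, iv.end))
        return [
            (GenomicInterval(iv.chrom, h.begin, h.end), h.data) for h in hits
        ]

    def overlap_bp(self, iv: GenomicInterval) -> int:
        """Number of bases of ``iv`` covered by the union of indexed intervals."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return 0
        # merge hits before summing so stacked peaks are not double counted
        segs = sorted((max(h.begin, iv.start), min(h.end, iv.end))
                      for h in tree.overlap(iv.start, iv.end))
        covered = 0
        cur_s = cur_e = None
        for s, e in segs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        return covered

    def any_overlap(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return tree is not None and bool(tree.overlap(iv.start, iv.end))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping *and abutting* intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # abutting counts as mergeable
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def iter_covered_bases(iv: GenomicInterval) -> Iterator[int]:
    return iter(range(iv.start, iv.end))
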