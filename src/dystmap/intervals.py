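"""Genomic intervals and elementary interval arithmetic.

Coordinates are 0-based, half-open throughout the library; 1-based
inclusive coordinates appear only at the GFF3/VCF-style I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and coalesce overlapping or abutting intervals."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def intersect_two(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of two interval sets (each assumed merged & sorted)."""
    out = []
    for x in a:
        for y in b:
            if x.overlaps(y):
                out.append(
                    GenomicInterval(x.chrom, max(x.start, y.start), min(x.end, y.end))
                )
    return merge_intervals(out)


def intersect_many(
    sets: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Intersection across many interval sets; empty input list is an error."""
    if not sets:
        raise ValueError("intersect_many requires at least one interval set")
    acc = merge_intervals(sets[0])
    for s in sets[1:]:
        acc = intersect_two(acc, merge_intervals(list(s)))
        if not acc:
            break
    return acc


def total_span(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))
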