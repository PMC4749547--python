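"""Reference sequence held as a region of a chromosome.

A full mouse chromosome is ~120 Mb, but only the few kb around the
candidate gene ever need base-level sequence; the rest of the pipeline
works on SNP tables. A :class:`ReferenceRegion` therefore stores the
sequence of one contiguous slice together with its genomic offset, the
same convention as ``samtools faidx chr:start-end`` output.
"""

from __future__ import annotations

from dataclasses import dataclass

VALID_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceRegion:
    """Sequence of [start, start+len(seq)) on `chrom` (0-based half-open)."""

    chrom: str
    start: int
    seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.seq)

    def covers(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def base(self, chrom: str, pos: int) -> str:
        if not self.covers(chrom, pos):
            raise KeyError(f"{chrom}:{pos} outside covered region "
                           f"{self.chrom}:{self.start}-{self.end}")
        return self.seq[pos - self.start]

    def slice(self, start: int, end: int) -> str:
        """Genomic slice [start, end); must lie inside the region."""
        if start < self.start or end > self.end or start > end:
            raise KeyError(f"slice {start}-{end} outside covered region")
        return self.seq[start - self.start : end - self.start]

    def region_id(self) -> str:
        """FASTA record id, 1-based inclusive (`chr12:19990001-20004000`)."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"
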