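"""Recombination-interval mapping from SNP-panel genotypes.

In a backcross of a dominant-mutation carrier (mutation on the B6
haplotype) to FVB, every affected animal must carry B6 DNA at the causal
locus. Strain-of-origin blocks are called per animal from informative
panel SNPs (those whose alleles differ between B6 and FVB), and the
candidate locus is the intersection of carrier-compatible regions across
all affected animals: the recombination breakpoints closest to the locus
in any animal define its edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, intersect_many, merge_intervals, total_span

B6_CARRIER = "B6_carrier"
FVB_HOM = "FVB_homozygous"
UNINFORMATIVE = "uninformative"

#: genotype strings that imply at least one B6 allele
_CARRIER_GENOTYPES = {"B6/FVB", "FVB/B6", "B6/B6"}
_MISSING = {"NA", "", "nan", None}


@dataclass
class StrainMosaic:
    """Per-chromosome strain-of-origin blocks for one mouse.

    Blocks tile each chromosome, are sorted, and adjacent blocks carry
    different labels.
    """

    mouse_id: str
    blocks: dict[str, list[tuple[GenomicInterval, str]]]

    def __post_init__(self) -> None:
        for chrom, blks in self.blocks.items():
            prev_end, prev_label = None, None
            for iv, label in blks:
                if iv.chrom != chrom:
                    raise ValueError(f"block chrom mismatch on {chrom}")
                if prev_end is not None and iv.start != prev_end:
                    raise ValueError(f"blocks do not tile {chrom}")
                if label == prev_label:
                    raise ValueError(f"adjacent equal labels on {chrom}")
                prev_end, prev_label = iv.end, label

    def label_at(self, chrom: str, pos: int) -> str:
        for iv, label in self.blocks.get(chrom, []):
            if iv.contains(chrom, pos):
                return label
        raise KeyError(f"{chrom}:{pos} not covered by mosaic of {self.mouse_id}")

    def carrier_compatible(
        self,
        chrom_lengths: Mapping[str, int],
        min_exclusion_span: int = 0,
    ) -> list[GenomicInterval]:
        """Regions where this mouse may carry B6 (everything not FVB/FVB).

        `min_exclusion_span` is a QC filter: an interior FVB block (one
        flanked by other blocks on both sides) spanning fewer bases is
        treated as a double-crossover or genotyping artifact and counted
        compatible. Filtering acts only in the conservative direction —
        it can widen, never narrow, the carrier-compatible set.
        """
        out = []
        for chrom in chrom_lengths:
            blks = self.blocks.get(
                chrom, [(GenomicInterval(chrom, 0, chrom_lengths[chrom]), UNINFORMATIVE)]
            )
            for i, (iv, label) in enumerate(blks):
                if label != FVB_HOM:
                    out.append(iv)
                elif (
                    min_exclusion_span
                    and 0 < i < len(blks) - 1
                    and len(iv) < min_exclusion_span
                ):
                    out.append(iv)
        return merge_intervals(out)


def _genotype_label(g: Optional[str]) -> str:
    if g in _MISSING or (isinstance(g, float) and np.isnan(g)):
        return UNINFORMATIVE
    if g in _CARRIER_GENOTYPES:
        return B6_CARRIER
    if g == "FVB/FVB":
        return FVB_HOM
    raise ValueError(f"unrecognized genotype {g!r}")


def call_strain_blocks(
    genotypes: Mapping[str, Sequence[Optional[str]]],
    panel: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    mouse_id: str = "mouse",
    boundary: str = "carrier",
) -> StrainMosaic:
    """Call strain-of-origin blocks for one mouse.

    Parameters
    ----------
    genotypes
        Per-chromosome genotype strings aligned with the panel rows of that
        chromosome ("B6/FVB", "FVB/FVB", "B6/B6", or "NA").
    panel
        SNP panel with columns chrom, pos, informative.
    boundary
        "carrier" (default): exclusion-conservative — FVB-homozygous blocks
        span exactly their outermost concordant SNPs; carrier blocks absorb
        the inter-run gaps and the chromosome ends adjacent to them. This
        guarantees (absent a double crossover hidden between two panel
        SNPs) that the causal position of a carrier animal is never placed
        in an FVB block, which is what candidate-interval intersection
        needs.
        "midpoint": block edges at the midpoint between the two informative
        SNPs flanking the inferred crossover (and at chromosome ends);
        unbiased for visualizing breakpoints, but can clip the true locus
        out of a carrier block when the defining crossover shares an
        inter-SNP gap with it.
        "flank": blocks end at the outermost concordant SNP on both sides,
        with explicitly uninformative gaps between blocks and at ends.

    Uninformative and missing SNPs never terminate a block. A chromosome
    with no informative genotyped SNP becomes a single uninformative block.
    """
    if boundary not in ("carrier", "midpoint", "flank"):
        raise ValueError(f"unknown boundary convention {boundary!r}")
    blocks: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for chrom, length in chrom_lengths.items():
        sub = panel[panel["chrom"] == chrom]
        gts = list(genotypes.get(chrom, []))
        if len(sub) != len(gts):
            raise ValueError(
                f"{chrom}: {len(gts)} genotypes for {len(sub)} panel SNPs"
            )
        pos = sub["pos"].to_numpy()
        informative = sub["informative"].to_numpy(dtype=bool)
        calls = [
            (int(p), _genotype_label(g))
            for p, inf, g in zip(pos, informative, gts)
            if inf and _genotype_label(g) != UNINFORMATIVE
        ]
        if not calls:
            blocks[chrom] = [(GenomicInterval(chrom, 0, length), UNINFORMATIVE)]
            continue
        # collapse consecutive concordant calls into runs
        runs: list[tuple[int, int, str]] = []  # (first_pos, last_pos, label)
        for p, lab in calls:
            if runs and runs[-1][2] == lab:
                runs[-1] = (runs[-1][0], p, lab)
            else:
                runs.append((p, p, lab))
        blks: list[tuple[GenomicInterval, str]] = []
        if boundary == "carrier":
            # edges: FVB runs keep [first, last+1); carrier runs take the rest
            edges = [0]
            for (f0, l0, lab0), (f1, _, _) in zip(runs, runs[1:]):
                edges.append(l0 + 1 if lab0 == FVB_HOM else f1)
            edges.append(length)
            for (s, e), (_, _, lab) in zip(zip(edges, edges[1:]), runs):
                blks.append((GenomicInterval(chrom, s, e), lab))
        elif boundary == "midpoint":
            edges = [0]
            for (f0, l0, _), (f1, _, _) in zip(runs, runs[1:]):
                edges.append((l0 + f1) // 2 + 1)
            edges.append(length)
            for (s, e), (_, _, lab) in zip(zip(edges, edges[1:]), runs):
                blks.append((GenomicInterval(chrom, s, e), lab))
        else:  # flank: outermost concordant SNP, uninformative gaps
            cursor = 0
            for first, last, lab in runs:
                if first > cursor:
                    blks.append(
                        (GenomicInterval(chrom, cursor, first), UNINFORMATIVE)
                    )
                blks.append((GenomicInterval(chrom, first, last + 1), lab))
                cursor = last + 1
            if cursor < length:
                blks.append((GenomicInterval(chrom, cursor, length), UNINFORMATIVE))
        blocks[chrom] = blks
    return StrainMosaic(mouse_id=mouse_id, blocks=blocks)


@dataclass
class MappingResult:
    """Shared carrier region across affected animals."""

    intervals: list[GenomicInterval]
    n_mice: int
    diagnostics: list[str] = field(default_factory=list)

    @property
    def total_span(self) -> int:
        return total_span(self.intervals)

    @property
    def is_single_interval(self) -> bool:
        return len(self.intervals) == 1


def shared_carrier_region(
    mosaics: Sequence[StrainMosaic],
    chrom_lengths: Mapping[str, int],
    min_exclusion_span: int = 0,
) -> MappingResult:
    """Intersect carrier-compatible regions across affected mice.

    A genomic position stays in the candidate region iff no mouse is
    FVB-homozygous there (uninformative regions are compatible with
    carrying); interior FVB blocks shorter than `min_exclusion_span` are
    ignored as artifacts. Raises on an empty cohort; an empty intersection
    returns an empty list plus diagnostics naming, per lost region of the
    first mouse, the first mouse that excluded it.
    """
    if not mosaics:
        raise ValueError("shared_carrier_region requires at least one mosaic")
    carrier_sets = [
        m.carrier_compatible(chrom_lengths, min_exclusion_span) for m in mosaics
    ]
    result = intersect_many(carrier_sets)
    diagnostics: list[str] = []
    if not result:
        acc = carrier_sets[0]
        for m, s in zip(mosaics[1:], carrier_sets[1:]):
            from .intervals import intersect_two

            new = intersect_two(acc, s)
            lost = [iv for iv in acc if not any(iv.overlaps(n) for n in new)]
            for iv in lost:
                diagnostics.append(
                    f"{iv.chrom}:{iv.start}-{iv.end} excluded by {m.mouse_id}"
                )
            acc = new
            if not acc:
                break
    return MappingResult(intervals=result, n_mice=len(mosaics), diagnostics=diagnostics)
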