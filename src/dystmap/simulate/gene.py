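"""Toy laminin-like gene model with a planted stop-gain variant.

Builds a multi-exon protein-coding gene whose geometry reproduces the
facts that matter for consequence annotation and the NMD escape rule:

* protein of 1786 residues by default;
* a Leu codon (TTG) at residue 1730 whose T>A substitution at the second
  codon position creates a TAG stop (a transversion), truncating the last
  57 residues;
* the premature stop's last base sits 36 nt upstream of the final
  exon-exon junction, inside the penultimate exon — close enough to the
  final junction (< 50 nt) for the mRNA to escape nonsense-mediated decay;
* a 5'UTR of 271 nt, so the mutated base falls at spliced-transcript
  position 5460 (codon 1730 second position = CDS nt 5189).

Everything is configurable; only self-consistent geometries are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..annotate import TranscriptModel, Variant
from ..reference import ReferenceRegion, revcomp

_BASES = np.array(list("ACGT"))
# sense codons only (no TAA/TAG/TGA), for the random CDS filler
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]
_BALANCED_CODONS = [
    c for c in _SENSE_CODONS if 1 <= sum(b in "GC" for b in c) <= 2
]


@dataclass(frozen=True)
class ToyGeneConfig:
    protein_length: int = 1786       # residues, stop not counted
    mutated_codon: int = 1730        # 1-based residue index of the planted Leu
    ptc_junction_distance: int = 36  # nt, stop's last base -> final junction
    utr5_len: int = 271              # puts the mutated base at transcript nt 5460
    utr3_len: int = 250
    n_exons: int = 5
    intron_len: int = 300
    chrom: str = "chr12"
    gene_start: int = 19_995_000     # within the mapped candidate interval
    strand: str = "+"
    flank: int = 700                 # reference flank kept around the gene
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protein_length < 2:
            raise ValueError("protein_length must be >= 2")
        if not 2 <= self.mutated_codon <= self.protein_length:
            raise ValueError(
                "mutated codon must lie in [2, protein_length] "
                "(codon 1 is the initiator ATG)"
            )
        if self.n_exons < 2:
            raise ValueError("need at least 2 exons for an exon-exon junction")
        if self.ptc_junction_distance < 0:
            raise ValueError("ptc_junction_distance must be >= 0")
        # final junction position in spliced coordinates (0-based offset at
        # which the final exon begins)
        j_final = self.utr5_len + 3 * self.mutated_codon + self.ptc_junction_distance
        if j_final >= self.transcript_length:
            raise ValueError(
                "ptc_junction_distance too large: final exon would be empty"
            )
        # the whole planted codon must sit in the penultimate exon
        penult_start = round(j_final * (self.n_exons - 2) / (self.n_exons - 1))
        if penult_start > self.utr5_len + 3 * (self.mutated_codon - 1):
            raise ValueError(
                "geometry places the planted codon outside the penultimate exon"
            )

    @property
    def cds_length(self) -> int:
        return 3 * (self.protein_length + 1)

    @property
    def transcript_length(self) -> int:
        return self.utr5_len + self.cds_length + self.utr3_len

    @property
    def final_junction(self) -> int:
        return self.utr5_len + 3 * self.mutated_codon + self.ptc_junction_distance


def _exon_lengths(cfg: ToyGeneConfig) -> list[int]:
    """Split the transcript into exons with the final junction fixed."""
    j_final = cfg.final_junction
    cuts = [round(j_final * i / (cfg.n_exons - 1)) for i in range(1, cfg.n_exons - 1)]
    junctions = cuts + [j_final]
    lengths, prev = [], 0
    for j in junctions:
        lengths.append(j - prev)
        prev = j
    lengths.append(cfg.transcript_length - j_final)
    assert all(n > 0 for n in lengths)
    return lengths


def make_toy_gene_model(
    cfg: ToyGeneConfig | None = None,
) -> tuple[ReferenceRegion, TranscriptModel, Variant]:
    """Build (reference region, transcript model, planted variant).

    The returned variant is the T>A substitution converting the planted
    TTG (Leu) codon to TAG, expressed in genomic coordinates on the
    configured strand.
    """
    cfg = cfg or ToyGeneConfig()
    rng = np.random.default_rng(cfg.seed)

    codons = list(rng.choice(_SENSE_CODONS, size=cfg.protein_length + 1))
    # moderate-GC context in a +/-12-codon window around the planted
    # mutation (both 27-nt flanks at 40-52% GC), so a genotyping assay is
    # designable at the site with ordinary primer lengths
    lo = max(1, cfg.mutated_codon - 13)
    hi = min(cfg.protein_length - 1, cfg.mutated_codon + 12)
    for _ in range(500):
        for i in range(lo, hi):
            codons[i] = str(rng.choice(_BALANCED_CODONS))
        codons[cfg.mutated_codon - 1] = "TTG"
        joined = "".join(codons)
        m = 3 * (cfg.mutated_codon - 1) + 1  # mutated base offset in the CDS
        up = joined[max(0, m - 27) : m]
        down = joined[m + 1 : m + 28]
        if all(
            0.40 <= sum(b in "GC" for b in w) / max(len(w), 1) <= 0.52
            for w in (up, down)
        ):
            break
    codons[0] = "ATG"
    codons[-1] = "TAA"
    cds = "".join(codons)
    utr5 = "".join(rng.choice(_BASES, size=cfg.utr5_len))
    utr3 = "".join(rng.choice(_BASES, size=cfg.utr3_len))
    mrna = utr5 + cds + utr3

    lengths = _exon_lengths(cfg)
    # plus-strand exonic sequence, left to right along the genome
    plus_exonic = mrna if cfg.strand == "+" else revcomp(mrna)
    glens = lengths if cfg.strand == "+" else lengths[::-1]

    pieces, exons, cursor, scursor = [], [], cfg.gene_start, 0
    for i, n in enumerate(glens):
        if i > 0:
            intron = "".join(rng.choice(_BASES, size=cfg.intron_len))
            pieces.append(intron)
            cursor += cfg.intron_len
        pieces.append(plus_exonic[scursor : scursor + n])
        exons.append((cursor, cursor + n))
        cursor += n
        scursor += n

    left = "".join(rng.choice(_BASES, size=cfg.flank))
    right = "".join(rng.choice(_BASES, size=cfg.flank))
    region = ReferenceRegion(
        chrom=cfg.chrom,
        start=cfg.gene_start - cfg.flank,
        seq=left + "".join(pieces) + right,
    )

    t = TranscriptModel(
        gene_id="toygene",
        chrom=cfg.chrom,
        strand=cfg.strand,
        exons=tuple(exons),
        cds_start=_cds_edge(cfg, exons, which="start"),
        cds_end=_cds_edge(cfg, exons, which="end"),
    )
    t.validate_cds(region)

    # the mutated base: second position of the planted codon
    toff = cfg.utr5_len + 3 * (cfg.mutated_codon - 1) + 1  # 0-based spliced
    gpos = t.transcript_to_genomic(toff)
    ref_b, alt_b = ("T", "A") if cfg.strand == "+" else ("A", "T")
    variant = Variant(
        chrom=cfg.chrom, pos=gpos, ref=ref_b, alt=alt_b, transcript_pos=toff + 1
    )
    assert region.base(cfg.chrom, gpos) == ref_b
    return region, t, variant


def _t2g(exons: list[tuple[int, int]], strand: str, toff: int) -> int:
    """Spliced offset -> genomic position for a bare exon list."""
    exon_iter = exons if strand == "+" else list(reversed(exons))
    for s, e in exon_iter:
        n = e - s
        if toff < n:
            return s + toff if strand == "+" else e - 1 - toff
        toff -= n
    raise IndexError("offset beyond transcript")


def _cds_edge(cfg: ToyGeneConfig, exons: list[tuple[int, int]], which: str) -> int:
    """Genomic CDS boundary from spliced UTR lengths."""
    g0 = _t2g(exons, cfg.strand, cfg.utr5_len)
    g1 = _t2g(exons, cfg.strand, cfg.utr5_len + cfg.cds_length - 1)
    lo, hi = min(g0, g1), max(g0, g1) + 1
    return lo if which == "start" else hi


def make_variant_table(
    region: ReferenceRegion,
    t: TranscriptModel,
    planted: Variant,
    n_intron_flank: int = 5,
    n_utr3: int = 3,
    seed: int = 0,
) -> list[Variant]:
    """The in-locus variant fixture: the planted stop-gain plus noncoding
    decoys in exon-flanking intron sequence and the 3'UTR.

    Defaults give nine variants of which exactly one is protein-altering.
    """
    rng = np.random.default_rng(seed)
    variants = [planted]
    taken = {planted.pos}

    # exon-flanking intronic positions (within 20 bp of an exon edge)
    intron_candidates: list[int] = []
    for (s0, e0), (s1, _) in zip(t.exons, t.exons[1:]):
        intron_candidates.extend(range(e0, min(e0 + 20, s1)))
        intron_candidates.extend(range(max(s1 - 20, e0), s1))
    picks = rng.choice(len(intron_candidates), size=n_intron_flank, replace=False)
    for i in sorted(picks):
        pos = intron_candidates[int(i)]
        if pos in taken:
            continue
        taken.add(pos)
        variants.append(_random_substitution(region, t.chrom, pos, rng))

    # 3'UTR positions
    t0, t1 = t.cds_transcript_span()
    utr3_offsets = rng.choice(
        np.arange(t1, t.transcript_length), size=n_utr3, replace=False
    )
    for toff in sorted(int(x) for x in utr3_offsets):
        pos = t.transcript_to_genomic(toff)
        if pos in taken:
            continue
        taken.add(pos)
        variants.append(_random_substitution(region, t.chrom, pos, rng))

    return sorted(variants, key=lambda v: v.pos)


def _random_substitution(
    region: ReferenceRegion, chrom: str, pos: int, rng: np.random.Generator
) -> Variant:
    ref = region.base(chrom, pos)
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt)
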