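"""Variant consequence annotation against a single transcript model.

Implements the in-locus candidate filter of the mapping pipeline: classify
each substitution as synonymous / missense / stop-gain / noncoding by
translating the affected codon before and after the change, compute the
truncation length for stop-gains, and apply the 50-nt rule for escape from
nonsense-mediated decay (a premature termination codon less than 50 nt
upstream of the final exon-exon junction, or inside the final exon, leaves
the mRNA stable).

All distances for the NMD rule are measured in spliced transcript (mRNA)
coordinates, from the last base of the stop codon to the final exon-exon
junction, because the rule is defined on the mature message.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from Bio.Seq import Seq

from .intervals import GenomicInterval
from .reference import ReferenceRegion, revcomp, VALID_BASES

_PURINES = frozenset("AG")

ConsequenceClass = str  # {"synonymous", "missense", "stop_gain", "noncoding"}


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide substitution; `pos` is 0-based genomic."""

    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_pos: Optional[int] = None  # 1-based spliced coordinate, if known

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"non-ACGT allele in {self}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt in {self}")

    @property
    def substitution_type(self) -> str:
        """'transition' (purine<->purine / pyr<->pyr) or 'transversion'."""
        same = (self.ref in _PURINES) == (self.alt in _PURINES)
        return "transition" if same else "transversion"


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS geometry of one protein-coding transcript.

    `exons` are genomic 0-based half-open intervals in genomic order;
    `cds_start`/`cds_end` delimit the CDS genomically (half-open), stop
    codon included. Transcript order equals genomic order on '+' and its
    reverse on '-'.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    codon_table: int = 1

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < prev_end:
                raise ValueError("exons must be ordered and non-overlapping")
            prev_end = e
        if self.cds_length % 3 != 0:
            raise ValueError("CDS length not divisible by 3")

    # ---- geometry -------------------------------------------------------

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        n = 0
        for s, e in self.exons:
            n += max(0, min(e, self.cds_end) - max(s, self.cds_start))
        return n

    @property
    def protein_length(self) -> int:
        """Residues in the mature protein (terminal stop not counted)."""
        return self.cds_length // 3 - 1

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """0-based spliced offset of a genomic position, None if intronic."""
        if self.strand == "+":
            off = 0
            for s, e in self.exons:
                if s <= pos < e:
                    return off + (pos - s)
                off += e - s
        else:
            off = 0
            for s, e in reversed(self.exons):
                if s <= pos < e:
                    return off + (e - 1 - pos)
                off += e - s
        return None

    def transcript_to_genomic(self, toff: int) -> int:
        if not 0 <= toff < self.transcript_length:
            raise IndexError(toff)
        exon_iter = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        for s, e in exon_iter:
            n = e - s
            if toff < n:
                return s + toff if self.strand == "+" else e - 1 - toff
            toff -= n
        raise AssertionError("unreachable")

    def spliced_sequence(self, ref: ReferenceRegion) -> str:
        plus = "".join(ref.slice(s, e) for s, e in self.exons)
        return plus if self.strand == "+" else revcomp(plus)

    def cds_transcript_span(self) -> tuple[int, int]:
        """CDS as a half-open span in spliced coordinates."""
        if self.strand == "+":
            t0 = self.genomic_to_transcript(self.cds_start)
            t1 = self.genomic_to_transcript(self.cds_end - 1)
        else:
            t0 = self.genomic_to_transcript(self.cds_end - 1)
            t1 = self.genomic_to_transcript(self.cds_start)
        assert t0 is not None and t1 is not None
        return t0, t1 + 1

    def junctions(self) -> list[int]:
        """Spliced offsets at which each downstream exon begins."""
        out, off = [], 0
        exon_iter = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        for s, e in exon_iter[:-1]:
            off += e - s
            out.append(off)
        return out

    def validate_cds(self, ref: ReferenceRegion) -> None:
        """Check the CDS starts with ATG, ends with a stop, and has no
        internal stop."""
        t0, t1 = self.cds_transcript_span()
        cds = self.spliced_sequence(ref)[t0:t1]
        prot = str(Seq(cds).translate(table=self.codon_table))
        if not cds.startswith("ATG"):
            raise ValueError("CDS does not start with ATG")
        if prot.count("*") != 1 or not prot.endswith("*"):
            raise ValueError("CDS must encode exactly one terminal stop")


@dataclass(frozen=True)
class VariantConsequence:
    """Classification of one substitution against one transcript."""

    vclass: ConsequenceClass
    codon_ref: Optional[str] = None
    codon_alt: Optional[str] = None
    residue_index: Optional[int] = None  # 1-based
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None        # '*' for stop
    truncated_residues: int = 0
    ptc_junction_distance: Optional[int] = None  # nt; None if n/a
    in_final_exon: Optional[bool] = None
    nmd_escape: Optional[bool] = None
    transcript_pos: Optional[int] = None  # 1-based spliced coordinate
    substitution_type: Optional[str] = None
    region: Optional[str] = None  # for noncoding: intergenic/intronic/5'UTR/3'UTR

    @property
    def protein_change(self) -> Optional[str]:
        if self.residue_index is None:
            return None
        alt = "stop" if self.alt_aa == "*" else self.alt_aa
        return f"p.{self.ref_aa}{self.residue_index}{alt}"


def _noncoding(v: Variant, region: str, toff: Optional[int]) -> VariantConsequence:
    return VariantConsequence(
        vclass="noncoding",
        region=region,
        transcript_pos=None if toff is None else toff + 1,
        substitution_type=v.substitution_type,
    )


def annotate_variant(
    v: Variant, t: TranscriptModel, ref: ReferenceRegion
) -> VariantConsequence:
    """Classify a substitution by re-translating its codon.

    Raises ``ValueError`` if the variant is on another chromosome or its
    stated reference base disagrees with the reference sequence.
    """
    if v.chrom != t.chrom:
        raise ValueError(f"variant on {v.chrom}, transcript on {t.chrom}")
    if ref.covers(v.chrom, v.pos) and ref.base(v.chrom, v.pos) != v.ref:
        raise ValueError(
            f"reference mismatch at {v.chrom}:{v.pos + 1}: "
            f"variant says {v.ref}, sequence has {ref.base(v.chrom, v.pos)}"
        )

    toff = t.genomic_to_transcript(v.pos)
    if toff is None:
        within_gene = t.exons[0][0] <= v.pos < t.exons[-1][1]
        return _noncoding(v, "intronic" if within_gene else "intergenic", None)

    cds_t0, cds_t1 = t.cds_transcript_span()
    if toff < cds_t0:
        return _noncoding(v, "5'UTR", toff)
    if toff >= cds_t1:
        return _noncoding(v, "3'UTR", toff)

    mrna = t.spliced_sequence(ref)
    ref_mrna = v.ref if t.strand == "+" else revcomp(v.ref)
    alt_mrna = v.alt if t.strand == "+" else revcomp(v.alt)
    assert mrna[toff] == ref_mrna

    cds_off = toff - cds_t0
    codon_idx = cds_off // 3          # 0-based residue index
    frame = cds_off % 3
    codon_start = cds_t0 + 3 * codon_idx
    codon_ref = mrna[codon_start : codon_start + 3]
    codon_alt = codon_ref[:frame] + alt_mrna + codon_ref[frame + 1 :]

    aa_ref = str(Seq(codon_ref).translate(table=t.codon_table))
    aa_alt = str(Seq(codon_alt).translate(table=t.codon_table))

    base = VariantConsequence(
        vclass="missense",
        codon_ref=codon_ref,
        codon_alt=codon_alt,
        residue_index=codon_idx + 1,
        ref_aa=aa_ref,
        alt_aa=aa_alt,
        transcript_pos=toff + 1,
        substitution_type=v.substitution_type,
    )
    if aa_alt == aa_ref:
        return replace(base, vclass="synonymous")
    if aa_alt == "*" and aa_ref != "*":
        stop_residue = codon_idx + 1
        truncated = t.protein_length - stop_residue + 1
        stop_last = codon_start + 2          # spliced offset of stop's 3rd base
        final_junction = t.junctions()[-1] if t.junctions() else None
        in_final = final_junction is None or stop_last >= final_junction
        dist = None if in_final else final_junction - (stop_last + 1)
        cons = replace(
            base,
            vclass="stop_gain",
            truncated_residues=truncated,
            ptc_junction_distance=dist,
            in_final_exon=in_final,
        )
        return replace(cons, nmd_escape=nmd_escape(cons, t))
    return base  # missense (stop-loss folded in here; terminal codon only)


def nmd_escape(c: VariantConsequence, t: TranscriptModel) -> bool:
    """True iff a stop-gain escapes nonsense-mediated decay.

    Escape requires the premature stop to sit in the final exon or strictly
    less than 50 nt upstream of the final exon-exon junction.
    """
    if c.vclass != "stop_gain":
        raise ValueError("nmd_escape is defined only for stop-gain variants")
    if c.in_final_exon:
        return True
    assert c.ptc_junction_distance is not None
    return c.ptc_junction_distance < 50


@dataclass(frozen=True)
class FilterDecision:
    variant: Variant
    consequence: VariantConsequence
    retained: bool
    reason: str


def filter_candidates(
    variants: Sequence[Variant],
    interval: GenomicInterval,
    t: TranscriptModel,
    ref: ReferenceRegion,
) -> tuple[list[Variant], list[FilterDecision]]:
    """Keep protein-altering variants inside the candidate interval.

    Returns the retained variants and a per-variant decision record with
    the exclusion reason (outside interval, or consequence class).
    """
    retained: list[Variant] = []
    decisions: list[FilterDecision] = []
    for v in variants:
        cons = annotate_variant(v, t, ref)
        if not interval.contains(v.chrom, v.pos):
            decisions.append(FilterDecision(v, cons, False, "outside_interval"))
            continue
        if cons.vclass in ("missense", "stop_gain"):
            retained.append(v)
            decisions.append(FilterDecision(v, cons, True, "protein_altering"))
        else:
            reason = cons.vclass if cons.region is None else f"noncoding:{cons.region}"
            decisions.append(FilterDecision(v, cons, False, reason))
    return retained, decisions
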