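"""Consequence annotation, the NMD 50-nt rule, and candidate filtering."""

from __future__ import annotations

import itertools

import pytest

from dystmap.annotate import (
    TranscriptModel,
    Variant,
    annotate_variant,
    filter_candidates,
    nmd_escape,
)
from dystmap.intervals import GenomicInterval
from dystmap.io import (
    read_variant_table_frame,
    write_variant_table,
)
from dystmap.reference import ReferenceRegion
from dystmap.simulate import ToyGeneConfig, make_toy_gene_model

from .oracles import CODON_TABLE, substitution_class_oracle

LOCUS = GenomicInterval("chr12", 0, 35_000_000)


def _find_codon(region, t, codon: str) -> int:
    """CDS codon index (0-based) of the first occurrence of `codon`."""
    t0, t1 = t.cds_transcript_span()
    cds = t.spliced_sequence(region)[t0:t1]
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] == codon:
            return i // 3
    raise AssertionError(f"codon {codon} absent from CDS")


def test_synonymous_third_position_leucine(default_gene):
    region, t, _ = default_gene
    idx = _find_codon(region, t, "CTG")
    t0, _ = t.cds_transcript_span()
    gpos = t.transcript_to_genomic(t0 + 3 * idx + 2)  # third codon position
    v = Variant("chr12", gpos, "G", "A")  # CTG -> CTA, both Leu
    cons = annotate_variant(v, t, region)
    assert cons.vclass == "synonymous"
    assert cons.codon_ref == "CTG" and cons.codon_alt == "CTA"
    assert cons.truncated_residues == 0


def test_all_576_codon_substitutions_match_codon_table_oracle():
    """Every single-base substitution of every codon classifies as the
    literal codon table dictates."""
    codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
    # one transcript whose CDS concatenates all 64 codons between ATG /
    # stop bookends; two exons so a final junction exists far downstream
    cds = "ATG" + "".join(codons) + "TAA"
    utr5, utr3 = "ACGTAC", "TTGCAA"
    mrna = utr5 + cds + utr3
    exon1_len = len(mrna) - 30
    seq = mrna[:exon1_len] + "G" * 50 + mrna[exon1_len:]
    region = ReferenceRegion("chrT", 0, seq)
    cds_end_g = exon1_len + 50 + (len(utr5) + len(cds) - exon1_len)
    t = TranscriptModel(
        gene_id="g", chrom="chrT", strand="+",
        exons=((0, exon1_len), (exon1_len + 50, len(seq))),
        cds_start=len(utr5), cds_end=cds_end_g,
    )
    checked = 0
    for ci, codon in enumerate(codons, start=1):  # codon 0 is the ATG
        for frame in range(3):
            toff = len(utr5) + 3 * ci + frame
            gpos = t.transcript_to_genomic(toff)
            ref = codon[frame]
            for alt in "ACGT":
                if alt == ref:
                    continue
                cons = annotate_variant(Variant("chrT", gpos, ref, alt), t, region)
                alt_codon = codon[:frame] + alt + codon[frame + 1 :]
                assert cons.vclass == substitution_class_oracle(codon, alt_codon)
                assert cons.codon_ref == codon and cons.codon_alt == alt_codon
                if cons.vclass == "stop_gain":
                    assert 1 <= cons.truncated_residues <= t.protein_length
                checked += 1
    assert checked == 576


class TestNmdRule:
    def test_planted_variant_escapes_at_36_nt(self, default_gene):
        region, t, v = default_gene
        cons = annotate_variant(v, t, region)
        assert cons.ptc_junction_distance == 36
        assert nmd_escape(cons, t) is True

    def test_distance_exactly_50_does_not_escape(self):
        cfg = ToyGeneConfig(
            protein_length=300, mutated_codon=200, ptc_junction_distance=50,
            utr5_len=40, utr3_len=40, n_exons=3, intron_len=90,
            gene_start=2000, flank=60,
        )
        region, t, v = make_toy_gene_model(cfg)
        cons = annotate_variant(v, t, region)
        assert cons.ptc_junction_distance == 50
        assert nmd_escape(cons, t) is False

    def test_distance_49_escapes(self):
        cfg = ToyGeneConfig(
            protein_length=300, mutated_codon=200, ptc_junction_distance=49,
            utr5_len=40, utr3_len=40, n_exons=3, intron_len=90,
            gene_start=2000, flank=60,
        )
        region, t, v = make_toy_gene_model(cfg)
        assert annotate_variant(v, t, region).nmd_escape is True

    def test_ptc_in_final_exon_escapes(self, default_gene):
        region, t, _ = default_gene
        t0, _ = t.cds_transcript_span()
        final_start = t.junctions()[-1]
        first_final_codon = (final_start - t0 + 2) // 3 + 1
        mrna = t.spliced_sequence(region)
        for ci in range(first_final_codon, t.protein_length):
            codon = mrna[t0 + 3 * ci : t0 + 3 * ci + 3]
            for frame in range(3):
                for alt in "ACGT":
                    if alt == codon[frame]:
                        continue
                    alt_codon = codon[:frame] + alt + codon[frame + 1 :]
                    if CODON_TABLE[alt_codon] != "*":
                        continue
                    gpos = t.transcript_to_genomic(t0 + 3 * ci + frame)
                    cons = annotate_variant(
                        Variant("chr12", gpos, codon[frame], alt), t, region
                    )
                    assert cons.vclass == "stop_gain"
                    assert cons.in_final_exon is True
                    assert nmd_escape(cons, t) is True
                    return
        raise AssertionError("no final-exon stop-gain constructible")

    def test_rejects_non_stop_gain(self, default_gene):
        region, t, _ = default_gene
        idx = _find_codon(region, t, "CTG")
        t0, _ = t.cds_transcript_span()
        gpos = t.transcript_to_genomic(t0 + 3 * idx + 2)
        cons = annotate_variant(Variant("chr12", gpos, "G", "A"), t, region)
        with pytest.raises(ValueError):
            nmd_escape(cons, t)


def test_noncoding_classes(default_gene):
    region, t, _ = default_gene
    # intronic: base just inside the first intron
    intron_pos = t.exons[0][1] + 5
    cons = annotate_variant(
        Variant("chr12", intron_pos,
                region.base("chr12", intron_pos),
                "A" if region.base("chr12", intron_pos) != "A" else "C"),
        t, region)
    assert cons.vclass == "noncoding" and cons.region == "intronic"
    # 3'UTR: last transcript base
    utr_pos = t.transcript_to_genomic(t.transcript_length - 1)
    cons = annotate_variant(
        Variant("chr12", utr_pos,
                region.base("chr12", utr_pos),
                "A" if region.base("chr12", utr_pos) != "A" else "C"),
        t, region)
    assert cons.vclass == "noncoding" and cons.region == "3'UTR"


def test_reference_mismatch_rejected(default_gene):
    region, t, v = default_gene
    wrong = Variant(v.chrom, v.pos, "C" if v.ref != "C" else "G", v.alt)
    with pytest.raises(ValueError, match="reference mismatch"):
        annotate_variant(wrong, t, region)


def test_minus_strand_gene_annotates_identically():
    """The same geometry built on the minus strand yields the same
    consequence (strand consistency)."""
    results = []
    for strand in "+-":
        cfg = ToyGeneConfig(strand=strand, seed=5)
        region, t, v = make_toy_gene_model(cfg)
        c = annotate_variant(v, t, region)
        results.append((c.vclass, c.codon_ref, c.codon_alt, c.residue_index,
                        c.truncated_residues, c.ptc_junction_distance,
                        c.nmd_escape))
    assert results[0] == results[1]
    assert results[0][0] == "stop_gain"


class TestFilterCandidates:
    def test_nine_variant_fixture_retains_exactly_the_stop_gain(
        self, default_gene, nine_variants
    ):
        region, t, planted = default_gene
        retained, decisions = filter_candidates(nine_variants, LOCUS, t, region)
        assert len(nine_variants) == 9
        assert retained == [planted]
        reasons = sorted(d.reason for d in decisions if not d.retained)
        assert all(r.startswith("noncoding") for r in reasons)
        assert {"noncoding:intronic", "noncoding:3'UTR"} <= set(reasons)

    def test_empty_variant_list(self, default_gene):
        region, t, _ = default_gene
        retained, decisions = filter_candidates([], LOCUS, t, region)
        assert retained == [] and decisions == []

    def test_outside_interval_excluded(self, default_gene):
        region, t, planted = default_gene
        tiny = GenomicInterval("chr12", 0, 100)
        retained, decisions = filter_candidates([planted], tiny, t, region)
        assert retained == []
        assert decisions[0].reason == "outside_interval"

    def test_random_variant_sets_match_reannotation_oracle(self, default_gene):
        """Retention equals independent containment + codon-table check."""
        import numpy as np

        region, t, _ = default_gene
        rng = np.random.default_rng(2)
        positions = rng.integers(region.start, region.end, size=120)
        variants = []
        for pos in sorted(set(int(p) for p in positions)):
            ref = region.base("chr12", pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variants.append(Variant("chr12", pos, ref, alt))
        retained, _ = filter_candidates(variants, LOCUS, t, region)
        expected = []
        t0, t1 = t.cds_transcript_span()
        mrna = t.spliced_sequence(region)
        for v in variants:
            if not LOCUS.contains(v.chrom, v.pos):
                continue
            toff = t.genomic_to_transcript(v.pos)
            if toff is None or not (t0 <= toff < t1):
                continue
            ci, frame = divmod(toff - t0, 3)
            codon = mrna[t0 + 3 * ci : t0 + 3 * ci + 3]
            alt_mrna = v.alt if t.strand == "+" else \
                {"A": "T", "T": "A", "C": "G", "G": "C"}[v.alt]
            alt_codon = codon[:frame] + alt_mrna + codon[frame + 1 :]
            if substitution_class_oracle(codon, alt_codon) in (
                "missense", "stop_gain"
            ):
                expected.append(v)
        assert retained == expected


def test_variant_table_round_trip(default_gene, nine_variants, tmp_path):
    region, t, _ = default_gene
    _, decisions = filter_candidates(nine_variants, LOCUS, t, region)
    path = tmp_path / "annotated.tsv"
    write_variant_table([d.variant for d in decisions], path, decisions=decisions)
    frame = read_variant_table_frame(path)
    assert len(frame) == 9
    by_pos = frame.set_index("POS")
    for d in decisions:
        row = by_pos.loc[d.variant.pos + 1]
        assert row["consequence"] == d.consequence.vclass
        assert bool(row["retained"]) == d.retained
        if d.consequence.vclass == "stop_gain":
            assert int(row["truncated_residues"]) == 57
            assert int(row["ptc_junction_distance"]) == 36
            assert bool(row["nmd_escape"]) is True
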