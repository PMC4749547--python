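"""Readers and writers for the pipeline's plain-text formats.

Conventions: internal coordinates are 0-based half-open; GFF3 and the
VCF-like variant table are 1-based inclusive on disk; BED is 0-based
half-open. The reference FASTA stores a region of a chromosome under a
``chrom:start-end`` record id (1-based inclusive), the samtools-faidx
region convention.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import FilterDecision, TranscriptModel, Variant
from .intervals import GenomicInterval
from .mapping import StrainMosaic
from .reference import ReferenceRegion
from .spiketrain import SpikeTrain

_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


# ---------------------------------------------------------------- FASTA

def write_fasta(region: ReferenceRegion, path: str | Path) -> None:
    rec = SeqRecord(Seq(region.seq), id=region.region_id(), description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path) -> ReferenceRegion:
    rec = next(SeqIO.parse(str(path), "fasta"))
    m = _REGION_RE.match(rec.id)
    if m:
        chrom, start = m.group("chrom"), int(m.group("start")) - 1
    else:
        chrom, start = rec.id, 0
    return ReferenceRegion(chrom=chrom, start=start, seq=str(rec.seq).upper())


# ----------------------------------------------------------------- GFF3

def write_gff3(t: TranscriptModel, path: str | Path, source: str = "dystmap") -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive."""
    lines = ["##gff-version 3"]
    gene_s, gene_e = t.exons[0][0] + 1, t.exons[-1][1]
    gid, tid = t.gene_id, f"{t.gene_id}.t1"

    def row(ftype: str, s: int, e: int, attrs: str) -> str:
        return "\t".join(
            [t.chrom, source, ftype, str(s), str(e), ".", t.strand, ".", attrs]
        )

    lines.append(row("gene", gene_s, gene_e, f"ID={gid}"))
    lines.append(row("mRNA", gene_s, gene_e, f"ID={tid};Parent={gid}"))
    for i, (s, e) in enumerate(t.exons, 1):
        lines.append(row("exon", s + 1, e, f"ID={tid}.exon{i};Parent={tid}"))
        cs, ce = max(s, t.cds_start), min(e, t.cds_end)
        if cs < ce:
            lines.append(row("CDS", cs + 1, ce, f"ID={tid}.cds;Parent={tid}"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> TranscriptModel:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    mrna = next(db.features_of_type("mRNA"))
    exons = sorted(
        (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
    )
    cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
    gene = next(db.features_of_type("gene"))
    return TranscriptModel(
        gene_id=gene.id,
        chrom=mrna.seqid,
        strand=mrna.strand,
        exons=tuple(exons),
        cds_start=cds[0][0],
        cds_end=cds[-1][1],
    )


# --------------------------------------------------- variant table (TSV)

_VCFISH_COLUMNS = ["CHROM", "POS", "REF", "ALT"]

_ANNOTATION_COLUMNS = [
    "consequence", "codon_change", "protein_change", "truncated_residues",
    "ptc_junction_distance", "in_final_exon", "nmd_escape",
    "transcript_pos", "substitution_type", "region", "retained", "reason",
]


def write_variant_table(
    variants: Sequence[Variant],
    path: str | Path,
    decisions: Optional[Sequence[FilterDecision]] = None,
) -> None:
    """VCF-like TSV (POS 1-based); annotation columns when decisions given."""
    rows = []
    by_variant = {d.variant: d for d in decisions} if decisions else {}
    for v in variants:
        row = {"CHROM": v.chrom, "POS": v.pos + 1, "REF": v.ref, "ALT": v.alt}
        d = by_variant.get(v)
        if d is not None:
            c = d.consequence
            row.update({
                "consequence": c.vclass,
                "codon_change": (f"{c.codon_ref}>{c.codon_alt}"
                                 if c.codon_ref else ""),
                "protein_change": c.protein_change or "",
                "truncated_residues": c.truncated_residues,
                "ptc_junction_distance": (
                    "" if c.ptc_junction_distance is None
                    else c.ptc_junction_distance),
                "in_final_exon": "" if c.in_final_exon is None else c.in_final_exon,
                "nmd_escape": "" if c.nmd_escape is None else c.nmd_escape,
                "transcript_pos": "" if c.transcript_pos is None else c.transcript_pos,
                "substitution_type": c.substitution_type or "",
                "region": c.region or "",
                "retained": d.retained,
                "reason": d.reason,
            })
        rows.append(row)
    cols = _VCFISH_COLUMNS + (_ANNOTATION_COLUMNS if decisions else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t")
    return [
        Variant(chrom=str(r.CHROM), pos=int(r.POS) - 1, ref=r.REF, alt=r.ALT)
        for r in df.itertuples()
    ]


def read_variant_table_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------- genotypes & panel

def write_genotype_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index_label="mouse_id")


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="mouse_id", keep_default_na=False)


def write_snp_panel(panel: pd.DataFrame, path: str | Path) -> None:
    out = panel.copy()
    out["pos"] = out["pos"] + 1  # 1-based on disk
    out.to_csv(path, sep="\t", index=False)


def read_snp_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t")
    panel["pos"] = panel["pos"] - 1
    panel["informative"] = panel["informative"].astype(bool)
    return panel


# -------------------------------------------------------------------- BED

def write_bed(
    intervals: Sequence[GenomicInterval], path: str | Path,
    names: Optional[Sequence[str]] = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, s, e = line.split("\t")[:3]
        out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def write_mosaic_bed(mosaics: Sequence[StrainMosaic], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in mosaics:
            for chrom in m.blocks:
                for iv, label in m.blocks[chrom]:
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{m.mouse_id}:{label}\n"
                    )


# ------------------------------------------------------------ spike data

def write_spike_csv(
    trains: Sequence[SpikeTrain], spike_path: str | Path, meta_path: str | Path
) -> None:
    """Spike-time CSV (cell_id, t_seconds, posture_label) + cell metadata TSV."""
    rows = []
    meta = []
    for tr in trains:
        meta.append({
            "cell_id": tr.cell_id, "cell_class": tr.cell_class,
            "genotype": tr.genotype, "posture_state": tr.posture_state,
            "duration": tr.duration,
        })
        for t in tr.times:
            rows.append({"cell_id": tr.cell_id, "t_seconds": t,
                         "posture_label": tr.posture_state})
    pd.DataFrame(rows, columns=["cell_id", "t_seconds", "posture_label"]).to_csv(
        spike_path, index=False, float_format="%.9f"
    )
    pd.DataFrame(meta).to_csv(meta_path, sep="\t", index=False)


def read_spike_csv(spike_path: str | Path, meta_path: str | Path) -> list[SpikeTrain]:
    spikes = pd.read_csv(spike_path)
    meta = pd.read_csv(meta_path, sep="\t")
    trains = []
    grouped = spikes.groupby("cell_id")["t_seconds"]
    for r in meta.itertuples():
        times = (
            grouped.get_group(r.cell_id).to_numpy()
            if r.cell_id in grouped.groups else []
        )
        trains.append(SpikeTrain(
            cell_id=r.cell_id, cell_class=r.cell_class, genotype=r.genotype,
            posture_state=r.posture_state, times=times, duration=float(r.duration),
        ))
    return trains


# ---------------------------------------------------------- chrom sizes

def write_chrom_sizes(chrom_lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, n in chrom_lengths.items():
            fh.write(f"{chrom}\t{n}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            chrom, n = line.split("\t")
            out[chrom] = int(n)
    return out


# --------------------------------------------------------------- litters

def write_litters(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_litters(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
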