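#!/usr/bin/env python
"""Annotate the in-locus variants and filter to protein-altering changes.

Reads the reference, gene model, variant table, and the candidate region
from the previous steps; classifies every substitution by codon
re-translation; applies the NMD 50-nt escape rule to stop-gains; and
writes the annotated table under results/variants.
"""

import argparse
from pathlib import Path

from dystmap import io as dio
from dystmap.annotate import filter_candidates

ap = argparse.ArgumentParser()
ap.add_argument("--indir", type=Path, default=Path("scratch/inputs"))
ap.add_argument("--mapdir", type=Path, default=Path("results/mapping"))
ap.add_argument("--outdir", type=Path, default=Path("results/variants"))
args = ap.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

region = dio.read_fasta(args.indir / "reference.fa")
transcript = dio.read_gff3(args.indir / "gene.gff3")
variants = dio.read_variant_table(args.indir / "variants.tsv")
candidate = [iv for iv in dio.read_bed(args.mapdir / "candidate_region.bed")
             if iv.chrom == transcript.chrom]
if not candidate:
    raise SystemExit("candidate region does not include the gene's chromosome")

retained, decisions = filter_candidates(variants, candidate[0], transcript,
                                        region)
dio.write_variant_table([d.variant for d in decisions],
                        args.outdir / "variants_annotated.tsv",
                        decisions=decisions)

print(f"{len(variants)} variants in the locus; {len(retained)} retained as "
      f"protein-altering")
for d in decisions:
    c = d.consequence
    tag = "RETAINED" if d.retained else f"excluded ({d.reason})"
    extra = ""
    if c.vclass == "stop_gain":
        extra = (f"; truncates {c.truncated_residues} aa, PTC "
                 f"{c.ptc_junction_distance} nt from final junction, "
                 f"NMD escape={c.nmd_escape}")
    print(f"  {d.variant.chrom}:{d.variant.pos + 1} {d.variant.ref}>"
          f"{d.variant.alt} {c.vclass} {c.protein_change or ''} {tag}{extra}")
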