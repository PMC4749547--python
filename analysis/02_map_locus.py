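#!/usr/bin/env python
"""Map the candidate locus by intersecting carrier regions.

Reads the SNP panel and affected-cohort genotypes written by step 01,
calls strain-of-origin blocks per animal, intersects the
carrier-compatible regions, and writes the candidate interval BED plus a
plain-text report under results/mapping.
"""

import argparse
from pathlib import Path

from dystmap import io as dio
from dystmap.mapping import call_strain_blocks, shared_carrier_region

ap = argparse.ArgumentParser()
ap.add_argument("--indir", type=Path, default=Path("scratch/inputs"))
ap.add_argument("--outdir", type=Path, default=Path("results/mapping"))
ap.add_argument("--min-exclusion-span", type=int, default=10_000_000)
args = ap.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

panel = dio.read_snp_panel(args.indir / "snp_panel.tsv")
genotypes = dio.read_genotype_matrix(args.indir / "genotypes.tsv")
chrom_lengths = dio.read_chrom_sizes(args.indir / "chrom.sizes")
affected = (args.indir / "affected.txt").read_text().split()

mosaics = []
for mouse_id in affected:
    row = genotypes.loc[mouse_id]
    per_chrom = {
        chrom: [row[sid] for sid in panel[panel.chrom == chrom]["snp_id"]]
        for chrom in chrom_lengths
    }
    mosaics.append(call_strain_blocks(per_chrom, panel, chrom_lengths,
                                      mouse_id=mouse_id))

mapping = shared_carrier_region(mosaics, chrom_lengths,
                                min_exclusion_span=args.min_exclusion_span)
dio.write_bed(mapping.intervals, args.outdir / "candidate_region.bed")
dio.write_mosaic_bed(mosaics, args.outdir / "mosaics.bed")

lines = [f"{len(mosaics)} affected mice intersected",
         f"candidate region spans {mapping.total_span / 1e6:.1f} Mb in "
         f"{len(mapping.intervals)} interval(s):"]
lines += [f"  {iv.chrom}:{iv.start}-{iv.end}" for iv in mapping.intervals]
(args.outdir / "mapping_report.txt").write_text("\n".join(lines) + "\n")
print("\n".join(lines))
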