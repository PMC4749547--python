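#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes the toy gene (FASTA + GFF3), the nine-variant in-locus table, the
SNP panel and genotypes of the 24-animal affected mapping cohort, the
het x het / WT x het litter tables, and the calibrated spike-train
cohorts. Bulky raw files land under scratch/inputs; everything later
steps read comes from there.
"""

import argparse
from pathlib import Path

import pandas as pd

from dystmap import io as dio
from dystmap.simulate import (
    LitterSpec,
    ToyGeneConfig,
    make_toy_gene_model,
    make_variant_table,
    simulate_litters,
)
from dystmap.simulate.cross import Cohort, simulate_mapping_cohort
from dystmap.simulate.spikes import full_reference_cohort

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("scratch/inputs"))
args = ap.parse_args()
out = args.outdir
out.mkdir(parents=True, exist_ok=True)

region, transcript, planted = make_toy_gene_model(ToyGeneConfig(seed=args.seed))
dio.write_fasta(region, out / "reference.fa")
dio.write_gff3(transcript, out / "gene.gff3")
variants = make_variant_table(region, transcript, planted, seed=args.seed)
dio.write_variant_table(variants, out / "variants.tsv")
print(f"toy gene: {transcript.protein_length} aa protein, planted "
      f"{planted.ref}>{planted.alt} at {planted.chrom}:{planted.pos + 1} "
      f"(transcript nt {planted.transcript_pos}); {len(variants)} in-locus variants")

spec, affected = simulate_mapping_cohort(seed=args.seed)
dio.write_snp_panel(spec.panel_frame(), out / "snp_panel.tsv")
dio.write_genotype_matrix(Cohort(spec=spec, mice=affected).genotype_frame(),
                          out / "genotypes.tsv")
dio.write_chrom_sizes(spec.chrom_lengths, out / "chrom.sizes")
(out / "affected.txt").write_text(
    "\n".join(m.mouse_id for m in affected) + "\n")
print(f"mapping cohort: {len(affected)} affected mice, "
      f"{len(spec.panel_frame())} panel SNPs "
      f"({int(spec.panel_frame().informative.sum())} informative)")

hh = simulate_litters(LitterSpec(("het", "het"), n_litters=200, seed=args.seed))
wh = simulate_litters(LitterSpec(("WT", "het"), n_litters=200,
                                 seed=args.seed + 1))
dio.write_litters(pd.concat([hh, wh], ignore_index=True), out / "litters.tsv")
print(f"litters: {len(hh)} het x het + {len(wh)} WT x het")

trains = full_reference_cohort(seed=args.seed)
dio.write_spike_csv(trains, out / "spikes.csv", out / "cells.tsv")
print(f"spike trains: {len(trains)} cells, "
      f"{sum(t.n_spikes for t in trains)} spikes total")
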