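#!/usr/bin/env python
"""Firing statistics of the simulated cerebellar cohorts.

Reads the spike-time CSV from step 01, computes per-cell average firing
rate, predominant firing rate (reciprocal mode ISI), and CV ISI,
summarizes per (cell class x genotype x posture) group, compares groups
with KS and Mann-Whitney tests, and reports the predominant-rate fold
ratios of the mutant-during-abnormal-postures group.
"""

import argparse
from pathlib import Path

from dystmap import io as dio
from dystmap.spiketrain import (
    compare_all,
    fold_ratios,
    per_cell_table,
    reference_summary_frame,
    summarize_groups,
)

ap = argparse.ArgumentParser()
ap.add_argument("--indir", type=Path, default=Path("scratch/inputs"))
ap.add_argument("--outdir", type=Path, default=Path("results/spikes"))
ap.add_argument("--bin-width", type=float, default=0.001)
args = ap.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

trains = dio.read_spike_csv(args.indir / "spikes.csv", args.indir / "cells.tsv")
cells = per_cell_table(trains, bin_width=args.bin_width)
summary = summarize_groups(trains, bin_width=args.bin_width)
comparisons = compare_all(trains, bin_width=args.bin_width)
folds = fold_ratios(summary)

cells.to_csv(args.outdir / "per_cell_stats.tsv", sep="\t", index=False)
summary.to_csv(args.outdir / "group_summary.tsv", sep="\t", index=False)
comparisons.to_csv(args.outdir / "group_comparisons.tsv", sep="\t", index=False)
folds.to_csv(args.outdir / "fold_ratios.tsv", sep="\t", index=False)

print("group summary (mean ± SEM):")
for _, r in summary.iterrows():
    print(f"  {r.cell_class:9s} {r.group:18s} n={r.n_cells:3d}  "
          f"avg {r.average_fr_mean:6.1f}±{r.average_fr_sem:4.1f} Hz  "
          f"pred {r.predominant_fr_mean:6.1f}±{r.predominant_fr_sem:4.1f} Hz  "
          f"CV {r.cv_isi_mean:5.3f}±{r.cv_isi_sem:5.3f}")

ref = reference_summary_frame().set_index(["cell_class", "group"])
got = summary.set_index(["cell_class", "group"])
print("recovery of published group means (predominant f.r. / CV ISI):")
for key in ref.index:
    for col in ("predominant_fr_mean", "cv_isi_mean"):
        rel = 100 * (got.loc[key, col] - ref.loc[key, col]) / ref.loc[key, col]
        print(f"  {key[0]:9s} {key[1]:18s} {col:20s} {rel:+5.1f}%")

dcn = folds[(folds.cell_class == "DCN")
            & (folds.statistic_name == "predominant_fr")]
for r in dcn.itertuples():
    print(f"DCN predominant f.r. fold, mutant-abnormal {r.comparison}: "
          f"{r.ratio:.2f}x")
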