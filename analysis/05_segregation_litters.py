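#!/usr/bin/env python
"""Segregation arithmetic: dominant transmission and homozygous lethality.

Reproduces the inheritance numbers — the 140/272 (51.5%) symptomatic
proportion, the 157/302 heterozygote-transmission check, the 25%
Mendelian homozygote expectation — and compares simulated het x het
versus WT x het litter sizes with the two-tailed t-test.
"""

import argparse
from pathlib import Path

import pandas as pd

from dystmap import io as dio
from dystmap.genetics import (
    SegregationCounts,
    litter_deficit,
    mendelian_homozygote_fraction,
    penetrance_estimate,
    transmission_test,
)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--indir", type=Path, default=Path("scratch/inputs"))
ap.add_argument("--outdir", type=Path, default=Path("results/segregation"))
args = ap.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

rows = []

pen = penetrance_estimate(SegregationCounts(272, 140, 0.5))
rows.append({"quantity": "symptomatic_with_one_WT_parent",
             "value": f"140/272 = {100 * pen.proportion:.1f}%",
             "ci95": f"[{pen.ci_low:.3f}, {pen.ci_high:.3f}]",
             "p_value": pen.p_value})
print(f"dominant inheritance: 140/272 = {100 * pen.proportion:.1f}% "
      f"symptomatic (exact p vs 50%: {pen.p_value:.3f} -> compatible)")

trans = transmission_test(302, 157)
rows.append({"quantity": "heterozygote_transmission",
             "value": f"157/302 = {100 * trans.proportion:.1f}%",
             "ci95": f"[{trans.ci_low:.3f}, {trans.ci_high:.3f}]",
             "p_value": trans.p_value})
print(f"heterozygote transmission: 157/302, exact p = {trans.p_value:.3f} "
      f"-> no evidence of heterozygote lethality")

hom = mendelian_homozygote_fraction(10_000, seed=args.seed)
rows.append({"quantity": "homozygote_fraction_hetxhet_sim10000",
             "value": f"{100 * hom:.2f}%", "ci95": "", "p_value": ""})
print(f"het x het homozygote fraction (10,000 simulated conceptions): "
      f"{100 * hom:.2f}% (analytic 25%)")

litters = dio.read_litters(args.indir / "litters.tsv")
hh = litters[litters["cross"] == "hetxhet"]["n_born"]
wh = litters[litters["cross"] == "WTxhet"]["n_born"]
d = litter_deficit(hh, wh, lethality=1.0)
rows.append({"quantity": "litter_size_deficit",
             "value": f"{d.percent_reduction:.1f}% "
                      f"(expected {d.expected_percent_reduction:.0f}%)",
             "ci95": "", "p_value": d.p_value})
print(f"litter deficit: het x het mean {d.mean_het_x_het:.2f} vs WT x het "
      f"{d.mean_wt_x_het:.2f} -> {d.percent_reduction:.1f}% reduction "
      f"(lethality model expects {d.expected_percent_reduction:.0f}%), "
      f"t-test p = {d.p_value:.2e}")

pd.DataFrame(rows).to_csv(args.outdir / "segregation_stats.tsv", sep="\t",
                          index=False)
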