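"""End-to-end pipeline: simulate -> map -> annotate -> primers -> genotype
-> segregation -> spike statistics, under one root seed.

Stage order mirrors the forward-genetics workflow: recombination-interval
mapping of affected backcross animals produces a candidate locus; in-locus
variants are filtered to protein-altering changes; the retained stop-gain
is validated by allele-specific PCR genotyping of a simulated litter;
segregation and litter statistics check dominant transmission and
homozygous lethality; and the calibrated spike-train cohorts are reduced
to the firing-statistics summary with group comparisons and fold ratios.

The root seed fans out deterministically to every stage; identical config
and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .annotate import annotate_variant, filter_candidates
from .genetics import SegregationCounts, litter_deficit, penetrance_estimate
from .mapping import call_strain_blocks, shared_carrier_region
from .primers import DesignConfig, design_as_primers, genotype_mouse
from .simulate import (
    LitterSpec,
    ToyGeneConfig,
    default_cross_spec,
    make_toy_gene_model,
    make_variant_table,
    simulate_cross,
    simulate_litters,
)
from .simulate.cross import Cohort, simulate_mapping_cohort
from .simulate.spikes import full_reference_cohort
from .spiketrain import compare_all, fold_ratios, per_cell_table, summarize_groups

log = logging.getLogger("dystmap.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "pipeline_out"
    # cross / mapping
    n_affected: int = 24            # mapped affected backcross animals
    n_advanced: int = 7             # of which advanced-generation animals
    penetrance: float = 1.0
    boundary: str = "carrier"
    min_exclusion_span: int = 10_000_000  # bp; interior-FVB-run QC filter
    # segregation
    transmission_n: int = 302
    # litters
    n_litters_per_arm: int = 30
    mean_litter_size: float = 8.0
    lethality: float = 1.0
    # genotyping
    genotyping_litter: int = 40
    # spikes
    spike_duration: float = 300.0
    bin_width: float = 0.001
    report_format: str = "markdown"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _child_seeds(root: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(root)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of key results and writes files
    plus a report under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 6)
    results: dict = {"outdir": str(out)}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - report stage context
                raise StageError(name, str(e)) from e
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return deco

    # ---------------------------------------------------------- simulate
    state: dict = {}

    @stage("simulate")
    def _simulate():
        region, transcript, planted = make_toy_gene_model(
            ToyGeneConfig(seed=seeds[0])
        )
        variants = make_variant_table(region, transcript, planted, seed=seeds[0])
        dio.write_fasta(region, out / "reference.fa")
        dio.write_gff3(transcript, out / "gene.gff3")
        dio.write_variant_table(variants, out / "variants.tsv")

        n_adv = min(config.n_advanced, config.n_affected)
        spec, affected = simulate_mapping_cohort(
            seed=seeds[1], n_n2=config.n_affected - n_adv, n_advanced=n_adv,
        )
        dio.write_snp_panel(spec.panel_frame(), out / "snp_panel.tsv")
        dio.write_genotype_matrix(
            Cohort(spec=spec, mice=affected).genotype_frame(),
            out / "genotypes.tsv",
        )
        dio.write_chrom_sizes(spec.chrom_lengths, out / "chrom.sizes")

        hh = simulate_litters(LitterSpec(
            parent_genotypes=("het", "het"), n_litters=config.n_litters_per_arm,
            mean_litter_size=config.mean_litter_size,
            lethality=config.lethality, seed=seeds[2]))
        wh = simulate_litters(LitterSpec(
            parent_genotypes=("WT", "het"), n_litters=config.n_litters_per_arm,
            mean_litter_size=config.mean_litter_size,
            lethality=config.lethality, seed=seeds[2] + 1))
        dio.write_litters(pd.concat([hh, wh], ignore_index=True),
                          out / "litters.tsv")

        trains = full_reference_cohort(seed=seeds[3], duration=config.spike_duration)
        dio.write_spike_csv(trains, out / "spikes.csv", out / "cells.tsv")

        state.update(region=region, transcript=transcript, planted=planted,
                     variants=variants, spec=spec, affected=affected,
                     litters_hh=hh, litters_wh=wh, trains=trains)

    # --------------------------------------------------------------- map
    @stage("map")
    def _map():
        spec, affected = state["spec"], state["affected"]
        if not affected:
            raise ValueError("no affected mice to map")
        panel = spec.panel_frame()
        mosaics = [
            call_strain_blocks(m.genotypes, panel, spec.chrom_lengths,
                               mouse_id=m.mouse_id, boundary=config.boundary)
            for m in affected
        ]
        mapping = shared_carrier_region(
            mosaics, spec.chrom_lengths,
            min_exclusion_span=config.min_exclusion_span,
        )
        dio.write_bed(mapping.intervals, out / "candidate_region.bed")
        dio.write_mosaic_bed(mosaics, out / "mosaics.bed")
        state.update(mapping=mapping, n_mapped=len(affected))
        results["candidate_intervals"] = [
            f"{iv.chrom}:{iv.start}-{iv.end}" for iv in mapping.intervals
        ]
        results["candidate_span_mb"] = mapping.total_span / 1e6

    # ---------------------------------------------------------- annotate
    @stage("annotate")
    def _annotate():
        mapping = state["mapping"]
        transcript = state["transcript"]
        on_chrom = [iv for iv in mapping.intervals if iv.chrom == transcript.chrom]
        if not on_chrom:
            raise ValueError("candidate region excludes the gene's chromosome")
        retained_all, decisions = [], []
        for iv in on_chrom:
            r, d = filter_candidates(
                state["variants"], iv, transcript, state["region"]
            )
            retained_all.extend(r)
            decisions.extend(
                x for x in d
                if x.reason != "outside_interval" or len(on_chrom) == 1
            )
        # deduplicate decisions by variant, preferring retained entries
        by_v = {}
        for d in decisions:
            if d.variant not in by_v or d.retained:
                by_v[d.variant] = d
        decisions = [by_v[v] for v in sorted(by_v, key=lambda v: v.pos)]
        dio.write_variant_table(
            [d.variant for d in decisions], out / "variants_annotated.tsv",
            decisions=decisions,
        )
        retained = sorted(set(retained_all), key=lambda v: v.pos)
        state["retained"] = retained
        cons = [annotate_variant(v, transcript, state["region"]) for v in retained]
        results["n_variants"] = len(state["variants"])
        results["n_retained"] = len(retained)
        results["retained_consequences"] = [
            {"protein_change": c.protein_change, "class": c.vclass,
             "truncated_residues": c.truncated_residues,
             "ptc_junction_distance": c.ptc_junction_distance,
             "nmd_escape": c.nmd_escape}
            for c in cons
        ]

    # ------------------------------------------------------------ primers
    @stage("primers")
    def _primers():
        region, planted = state["region"], state["planted"]
        pad = 350
        start = planted.pos - pad
        template = region.slice(start, planted.pos + pad)
        # wide acceptance window: the inner primers are anchored at the
        # mutation, so the assay adopts whatever Tm the site permits and
        # Tm-matches the outside primers to it
        pset = design_as_primers(
            template, pad, planted.ref, planted.alt,
            chrom=planted.chrom, template_start=start,
            cfg=DesignConfig(tm_window=8.0),
        )
        rows = [
            {"name": p.name, "sequence": p.sequence, "orientation": p.orientation,
             "tm_C": round(p.tm, 2), "allele": p.allele,
             "footprint": f"{p.footprint.chrom}:{p.footprint.start}-{p.footprint.end}"}
            for p in pset.all_primers()
        ]
        pd.DataFrame(rows).to_csv(out / "primers.tsv", sep="\t", index=False)
        state.update(pset=pset, template=template, template_start=start, pad=pad)
        results["product_lengths"] = pset.product_lengths

    # ----------------------------------------------------------- genotype
    @stage("genotype")
    def _genotype():
        pset, template, pad = state["pset"], state["template"], state["pad"]
        planted = state["planted"]
        mut_template = template[:pad] + planted.alt + template[pad + 1:]
        rng = np.random.default_rng(seeds[4])
        truth = rng.random(config.genotyping_litter) < 0.5  # backcross litter
        calls = []
        for carrier in truth:
            alleles = (template, mut_template) if carrier else (template, template)
            calls.append(genotype_mouse(alleles, pset))
        frame = pd.DataFrame({
            "mouse": [f"pup{i:02d}" for i in range(config.genotyping_litter)],
            "true_carrier": truth,
            "call": calls,
        })
        frame.to_csv(out / "genotype_calls.tsv", sep="\t", index=False)
        concordant = sum(
            (c == "carrier") == bool(t) and c != "fail"
            for c, t in zip(calls, truth)
        )
        results["genotyping_concordance"] = concordant / config.genotyping_litter

    # -------------------------------------------------------- segregation
    @stage("segregation")
    def _segregation():
        spec = default_cross_spec(
            n_offspring=config.transmission_n, seed=seeds[5], penetrance=1.0
        )
        cohort = simulate_cross(spec)
        n_carriers = sum(m.carrier for m in cohort.mice)
        trans = penetrance_estimate(SegregationCounts(
            n_total=config.transmission_n, n_positive=n_carriers,
            expected_fraction=0.5))
        hh = state["litters_hh"]["n_born"]
        wh = state["litters_wh"]["n_born"]
        deficit = litter_deficit(hh, wh, lethality=config.lethality)
        results["transmission"] = {
            "n": config.transmission_n, "carriers": n_carriers,
            "proportion": trans.proportion, "p_value": trans.p_value,
        }
        results["litter_deficit"] = {
            "percent_reduction": deficit.percent_reduction,
            "expected_percent": deficit.expected_percent_reduction,
            "p_value": deficit.p_value,
        }
        state["segregation_text"] = (
            f"transmission {n_carriers}/{config.transmission_n} "
            f"(p={trans.p_value:.3f}); litter deficit "
            f"{deficit.percent_reduction:.1f}% "
            f"(expected {deficit.expected_percent_reduction:.0f}%, "
            f"p={deficit.p_value:.2e})"
        )

    # ------------------------------------------------------------- spikes
    @stage("spikes")
    def _spikes():
        trains = state["trains"]
        cells = per_cell_table(trains, bin_width=config.bin_width)
        summary = summarize_groups(trains, bin_width=config.bin_width)
        comparisons = compare_all(trains, bin_width=config.bin_width)
        folds = fold_ratios(summary)
        cells.to_csv(out / "spike_cells.tsv", sep="\t", index=False)
        summary.to_csv(out / "spike_summary.tsv", sep="\t", index=False)
        comparisons.to_csv(out / "spike_comparisons.tsv", sep="\t", index=False)
        folds.to_csv(out / "spike_fold_ratios.tsv", sep="\t", index=False)
        dcn = folds[(folds.cell_class == "DCN")
                    & (folds.statistic_name == "predominant_fr")]
        results["dcn_predominant_fold"] = {
            r.comparison: r.ratio for r in dcn.itertuples()
        }

    _write_report(out, config, results, state)
    results["report"] = str(out / "report.md")
    return results


def _write_report(out: Path, config: PipelineConfig, results: dict, state: dict) -> None:
    planted = state.get("planted")
    lines = [
        "# dystmap pipeline report",
        "",
        f"- seed: {config.seed}",
        f"- candidate region: {', '.join(results.get('candidate_intervals', []))} "
        f"({results.get('candidate_span_mb', float('nan')):.1f} Mb total)",
        f"- variants in locus: {results.get('n_variants')}; retained "
        f"protein-altering: {results.get('n_retained')}",
    ]
    for c in results.get("retained_consequences", []):
        lines.append(
            f"  - {c['protein_change']} ({c['class']}), truncates "
            f"{c['truncated_residues']} residues, PTC {c['ptc_junction_distance']} nt "
            f"from final junction, NMD escape: {c['nmd_escape']}"
        )
    if planted is not None:
        lines.append(
            f"- planted mutation: {planted.chrom}:{planted.pos + 1} "
            f"{planted.ref}>{planted.alt} (transcript nt {planted.transcript_pos})"
        )
    lines += [
        f"- genotyping concordance on litter of {config.genotyping_litter}: "
        f"{results.get('genotyping_concordance', float('nan')):.0%}",
        f"- segregation: {state.get('segregation_text', 'n/a')}",
        "- DCN predominant-rate fold ratios: "
        + ", ".join(f"{k}={v:.2f}"
                    for k, v in results.get("dcn_predominant_fold", {}).items()),
        "",
    ]
    (out / "report.md").write_text("\n".join(lines))
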