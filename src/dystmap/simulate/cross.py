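"""Backcross / intercross cohort and litter simulation.

Meioses follow the Haldane model: crossover counts on each chromosome are
Poisson with mean equal to its genetic length (bp x cM/Mb, no
interference), crossover positions uniform. A carrier parent is
heterozygous with the causal mutation on its B6 haplotype, so an offspring
inherits the mutation iff the transmitted gamete is B6 at the causal
position. Offspring are symptomatic with probability `penetrance` iff they
carry at least one mutant allele.

Litters: conceived sizes are Poisson(mean_litter_size); genotypes are
Mendelian for the configured parents; each conceived homozygous-mutant pup
dies in utero with probability `lethality`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ..intervals import GenomicInterval
from ..mapping import B6_CARRIER, FVB_HOM, StrainMosaic

#: panel scale mirroring a medium-density array: 1449 SNPs genome-wide of
#: which 833 are informative between B6 and FVB (~0.575), i.e. roughly
#: 61 SNPs / 35 informative per chromosome over ~24 chromosome arms.
PANEL_SNPS_PER_CHROM = 61
INFORMATIVE_PER_CHROM = 35

#: the causal chromosome's proximal region has no informative panel SNPs
DEFAULT_PROXIMAL_GAP = 11_922_132


@dataclass
class CrossSpec:
    cross_type: str                      # "backcross" | "intercross"
    n_offspring: int
    chrom_lengths: dict[str, int]
    snp_positions: dict[str, np.ndarray]
    informative: dict[str, np.ndarray]   # bool mask aligned with snp_positions
    causal_locus: tuple[str, int]
    penetrance: float = 1.0
    recomb_rate: float = 0.5             # cM per Mb
    homozygous_lethality: float = 1.0
    missing_rate: float = 0.01
    meioses: int = 1      # carrier-chromosome meioses since the founder F1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cross_type not in ("backcross", "intercross"):
            raise ValueError(f"unknown cross_type {self.cross_type!r}")
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must be in [0, 1]")
        if not 0 <= self.homozygous_lethality <= 1:
            raise ValueError("homozygous_lethality must be in [0, 1]")
        chrom, pos = self.causal_locus
        if chrom not in self.chrom_lengths or not 0 <= pos < self.chrom_lengths[chrom]:
            raise ValueError(f"causal locus {chrom}:{pos} off the genome")
        for c, p in self.snp_positions.items():
            p = np.asarray(p)
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"SNP positions on {c} must be strictly increasing")
            if p.size and (p[0] < 0 or p[-1] >= self.chrom_lengths[c]):
                raise ValueError(f"SNP positions on {c} outside chromosome")

    def panel_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chrom_lengths:
            pos = self.snp_positions.get(chrom, np.array([], dtype=int))
            inf = self.informative.get(chrom, np.array([], dtype=bool))
            for p, i in zip(pos, inf):
                rows.append({"chrom": chrom, "pos": int(p),
                             "snp_id": f"{chrom}:{int(p) + 1}",
                             "informative": bool(i)})
        return pd.DataFrame(rows, columns=["chrom", "pos", "snp_id", "informative"])


def default_cross_spec(
    n_offspring: int = 24,
    seed: int = 0,
    cross_type: str = "backcross",
    penetrance: float = 1.0,
    n_informative: int = INFORMATIVE_PER_CHROM,
    proximal_gap: int = DEFAULT_PROXIMAL_GAP,
    meioses: int = 1,
) -> CrossSpec:
    """Five-chromosome genome with the causal locus at chr12:20 Mb.

    The causal chromosome is 120 Mb and its proximal end carries no
    informative SNPs (mirroring the real panel's gap); the other
    chromosomes stand in for the rest of the genome.
    """
    chrom_lengths = {
        "chr12": 120_000_000,
        "chr2": 182_000_000,
        "chr5": 151_000_000,
        "chr9": 124_000_000,
        "chr15": 104_000_000,
    }
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    snp_positions, informative = {}, {}
    for chrom, length in chrom_lengths.items():
        lo = proximal_gap if chrom == "chr12" else 3_000_000
        hi = length - 1_000_000
        # informative SNPs stratified (one per equal-width stratum), the way
        # linkage panels are designed for even genome coverage; the
        # uninformative remainder lands uniformly
        edges = np.linspace(lo, hi, n_informative + 1)
        inf_pos = np.array([
            int(rng.integers(int(a), int(b))) for a, b in zip(edges, edges[1:])
        ])
        n_uninf = PANEL_SNPS_PER_CHROM - n_informative
        uninf_pos = rng.integers(lo, hi, size=n_uninf)
        pos = np.concatenate([inf_pos, uninf_pos])
        mask = np.concatenate([
            np.ones(n_informative, dtype=bool), np.zeros(n_uninf, dtype=bool)
        ])
        order = np.argsort(pos, kind="stable")
        pos, mask = pos[order], mask[order]
        # enforce strictly increasing positions
        for i in range(1, len(pos)):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        snp_positions[chrom] = pos.astype(int)
        informative[chrom] = mask
    return CrossSpec(
        cross_type=cross_type,
        n_offspring=n_offspring,
        chrom_lengths=chrom_lengths,
        snp_positions=snp_positions,
        informative=informative,
        causal_locus=("chr12", 20_000_000),
        penetrance=penetrance,
        meioses=meioses,
        seed=seed,
    )


@dataclass
class Mouse:
    mouse_id: str
    mosaic: StrainMosaic                    # true carrier-status mosaic
    genotypes: dict[str, list[str]]         # per chrom, aligned with panel rows
    n_mutant_alleles: int
    affected: bool

    @property
    def carrier(self) -> bool:
        return self.n_mutant_alleles > 0


@dataclass
class Cohort:
    spec: CrossSpec
    mice: list[Mouse]
    warnings: list[str] = field(default_factory=list)

    @property
    def affected(self) -> list[Mouse]:
        return [m for m in self.mice if m.affected]

    def genotype_frame(self) -> pd.DataFrame:
        panel = self.spec.panel_frame()
        data = {}
        for m in self.mice:
            row = []
            for chrom in self.spec.chrom_lengths:
                row.extend(m.genotypes[chrom])
            data[m.mouse_id] = row
        return pd.DataFrame.from_dict(
            data, orient="index", columns=panel["snp_id"].tolist()
        )


def _gamete(
    rng: np.random.Generator, length: int, morgans: float
) -> list[tuple[int, int, str]]:
    """One transmitted chromosome as (start, end, strain) blocks."""
    n_xo = rng.poisson(morgans)
    cuts = np.sort(rng.integers(1, length, size=n_xo)) if n_xo else np.array([], int)
    edges = [0, *[int(c) for c in cuts], length]
    strains = ["B6", "FVB"] if rng.random() < 0.5 else ["FVB", "B6"]
    blocks = []
    for i, (s, e) in enumerate(zip(edges, edges[1:])):
        if s < e:
            blocks.append((s, e, strains[i % 2]))
    # merge zero-length-cut artifacts
    merged = [blocks[0]]
    for s, e, lab in blocks[1:]:
        if lab == merged[-1][2]:
            merged[-1] = (merged[-1][0], e, lab)
        else:
            merged.append((s, e, lab))
    return merged


def _strain_at(blocks: list[tuple[int, int, str]], pos: int) -> str:
    for s, e, lab in blocks:
        if s <= pos < e:
            return lab
    raise KeyError(pos)


def _carrier_mosaic(
    mouse_id: str,
    gametes: dict[str, list[list[tuple[int, int, str]]]],
    chrom_lengths: dict[str, int],
) -> StrainMosaic:
    """True diplotype mosaic: B6_carrier wherever any allele is B6."""
    blocks = {}
    for chrom, gams in gametes.items():
        edges = sorted({0, chrom_lengths[chrom]}
                       | {s for g in gams for s, _, _ in g}
                       | {e for g in gams for _, e, _ in g})
        merged: list[tuple[GenomicInterval, str]] = []
        for s, e in zip(edges, edges[1:]):
            carrier = any(_strain_at(g, s) == "B6" for g in gams)
            lab = B6_CARRIER if carrier else FVB_HOM
            if merged and merged[-1][1] == lab:
                merged[-1] = (GenomicInterval(chrom, merged[-1][0].start, e), lab)
            else:
                merged.append((GenomicInterval(chrom, s, e), lab))
        blocks[chrom] = merged
    return StrainMosaic(mouse_id=mouse_id, blocks=blocks)


def simulate_cross(spec: CrossSpec) -> Cohort:
    """Simulate a cohort of offspring with genotypes and phenotype labels."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    causal_chrom, causal_pos = spec.causal_locus
    warnings = []
    inf = spec.informative.get(causal_chrom)
    if inf is None or not np.any(inf):
        warnings.append(f"no informative SNPs on causal chromosome {causal_chrom}")

    mice = []
    for i in range(spec.n_offspring):
        gametes: dict[str, list[list[tuple[int, int, str]]]] = {}
        for chrom, length in spec.chrom_lengths.items():
            morgans = length / 1e6 * spec.recomb_rate / 100.0
            # successive backcross generations accumulate crossovers on the
            # carrier haplotype; model k meioses as k-fold genetic length
            g1 = _gamete(rng, length, morgans * spec.meioses)
            if spec.cross_type == "backcross":
                g2 = [(0, length, "FVB")]       # recurrent FVB parent
            else:
                g2 = _gamete(rng, length, morgans)  # second carrier parent
            gametes[chrom] = [g1, g2]

        n_mut = sum(
            1 for g in (
                gametes[causal_chrom] if spec.cross_type == "intercross"
                else gametes[causal_chrom][:1]
            )
            if _strain_at(g, causal_pos) == "B6"
        )
        affected = n_mut > 0 and rng.random() < spec.penetrance

        genotypes = {}
        for chrom in spec.chrom_lengths:
            calls = []
            for pos in spec.snp_positions.get(chrom, []):
                alleles = sorted(
                    _strain_at(g, int(pos)) for g in gametes[chrom]
                )  # sorted -> "B6" before "FVB"
                gt = "/".join(alleles)
                if rng.random() < spec.missing_rate:
                    gt = "NA"
                calls.append(gt)
            genotypes[chrom] = calls

        mouse_id = f"m{i:04d}"
        mice.append(
            Mouse(
                mouse_id=mouse_id,
                mosaic=_carrier_mosaic(mouse_id, gametes, spec.chrom_lengths),
                genotypes=genotypes,
                n_mutant_alleles=n_mut,
                affected=affected,
            )
        )
    return Cohort(spec=spec, mice=mice, warnings=warnings)


@dataclass
class LitterSpec:
    parent_genotypes: tuple[str, str]    # each "WT" or "het"
    mean_litter_size: float = 8.0
    n_litters: int = 20
    lethality: float = 1.0               # in-utero death prob per homozygote
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_litter_size <= 0:
            raise ValueError("mean_litter_size must be positive")
        for p in self.parent_genotypes:
            if p not in ("WT", "het"):
                raise ValueError(f"unknown parent genotype {p!r}")
        if not 0 <= self.lethality <= 1:
            raise ValueError("lethality must be in [0, 1]")


_OFFSPRING_PROBS = {
    ("het", "het"): {"WT": 0.25, "het": 0.5, "hom": 0.25},
    ("WT", "het"): {"WT": 0.5, "het": 0.5, "hom": 0.0},
    ("het", "WT"): {"WT": 0.5, "het": 0.5, "hom": 0.0},
    ("WT", "WT"): {"WT": 1.0, "het": 0.0, "hom": 0.0},
}


def simulate_litters(spec: LitterSpec) -> pd.DataFrame:
    """Litter table: conceived and live counts per genotype, one row per litter."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 13]))
    probs = _OFFSPRING_PROBS[tuple(spec.parent_genotypes)]
    p = np.array([probs["WT"], probs["het"], probs["hom"]])
    rows = []
    for i in range(spec.n_litters):
        conceived = int(rng.poisson(spec.mean_litter_size))
        n_wt, n_het, n_hom = (
            rng.multinomial(conceived, p) if conceived else (0, 0, 0)
        )
        hom_dead = int(rng.binomial(n_hom, spec.lethality)) if n_hom else 0
        rows.append({
            "litter_id": f"L{i:03d}",
            "cross": "x".join(spec.parent_genotypes),
            "n_conceived": conceived,
            "n_born": conceived - hom_dead,
            "n_wt": int(n_wt),
            "n_het": int(n_het),
            "n_hom_conceived": int(n_hom),
            "n_hom_born": int(n_hom) - hom_dead,
        })
    return pd.DataFrame(rows)


def simulate_mapping_cohort(
    seed: int = 0,
    n_n2: int = 17,
    n_advanced: int = 7,
    advanced_meioses: int = 3,
) -> tuple[CrossSpec, list[Mouse]]:
    """Affected mapping cohort mirroring the mixed-generation panel study:
    `n_n2` first-backcross animals plus `n_advanced` animals whose carrier
    chromosome passed through `advanced_meioses` meioses. Both groups share
    one SNP panel. Raises if too few affected animals arise."""
    spec = default_cross_spec(n_offspring=3 * n_n2 + 10, seed=seed,
                              penetrance=1.0)

    def affected_batch(base_spec: CrossSpec, n_needed: int, seed0: int,
                       prefix: str) -> list[Mouse]:
        out: list[Mouse] = []
        for batch in range(6):  # top up against rare binomial shortfalls
            if len(out) >= n_needed:
                break
            base_spec.seed = seed0 + 700_001 * batch
            out.extend(simulate_cross(base_spec).affected)
        if len(out) < n_needed:
            raise RuntimeError("not enough affected mice; increase cohort sizes")
        out = out[:n_needed]
        for i, m in enumerate(out):  # unique ids across groups and batches
            m.mouse_id = f"{prefix}{i:03d}"
            m.mosaic.mouse_id = m.mouse_id
        return out

    n2 = affected_batch(spec, n_n2, seed, "n2_") if n_n2 else []
    adv_spec = default_cross_spec(n_offspring=3 * n_advanced + 10, seed=seed,
                                  penetrance=1.0, meioses=advanced_meioses)
    adv = (affected_batch(adv_spec, n_advanced, seed + 500_009, "adv_")
           if n_advanced else [])
    spec.seed = seed
    return spec, n2 + adv
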