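"""Allele-specific nested PCR design and in-silico genotyping.

Allele-specific PCR discriminates a point mutation by placing the variant
base at the primer's 3' terminus: a 3'-terminal mismatch blocks extension.
The nested design pairs Tm-matched outside primers (the positive control
amplicon spans the mutation) with internal allele-specific primers whose
3' ends sit exactly on the mutated base; an optional extra destabilizing
substitution at -2 from the 3' end sharpens discrimination. Routine
genotyping runs two tubes per animal — (F-outside + R-outside) control and
(F-outside + R-mutant) diagnostic — and calls carrier status from product
presence; a third WT-allele tube (off by default) would distinguish het
from homozygous mutant.

Priming in the in-silico PCR is a discrete rule, exactly testable: a
primer primes a site iff its 3'-terminal base matches and it has at most
a configured number of internal mismatches (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .intervals import GenomicInterval
from .reference import revcomp, VALID_BASES

WALLACE_MAX_LEN = 13  # Wallace rule below this+1; nearest-neighbor at >= 14


def tm(
    sequence: str,
    model: str = "auto",
    salt_mM: float = 50.0,
    mg_mM: float = 1.5,
    dnac_nM: float = 250.0,
) -> float:
    """Primer melting temperature in deg C.

    model="wallace": 2(A+T) + 4(G+C); model="nn": nearest-neighbor
    (SantaLucia unified parameters) under PCR-like conditions — 250 nM
    primer, 50 mM monovalent salt, 1.5 mM Mg2+ with the Owczarzy divalent
    correction (plain monovalent entropy correction when mg_mM=0);
    model="auto": Wallace for sequences shorter than 14 nt, NN otherwise.
    """
    if not sequence or any(b not in VALID_BASES for b in sequence):
        raise ValueError(f"sequence must be non-empty ACGT, got {sequence!r}")
    if model == "auto":
        model = "wallace" if len(sequence) <= WALLACE_MAX_LEN else "nn"
    if model == "wallace":
        return float(_mt.Tm_Wallace(sequence))
    if model == "nn":
        return float(_mt.Tm_NN(
            sequence, nn_table=_mt.DNA_NN3, Na=salt_mM, Mg=mg_mM,
            saltcorr=7 if mg_mM > 0 else 5, dnac1=dnac_nM, dnac2=0,
        ))
    raise ValueError(f"unknown Tm model {model!r}")


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str              # 5'->3'
    orientation: str           # "forward" | "reverse"
    footprint: GenomicInterval
    tm: float
    allele: str = "none"       # "WT" | "mutant" | "none"
    extra_mismatch_offset: Optional[int] = None  # relative to 3' end, e.g. -2

    def __post_init__(self) -> None:
        if len(self.sequence) < 15:
            raise ValueError(f"primer {self.name} shorter than 15 nt")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.allele not in ("WT", "mutant", "none"):
            raise ValueError(f"bad allele tag {self.allele!r}")


@dataclass
class PrimerSet:
    outside_forward: Primer
    outside_reverse: Primer
    as_forward_wt: Primer
    as_forward_mut: Primer
    as_reverse_wt: Primer
    as_reverse_mut: Primer
    product_lengths: dict[str, int] = field(default_factory=dict)

    def all_primers(self) -> list[Primer]:
        return [self.outside_forward, self.outside_reverse,
                self.as_forward_wt, self.as_forward_mut,
                self.as_reverse_wt, self.as_reverse_mut]


@dataclass(frozen=True)
class DesignConfig:
    min_len: int = 18
    max_len: int = 28
    tm_target: float = 62.0     # deg C; mid of the 60-64 window
    tm_window: float = 2.0      # acceptance half-width for anchored primers
    tm_tolerance: float = 2.0   # pair Tm-matching tolerance
    outside_min_gap: int = 40   # bp between mutation and outside primer 3' end
    outside_max_gap: int = 260
    destabilize_wt_reverse: bool = False  # G-for-C substitution at -2
    annealing_temp: float = 63.0  # deg C, protocol metadata


class DesignError(ValueError):
    pass


def _best_length(
    seqs_by_len: dict[int, str], cfg: DesignConfig
) -> tuple[int, float]:
    """Pick the candidate length whose Tm is closest to target, within window."""
    best = None
    for n, s in seqs_by_len.items():
        t = tm(s, model="nn")
        if abs(t - cfg.tm_target) <= cfg.tm_window:
            score = abs(t - cfg.tm_target)
            if best is None or score < best[2]:
                best = (n, t, score)
    if best is None:
        raise DesignError(
            f"no primer length in [{min(seqs_by_len)}, {max(seqs_by_len)}] reaches "
            f"Tm {cfg.tm_target}±{cfg.tm_window} °C"
        )
    return best[0], best[1]


def design_as_primers(
    template: str,
    mutation_index: int,
    wt_base: str,
    mut_base: str,
    chrom: str = "template",
    template_start: int = 0,
    cfg: DesignConfig | None = None,
) -> PrimerSet:
    """Design the nested allele-specific primer set around a point mutation.

    `template` is the WT plus-strand sequence; `mutation_index` is 0-based
    within it. Allele-specific forward primers end (3') on the mutated
    base; allele-specific reverse primers end on its complement. Outside
    primers are chosen in the flanks, Tm-matched to the allele-specific
    primers within tolerance.
    """
    cfg = cfg or DesignConfig()
    if template[mutation_index] != wt_base:
        raise DesignError(
            f"template has {template[mutation_index]!r} at the mutation site, "
            f"expected WT base {wt_base!r}"
        )
    if mutation_index < cfg.min_len - 1 or mutation_index > len(template) - cfg.min_len:
        raise DesignError("mutation too close to the template edge to design primers")

    def fwd_candidates() -> dict[int, str]:
        out = {}
        for n in range(cfg.min_len, cfg.max_len + 1):
            start = mutation_index - n + 1
            if start >= 0:
                out[n] = template[start : mutation_index + 1]
        return out

    def rev_candidates() -> dict[int, str]:
        out = {}
        for n in range(cfg.min_len, cfg.max_len + 1):
            end = mutation_index + n
            if end <= len(template):
                out[n] = revcomp(template[mutation_index:end])
        return out

    fc, rc = fwd_candidates(), rev_candidates()
    if not fc or not rc:
        raise DesignError("template too short around the mutation")
    n_f, _ = _best_length(fc, cfg)
    n_r, _ = _best_length(rc, cfg)

    def allele_fwd(allele: str, base: str) -> Primer:
        seq = fc[n_f][:-1] + base
        return Primer(
            name=f"F-{allele}", sequence=seq, orientation="forward",
            footprint=GenomicInterval(
                chrom, template_start + mutation_index - n_f + 1,
                template_start + mutation_index + 1),
            tm=tm(seq, model="nn"), allele=allele,
        )

    def allele_rev(allele: str, base: str) -> Primer:
        seq = rc[n_r][:-1] + revcomp(base)
        offset = None
        if allele == "WT" and cfg.destabilize_wt_reverse:
            if seq[-2] == "C":
                seq = seq[:-2] + "G" + seq[-1]
                offset = -2
        return Primer(
            name=f"R-{allele}", sequence=seq, orientation="reverse",
            footprint=GenomicInterval(
                chrom, template_start + mutation_index,
                template_start + mutation_index + n_r),
            tm=tm(seq, model="nn"), allele=allele,
            extra_mismatch_offset=offset,
        )

    as_f_wt, as_f_mut = allele_fwd("WT", wt_base), allele_fwd("mutant", mut_base)
    as_r_wt, as_r_mut = allele_rev("WT", wt_base), allele_rev("mutant", mut_base)
    inner_tm = (as_f_wt.tm + as_r_wt.tm) / 2.0

    def outside(orientation: str) -> Primer:
        best = None
        for gap in range(cfg.outside_min_gap, cfg.outside_max_gap):
            for n in range(cfg.min_len, cfg.max_len + 1):
                if orientation == "forward":
                    end = mutation_index - gap        # 3' end position (exclusive)
                    start = end - n
                    if start < 0:
                        continue
                    seq = template[start:end]
                    fp = (start, end)
                else:
                    start = mutation_index + 1 + gap
                    end = start + n
                    if end > len(template):
                        continue
                    seq = revcomp(template[start:end])
                    fp = (start, end)
                t = tm(seq, model="nn")
                diff = abs(t - inner_tm)
                if diff <= cfg.tm_tolerance and (best is None or diff < best[0]):
                    best = (diff, seq, fp, t)
            if best is not None and best[0] < 0.3:
                break
        if best is None:
            raise DesignError(
                f"no {orientation} outside primer matches Tm {inner_tm:.1f}"
                f"±{cfg.tm_tolerance} °C in the flank"
            )
        _, seq, (s, e), t = best
        return Primer(
            name=f"{'F' if orientation == 'forward' else 'R'}-outside",
            sequence=seq, orientation=orientation,
            footprint=GenomicInterval(chrom, template_start + s, template_start + e),
            tm=t,
        )

    out_f, out_r = outside("forward"), outside("reverse")
    control_len = out_r.footprint.end - out_f.footprint.start
    pset = PrimerSet(
        outside_forward=out_f, outside_reverse=out_r,
        as_forward_wt=as_f_wt, as_forward_mut=as_f_mut,
        as_reverse_wt=as_r_wt, as_reverse_mut=as_r_mut,
        product_lengths={
            "control": control_len,
            "fout_rmut": as_r_mut.footprint.end - out_f.footprint.start,
            "fout_rwt": as_r_wt.footprint.end - out_f.footprint.start,
            "fmut_rout": out_r.footprint.end - as_f_mut.footprint.start,
        },
    )
    return pset


@dataclass(frozen=True)
class PcrProduct:
    start: int      # 0-based on the template plus strand
    end: int        # exclusive
    forward_primer: str
    reverse_primer: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _forward_sites(template: str, primer: str, max_internal_mm: int) -> list[int]:
    """Start positions where the primer anneals to the minus strand and
    extends rightward (primer sequence read along the plus strand)."""
    n, sites = len(primer), []
    for i in range(len(template) - n + 1):
        window = template[i : i + n]
        if window[-1] != primer[-1]:
            continue  # 3'-terminal mismatch: no extension
        mm = sum(a != b for a, b in zip(window[:-1], primer[:-1]))
        if mm <= max_internal_mm:
            sites.append(i)
    return sites


def _reverse_sites(template: str, primer: str, max_internal_mm: int) -> list[int]:
    """Start positions (plus strand) of sites where the primer anneals to
    the plus strand and extends leftward; primer 3' end maps to the site
    start."""
    rc = revcomp(primer)  # rc[0] pairs with the primer's 3'-terminal base
    n, sites = len(rc), []
    for i in range(len(template) - n + 1):
        window = template[i : i + n]
        if window[0] != rc[0]:
            continue
        mm = sum(a != b for a, b in zip(window[1:], rc[1:]))
        if mm <= max_internal_mm:
            sites.append(i)
    return sites


def in_silico_pcr(
    template: str,
    forward: Primer | str,
    reverse: Primer | str,
    max_internal_mismatches: int = 1,
    max_product: int = 5000,
) -> list[PcrProduct]:
    """Enumerate products of a two-primer reaction on one template allele.

    Both primers are tried in both roles (a primer may prime either
    strand). A site primes iff the 3'-terminal base matches and internal
    mismatches are within the allowance. No product is a valid outcome.
    """
    f_seq = forward.sequence if isinstance(forward, Primer) else forward
    r_seq = reverse.sequence if isinstance(reverse, Primer) else reverse
    f_name = forward.name if isinstance(forward, Primer) else "forward"
    r_name = reverse.name if isinstance(reverse, Primer) else "reverse"

    products = []
    for (pf, nf), (pr, nr) in [
        ((f_seq, f_name), (r_seq, r_name)),
        ((r_seq, r_name), (f_seq, f_name)),
        ((f_seq, f_name), (f_seq, f_name)),
        ((r_seq, r_name), (r_seq, r_name)),
    ]:
        for i in _forward_sites(template, pf, max_internal_mismatches):
            for j in _reverse_sites(template, pr, max_internal_mismatches):
                start, end = i, j + len(pr)
                if end - start >= len(pf) + len(pr) and end - start <= max_product:
                    products.append(PcrProduct(start, end, nf, nr))
    return sorted(set(products), key=lambda p: (p.start, p.end))


def genotype_call(
    control_product: bool,
    mutant_product: bool,
    wt_product: Optional[bool] = None,
) -> str:
    """Two-tube call: carrier / non-carrier / fail.

    The optional third (WT-allele) tube refines a carrier call to
    "carrier_homozygous" when the WT reaction is empty.
    """
    if not control_product:
        return "fail"
    if not mutant_product:
        return "non-carrier"
    if wt_product is False:
        return "carrier_homozygous"
    return "carrier"


def genotype_mouse(
    allele_templates: Sequence[str],
    pset: PrimerSet,
    max_internal_mismatches: int = 1,
    use_wt_tube: bool = False,
) -> str:
    """Run the two-tube (optionally three-tube) scheme on a diploid animal.

    `allele_templates` are the plus-strand sequences of the two alleles
    over the amplicon region; a tube shows a product if any allele yields
    one.
    """
    def tube(fwd: Primer, rev: Primer) -> bool:
        return any(
            in_silico_pcr(t, fwd, rev, max_internal_mismatches)
            for t in allele_templates
        )

    control = tube(pset.outside_forward, pset.outside_reverse)
    mutant = tube(pset.outside_forward, pset.as_reverse_mut)
    wt = tube(pset.outside_forward, pset.as_reverse_wt) if use_wt_tube else None
    return genotype_call(control, mutant, wt)
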