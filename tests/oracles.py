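"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value by the most direct route
available (literal tables, exhaustive enumeration, first-principles
formulas) and deliberately shares no code with the implementation paths
it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

# ---------------------------------------------------------- codon table

#: standard nuclear genetic code, written out literally
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def substitution_class_oracle(codon_ref: str, codon_alt: str) -> str:
    """synonymous / missense / stop_gain from the literal codon table."""
    aa_ref, aa_alt = CODON_TABLE[codon_ref], CODON_TABLE[codon_alt]
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*" and aa_ref != "*":
        return "stop_gain"
    return "missense"


# --------------------------------------------------- nearest-neighbor Tm

#: SantaLucia (1997) unified duplex parameters: dH kcal/mol, dS cal/(mol K)
_NN97 = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)


def tm_nn_oracle(seq: str, na_mM: float = 50.0, dnac_nM: float = 250.0) -> float:
    """Duplex Tm (deg C): literal NN sums + monovalent entropy correction."""
    dh = ds = 0.0
    for b in (seq[0], seq[-1]):
        inc = _INIT_AT if b in "AT" else _INIT_GC
        dh += inc[0]
        ds += inc[1]
    for i in range(len(seq) - 1):
        h, s = _NN97[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1e3)
    r_gas = 1.987  # cal/(mol K)
    return 1000.0 * dh / (ds + r_gas * math.log(dnac_nM * 1e-9)) - 273.15


# --------------------------------------------------- exact binomial test

def binom_pmf_exact(k: int, n: int, p: Fraction) -> Fraction:
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def exact_binomial_p_oracle(k: int, n: int, p0: float) -> float:
    """Two-sided p by tail doubling, summing the pmf term by term."""
    p = Fraction(p0).limit_denominator(10**6)
    lower = sum(binom_pmf_exact(i, n, p) for i in range(0, k + 1))
    upper = sum(binom_pmf_exact(i, n, p) for i in range(k, n + 1))
    return float(min(Fraction(1), 2 * min(lower, upper)))


# --------------------------------- permutation two-sample test oracles

def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    grid = np.concatenate([a, b])
    fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def ks_permutation_p(a, b) -> float:
    """Exact permutation p for the two-sample KS statistic."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    obs = ks_statistic(a, b)
    pooled = np.concatenate([a, b])
    n = a.size
    idx = range(pooled.size)
    hits = total = 0
    for comb in itertools.combinations(idx, n):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        d = ks_statistic(pooled[mask], pooled[~mask])
        total += 1
        if d >= obs - 1e-12:
            hits += 1
    return hits / total


def mannwhitney_u(a: np.ndarray, b: np.ndarray) -> float:
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


def mw_permutation_p(a, b) -> float:
    """Exact two-sided permutation p for Mann-Whitney U (no ties assumed)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    obs = mannwhitney_u(a, b)
    mu = a.size * b.size / 2.0
    pooled = np.concatenate([a, b])
    hits = total = 0
    for comb in itertools.combinations(range(pooled.size), a.size):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        u = mannwhitney_u(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mu) >= abs(obs - mu) - 1e-12:
            hits += 1
    return hits / total


# ----------------------------------------- per-SNP strain-label oracle

def per_snp_labels(genotypes, panel, chrom: str):
    """Brute-force expected label at each informative, called SNP."""
    sub = panel[panel["chrom"] == chrom].reset_index(drop=True)
    out = []
    for i, g in enumerate(genotypes):
        if not sub.loc[i, "informative"] or g in ("NA", "", None):
            continue
        label = "FVB_homozygous" if g == "FVB/FVB" else "B6_carrier"
        out.append((int(sub.loc[i, "pos"]), label))
    return out
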