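"""Segregation, penetrance, and litter-deficit statistics.

Exact binomial inference for transmission ratios (is the observed carrier
fraction compatible with Mendelian 1:2 transmission of a dominant
allele?) and a two-sample comparison of litter sizes between het x het
and WT x het crosses, whose expected deficit under full homozygous
embryonic lethality is lethality x 25% of conceptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class SegregationCounts:
    n_total: int
    n_positive: int
    expected_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("need 0 <= n_positive <= n_total")
        if not 0 <= self.expected_fraction <= 1:
            raise ValueError("expected_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SegregationResult:
    counts: SegregationCounts
    proportion: float
    ci_low: float
    ci_high: float
    p_value: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def exact_binomial_p(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value by tail doubling, capped at 1."""
    if n == 0:
        raise ValueError("n must be positive")
    lower = sps.binom.cdf(k, n, p0)
    upper = sps.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def clopper_pearson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) confidence interval for a proportion."""
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def penetrance_estimate(
    counts: SegregationCounts, alpha: float = 0.05
) -> SegregationResult:
    """Proportion, exact CI, and exact two-sided p vs the expected fraction."""
    if counts.n_total == 0:
        raise ValueError("n_total must be positive")
    k, n = counts.n_positive, counts.n_total
    lo, hi = clopper_pearson_ci(k, n, alpha)
    return SegregationResult(
        counts=counts,
        proportion=k / n,
        ci_low=lo,
        ci_high=hi,
        p_value=exact_binomial_p(k, n, counts.expected_fraction),
        alpha=alpha,
    )


def transmission_test(
    n_total: int, n_carriers: int, alpha: float = 0.05
) -> SegregationResult:
    """Test carrier transmission against the Mendelian 50% expectation.

    A non-significant result at n in the hundreds is the statistical
    content of "no in utero lethality for heterozygotes".
    """
    return penetrance_estimate(
        SegregationCounts(n_total=n_total, n_positive=n_carriers,
                          expected_fraction=0.5),
        alpha=alpha,
    )


@dataclass(frozen=True)
class LitterDeficitResult:
    mean_het_x_het: float
    mean_wt_x_het: float
    percent_reduction: float       # 1 - mean(hh)/mean(wh), as percent
    t_statistic: Optional[float]
    p_value: Optional[float]
    expected_percent_reduction: float   # lethality x 25%
    degenerate: bool = False


def litter_deficit(
    het_x_het_sizes: Sequence[float],
    wt_x_het_sizes: Sequence[float],
    lethality: float = 1.0,
    permutation: bool = False,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> LitterDeficitResult:
    """Compare litter sizes between cross types.

    Default comparison is the unpaired two-tailed Student t-test (pooled
    variance); `permutation=True` swaps in a permutation test on the
    difference of means. Degenerate (zero-variance) inputs produce an
    exact-equality report with p undefined unless the means differ.
    """
    a = np.asarray(het_x_het_sizes, dtype=float)
    b = np.asarray(wt_x_het_sizes, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 litters per arm")
    reduction = 100.0 * (1.0 - a.mean() / b.mean())
    expected = 100.0 * lethality * 0.25

    if np.var(a) == 0 and np.var(b) == 0:
        return LitterDeficitResult(
            mean_het_x_het=float(a.mean()), mean_wt_x_het=float(b.mean()),
            percent_reduction=reduction, t_statistic=None,
            p_value=1.0 if a.mean() == b.mean() else 0.0,
            expected_percent_reduction=expected, degenerate=True,
        )

    if permutation:
        rng = np.random.default_rng(seed)
        obs = abs(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            if abs(pooled[: a.size].mean() - pooled[a.size :].mean()) >= obs - 1e-12:
                count += 1
        return LitterDeficitResult(
            mean_het_x_het=float(a.mean()), mean_wt_x_het=float(b.mean()),
            percent_reduction=reduction, t_statistic=None,
            p_value=(count + 1) / (n_permutations + 1),
            expected_percent_reduction=expected,
        )

    t, p = sps.ttest_ind(a, b, equal_var=True)
    return LitterDeficitResult(
        mean_het_x_het=float(a.mean()), mean_wt_x_het=float(b.mean()),
        percent_reduction=reduction, t_statistic=float(t), p_value=float(p),
        expected_percent_reduction=expected,
    )


def mendelian_homozygote_fraction(n_offspring: int = 10_000, seed: int = 0) -> float:
    """Fraction of het x het conceptions homozygous for the mutation,
    estimated by simulation (analytic value: 0.25)."""
    rng = np.random.default_rng(seed)
    alleles = rng.integers(0, 2, size=(n_offspring, 2))  # 1 = mutant allele
    return float(np.mean(alleles.sum(axis=1) == 2))
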