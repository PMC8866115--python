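"""Luria-Delbruck fluctuation-assay mutation-rate estimation.

Rates are estimated by the Lea-Coulson method of the median: the expected
number of mutations per culture ``m`` solves ``r0/m - ln(m) = 1.24`` where
``r0`` is the median mutant count over parallel cultures.  The per-generation
per-locus rate is ``m / N_final`` (total generations approximated by the final
population size, the standard fluctuation-assay convention), and the per-bp
rate divides further by the mutational target size and reporter copy number.

The 95% CI comes from rank statistics of the per-culture counts: the tightest
symmetric order-statistic pair (j, n+1-j) whose coverage under Binomial(n, 1/2)
reaches the requested level; for n = 16 cultures this selects the 4th- and
13th-ranked counts, each converted to a rate through the same median relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

#: Constant of the Lea-Coulson median relation r0/m - ln(m) = C.
LEA_COULSON_CONSTANT = 1.24


@dataclass
class FluctuationExperiment:
    """Per-culture mutant counts plus population and target-size metadata."""

    mutant_counts: list[int]
    n_final: float
    target_bp: int = 1032
    reporter_copies: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if self.target_bp < 1:
            raise ValueError("target_bp must be >= 1")
        if self.reporter_copies not in (1, 2):
            raise ValueError("reporter_copies must be 1 or 2")
        if self.n_final < 1:
            raise ValueError("n_final must be >= 1")
        for c in self.mutant_counts:
            if c < 0 or int(c) != c:
                raise ValueError(f"mutant counts must be non-negative integers: {c}")

    @property
    def n_cultures(self) -> int:
        return len(self.mutant_counts)


@dataclass
class RateEstimate:
    m: float  # expected mutations per culture
    rate: float  # per bp per generation
    rate_per_locus: float  # per reporter locus per generation
    ci_low: float
    ci_high: float
    rank_low: int | None
    rank_high: int | None
    below_detection: bool = False
    name: str = ""


def solve_lea_coulson_m(r0: float, constant: float = LEA_COULSON_CONSTANT) -> float:
    """Root of r0/m - ln(m) = constant for the expected mutations per culture."""
    if r0 < 0:
        raise ValueError("median count must be non-negative")
    if r0 == 0:
        return 0.0

    def f(m: float) -> float:
        return r0 / m - math.log(m) - constant

    return float(brentq(f, 1e-12, 1e9, xtol=1e-12, rtol=1e-12))


def median_ci_ranks(n_cultures: int, level: float = 0.95) -> tuple[int, int]:
    """Tightest symmetric order-statistic pair (j, n+1-j) covering the median.

    Coverage of the pair is P(j <= X <= n-j) with X ~ Binomial(n, 1/2); the
    largest j achieving coverage >= ``level`` is returned (1-based ranks).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0,1)")
    n = n_cultures
    min_n = math.ceil(math.log2(2.0 / (1.0 - level)))
    if n < 1 or 1.0 - 2.0 * 0.5**n < level:
        raise ValueError(
            f"{n} cultures cannot achieve {level:.0%} coverage; need n >= {min_n}"
        )
    best = 1
    for j in range(1, n // 2 + 1):
        coverage = 1.0 - 2.0 * binom.cdf(j - 1, n, 0.5)
        if coverage >= level:
            best = j
        else:
            break
    return best, n + 1 - best


def _rate_from_count(
    count: float, experiment: FluctuationExperiment, constant: float
) -> tuple[float, float]:
    """(per-locus, per-bp) rate from one count via the median relation."""
    m = solve_lea_coulson_m(count, constant)
    per_locus = m / experiment.n_final
    per_bp = per_locus / (experiment.target_bp * experiment.reporter_copies)
    return per_locus, per_bp


def lea_coulson_estimate(
    experiment: FluctuationExperiment,
    level: float = 0.95,
    constant: float = LEA_COULSON_CONSTANT,
) -> RateEstimate:
    """Strain-level mutation rate by the Lea-Coulson method of the median.

    A zero median yields rate 0 flagged below detection.  CI-limit rates apply
    the same relation to the rank-selected per-culture counts.
    """
    if experiment.n_cultures < 1:
        raise ValueError("need at least one culture")
    counts = sorted(experiment.mutant_counts)
    r0 = float(np.median(counts))
    m = solve_lea_coulson_m(r0, constant)
    per_locus, per_bp = _rate_from_count(r0, experiment, constant)

    rank_low = rank_high = None
    ci_low = ci_high = float("nan")
    try:
        rank_low, rank_high = median_ci_ranks(experiment.n_cultures, level)
    except ValueError:
        pass
    else:
        _, ci_low = _rate_from_count(counts[rank_low - 1], experiment, constant)
        _, ci_high = _rate_from_count(counts[rank_high - 1], experiment, constant)

    return RateEstimate(
        m=m,
        rate=per_bp,
        rate_per_locus=per_locus,
        ci_low=ci_low,
        ci_high=ci_high,
        rank_low=rank_low,
        rank_high=rank_high,
        below_detection=r0 == 0,
        name=experiment.name,
    )


@dataclass
class FoldChange:
    ratio: float
    ci_overlap: bool | None  # None when either CI is unavailable
    flag: str | None = None  # "infinite" / "zero" for degenerate inputs


def rate_fold_change(estimate_a: RateEstimate, estimate_b: RateEstimate) -> FoldChange:
    """Ratio of two rate estimates (a/b) with a rank-CI overlap annotation."""
    if estimate_b.rate == 0:
        return FoldChange(ratio=float("inf"), ci_overlap=None, flag="infinite")
    flag = "zero" if estimate_a.rate == 0 else None
    overlap: bool | None = None
    if not (math.isnan(estimate_a.ci_low) or math.isnan(estimate_b.ci_low)):
        overlap = (
            estimate_a.ci_low <= estimate_b.ci_high
            and estimate_b.ci_low <= estimate_a.ci_high
        )
    return FoldChange(ratio=estimate_a.rate / estimate_b.rate, ci_overlap=overlap, flag=flag)
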