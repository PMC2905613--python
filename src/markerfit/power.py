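"""Analytic power and sample size for association tests at genome-wide significance.

Power is computed for the likelihood-ratio chi-square test of a genotype
coding against the intercept-only null.  In an infinite-population design the
LRT statistic for a sample of n cases and n controls is noncentral
chi-square with noncentrality

    lambda = 2 * (2 n) * (l_coding - l_null)

where l are expected per-individual log-likelihoods, so power and minimal
sample size follow from the noncentral chi-square distribution.  The default
significance level is the genome-wide threshold alpha = 5e-7 with target
power 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, ncx2

from .fitting import CODINGS, GenotypeCoding, coding_for_moi, fit_weighted_logistic
from .twolocus import (
    MarkerCaseControlDistribution,
    PenetranceModel,
    TwoLocusScenario,
    expected_marker_distribution,
)

__all__ = [
    "GENOME_WIDE_ALPHA",
    "PowerQuery",
    "PowerResult",
    "UnreachablePowerError",
    "lrt_noncentrality",
    "power_from_noncentrality",
    "power_at_n",
    "min_sample_size",
    "detectable_freq_range",
    "multi_locus_power",
]

GENOME_WIDE_ALPHA = 5e-7
DEFAULT_TARGET_POWER = 0.8

_N_CAP = 10**9  # sample sizes beyond this are treated as unreachable


class UnreachablePowerError(ValueError):
    """No finite sample size reaches the target power (no association)."""


@dataclass(frozen=True)
class PowerQuery:
    """A power/sample-size question about one scenario."""

    scenario: TwoLocusScenario
    penetrance: PenetranceModel
    coding: GenotypeCoding | None = None  # default: the coding matching the true MOI
    alpha: float = GENOME_WIDE_ALPHA
    target_power: float = DEFAULT_TARGET_POWER
    n_cases: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 < self.target_power < 1.0):
            raise ValueError("target_power must lie in (0, 1)")

    def resolved_coding(self) -> GenotypeCoding:
        return self.coding if self.coding is not None else coding_for_moi(self.penetrance)


@dataclass(frozen=True)
class PowerResult:
    noncentrality: float
    df: int
    power: float
    n_required: int | None = None


def _delta_loglik(dist: MarkerCaseControlDistribution, coding: GenotypeCoding) -> float:
    """Expected per-individual log-likelihood gain of the coding over the null."""
    w1 = 0.5 * dist.case_probs
    w0 = 0.5 * dist.control_probs
    _, ll = fit_weighted_logistic(w1, w0, coding.design)
    _, ll_null = fit_weighted_logistic(w1, w0, CODINGS["null"].design)
    return max(ll - ll_null, 0.0)


def lrt_noncentrality(
    dist: MarkerCaseControlDistribution, coding: GenotypeCoding, n_cases: int
) -> float:
    """LRT noncentrality for n_cases cases and n_cases controls: 2 * (2 n) * (l - l0)."""
    return 2.0 * (2.0 * n_cases) * _delta_loglik(dist, coding)


def power_from_noncentrality(noncentrality: float, df: int, alpha: float) -> float:
    """P(X > chi2 quantile) for X ~ noncentral chi-square(df, lambda)."""
    if noncentrality < 0.0:
        raise ValueError("noncentrality must be non-negative")
    q = chi2.ppf(1.0 - alpha, df)
    if noncentrality == 0.0:
        return alpha
    return float(ncx2.sf(q, df, noncentrality))


def power_at_n(
    dist: MarkerCaseControlDistribution,
    coding: GenotypeCoding,
    n_cases: int,
    alpha: float = GENOME_WIDE_ALPHA,
) -> PowerResult:
    lam = lrt_noncentrality(dist, coding, n_cases)
    return PowerResult(lam, coding.df, power_from_noncentrality(lam, coding.df, alpha))


def min_sample_size(query: PowerQuery) -> PowerResult:
    """Smallest integer n_cases (= n_controls) achieving the target power.

    Exact at integer resolution: power(n_required) >= target and
    power(n_required - 1) < target.  Raises UnreachablePowerError for a null
    scenario (zero per-individual noncentrality).
    """
    coding = query.resolved_coding()
    dist = expected_marker_distribution(query.scenario, query.penetrance)
    lam_per_case = 4.0 * _delta_loglik(dist, coding)
    if lam_per_case <= 0.0:
        raise UnreachablePowerError("no association: target power is unreachable")

    def power(n: int) -> float:
        return power_from_noncentrality(lam_per_case * n, coding.df, query.alpha)

    hi = 1
    while power(hi) < query.target_power:
        hi *= 2
        if hi > _N_CAP:
            raise UnreachablePowerError(f"target power not reached by n_cases = {_N_CAP}")
    lo = hi // 2  # power(lo) < target (or lo == 0)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power(mid) >= query.target_power:
            hi = mid
        else:
            lo = mid
    return PowerResult(lam_per_case * hi, coding.df, power(hi), n_required=hi)


def _power_at_freq(
    p: float,
    pen: PenetranceModel,
    r2: float,
    n_cases: int,
    alpha: float,
    coding: GenotypeCoding,
) -> float:
    dist = expected_marker_distribution(TwoLocusScenario(p, p, r2), pen)
    return power_from_noncentrality(
        lrt_noncentrality(dist, coding, n_cases), coding.df, alpha
    )


def detectable_freq_range(
    n_cases: int,
    pen: PenetranceModel,
    r2: float = 1.0,
    alpha: float = GENOME_WIDE_ALPHA,
    target_power: float = DEFAULT_TARGET_POWER,
    grid_step: float = 0.01,
    refine_tol: float = 1e-3,
) -> list[tuple[float, float]]:
    """Risk-allele frequency interval(s) detectable with the given design.

    The marker frequency is matched to the risk-allele frequency.  Scans the
    grid {grid_step, ..., 1 - grid_step}, then refines each boundary by
    bisection to ``refine_tol``.  An empty list is a valid result (the design
    is underpowered everywhere).
    """
    coding = coding_for_moi(pen)
    grid = np.arange(grid_step, 1.0, grid_step)
    ok = np.array(
        [_power_at_freq(p, pen, r2, n_cases, alpha, coding) >= target_power for p in grid]
    )

    def refine(p_in: float, p_out: float) -> float:
        """Bisect between a detectable and an undetectable frequency."""
        while abs(p_in - p_out) > refine_tol:
            mid = 0.5 * (p_in + p_out)
            if _power_at_freq(mid, pen, r2, n_cases, alpha, coding) >= target_power:
                p_in = mid
            else:
                p_out = mid
        return p_in

    intervals: list[tuple[float, float]] = []
    i = 0
    while i < len(grid):
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(grid) and ok[j + 1]:
            j += 1
        lo = refine(grid[i], grid[i - 1]) if i > 0 else grid[0]
        hi = refine(grid[j], grid[j + 1]) if j + 1 < len(grid) else grid[-1]
        intervals.append((float(lo), float(hi)))
        i = j + 1
    return intervals


def multi_locus_power(k: int, overall_power: float) -> float:
    """Per-locus power needed so that, independently, >=1 of k loci is detected.

    Solves 1 - (1 - p)^k = overall_power, i.e. p = 1 - (1 - overall)^(1/k).
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if not (0.0 < overall_power < 1.0):
        raise ValueError("overall_power must lie in (0, 1)")
    return 1.0 - (1.0 - overall_power) ** (1.0 / k)
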