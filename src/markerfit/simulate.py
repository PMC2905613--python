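"""Finite-sample case-control simulation and tests.

The infinite-population analytics elsewhere in the package are validated here
by Monte Carlo: genotype counts are drawn retrospectively (genotypes sampled
given case/control status, matching the equal-cases-and-controls design),
tested with the Cochran-Armitage trend test or a likelihood-ratio test of a
chosen genotype coding, and the empirical rejection rate is compared with the
analytic power.  All randomness flows from one integer seed; per-replicate
streams are split deterministically so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest, chi2

from .fitting import CODINGS, ConvergenceError, FitResult, GenotypeCoding, fit_expected
from .twolocus import MarkerCaseControlDistribution

__all__ = [
    "GenotypeCounts",
    "TrendTestResult",
    "simulate_case_control",
    "cochran_armitage_trend",
    "fit_finite_sample",
    "lrt_statistic",
    "empirical_power",
]

TREND_SCORES = np.array([0.0, 1.0, 2.0])


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed marker-genotype counts in a case-control sample."""

    case_counts: np.ndarray
    control_counts: np.ndarray

    def __post_init__(self) -> None:
        for name in ("case_counts", "control_counts"):
            v = np.asarray(getattr(self, name))
            if v.shape != (3,) or np.any(v < 0) or not np.issubdtype(v.dtype, np.integer):
                raise ValueError(f"{name} must be a 3-vector of non-negative integers")
            object.__setattr__(self, name, v)

    @property
    def n_cases(self) -> int:
        return int(self.case_counts.sum())

    @property
    def n_controls(self) -> int:
        return int(self.control_counts.sum())


@dataclass(frozen=True)
class TrendTestResult:
    statistic: float
    p_value: float
    scores: tuple = (0.0, 1.0, 2.0)


def simulate_case_control(
    dist: MarkerCaseControlDistribution,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.Generator,
) -> GenotypeCounts:
    """Draw genotype counts retrospectively: multinomials given case/control status."""
    rng = np.random.default_rng(seed)
    return GenotypeCounts(
        case_counts=rng.multinomial(n_cases, dist.case_probs),
        control_counts=rng.multinomial(n_controls, dist.control_probs),
    )


def cochran_armitage_trend(counts: GenotypeCounts) -> TrendTestResult:
    """Cochran-Armitage trend test with scores (0, 1, 2), no continuity correction.

    The statistic is the squared score for a linear trend in the case
    proportion across genotype classes,

        T = N (N sum_g x_g r_g - R sum_g x_g n_g)^2
            / [ R (N - R) (N sum_g x_g^2 n_g - (sum_g x_g n_g)^2) ]

    with r_g case counts, n_g column totals, R total cases, N grand total;
    T is central chi-square with 1 df under no association.
    """
    r = counts.case_counts.astype(float)
    n = r + counts.control_counts.astype(float)
    big_n = n.sum()
    big_r = r.sum()
    if big_n <= 0:
        raise ValueError("empty table")
    if np.count_nonzero(n) < 2:
        raise ValueError("trend statistic undefined: all mass in one genotype class")
    x = TREND_SCORES
    num = big_n * np.sum(x * r) - big_r * np.sum(x * n)
    den = big_r * (big_n - big_r) * (big_n * np.sum(x * x * n) - np.sum(x * n) ** 2)
    if den <= 0:
        raise ValueError("trend statistic undefined: no variation in scores or outcome")
    stat = float(big_n * num * num / den)
    return TrendTestResult(stat, float(chi2.sf(stat, 1)))


def fit_finite_sample(counts: GenotypeCounts, coding: GenotypeCoding) -> FitResult:
    """Maximum-likelihood logistic fit to observed counts.

    Shares the expected-likelihood machinery: the count table normalised by
    the grand total is a case-control distribution with case weight equal to
    the observed case fraction, and the score equations coincide.
    """
    n = counts.n_cases + counts.n_controls
    case = counts.case_counts / max(counts.n_cases, 1)
    ctrl = counts.control_counts / max(counts.n_controls, 1)
    dist = MarkerCaseControlDistribution(case, ctrl, prevalence=0.5)
    return fit_expected(dist, coding, case_fraction=counts.n_cases / n)


def lrt_statistic(counts: GenotypeCounts, coding: GenotypeCoding) -> tuple[float, float]:
    """Likelihood-ratio chi-square of a coding against the intercept-only null.

    Returns (statistic, p_value); the statistic is on the observed-count
    scale, i.e. 2 n (l_coding - l_null) per-individual log-likelihoods.
    """
    n = counts.n_cases + counts.n_controls
    fit = fit_finite_sample(counts, coding)
    null = fit_finite_sample(counts, CODINGS["null"])
    stat = 2.0 * n * (fit.expected_loglik - null.expected_loglik)
    stat = max(float(stat), 0.0)
    return stat, float(chi2.sf(stat, coding.df))


def empirical_power(
    dist: MarkerCaseControlDistribution,
    n_cases: int,
    alpha: float,
    reps: int,
    seed: int,
    test: str | GenotypeCoding = "trend",
    n_controls: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Monte Carlo rejection rate and its exact binomial 99% confidence interval.

    ``test`` is ``"trend"`` for the Cochran-Armitage test or a
    GenotypeCoding for the corresponding likelihood-ratio test.  Replicates
    with an undefined statistic (degenerate tables, separation) count as
    non-rejections.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    if n_controls is None:
        n_controls = n_cases
    streams = np.random.SeedSequence(seed).spawn(reps)
    hits = 0
    for ss in streams:
        counts = simulate_case_control(dist, n_cases, n_controls, np.random.default_rng(ss))
        try:
            if test == "trend":
                p = cochran_armitage_trend(counts).p_value
            else:
                p = lrt_statistic(counts, test)[1]
        except (ValueError, ConvergenceError):
            continue
        hits += p < alpha
    ci = binomtest(hits, reps).proportion_ci(confidence_level=0.99, method="exact")
    return hits / reps, (float(ci.low), float(ci.high))
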