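"""Logistic disease models fitted to the expected case-control distribution.

The study design is an infinite population sampled with equal numbers of
cases and controls, so instead of fitting to data we maximise the *expected*
per-individual Bernoulli log-likelihood

    l(beta) = sum_g [ 0.5 case[g] log pi(g) + 0.5 control[g] log(1 - pi(g)) ]

where pi(g) is the inverse-logit of the linear predictor for genotype g.
Codings with a single binary covariate (dominant, recessive) collapse to a
2x2 table and are solved in closed form; the saturated (general) coding is
solved per genotype class; the multiplicative trend coding needs Newton
iteration.  Model fit is summarised by a pseudo-r^2 against the
intercept-only null (which has l = -log 2 under equal weighting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .twolocus import MarkerCaseControlDistribution, PenetranceModel

__all__ = [
    "GenotypeCoding",
    "CODINGS",
    "FitResult",
    "FitComparison",
    "ConvergenceError",
    "fit_expected",
    "fit_weighted_logistic",
    "pseudo_r2",
    "fit_ratio",
    "estimate_risks",
]

NEWTON_TOL = 1e-12
NEWTON_MAX_ITER = 100

#: pseudo-r^2 below this floor means "no association"; fit ratios built on
#: two such values are reported as undefined rather than silently 1
PSEUDO_R2_FLOOR = 1e-14


class ConvergenceError(RuntimeError):
    """The logistic fit cannot converge (e.g. complete separation)."""


@dataclass(frozen=True)
class GenotypeCoding:
    """A genotype-to-covariate coding, given as a design with intercept.

    ``design`` has one row per genotype g in {0, 1, 2}; the first column is
    the intercept.  ``df`` is the number of non-intercept parameters, i.e.
    the degrees of freedom the coding spends against the null.
    """

    name: str
    design: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.design, dtype=float)
        if d.shape[0] != 3 or d.ndim != 2 or np.any(d[:, 0] != 1.0):
            raise ValueError("design must be 3 x k with an intercept column first")
        object.__setattr__(self, "design", d)

    @property
    def df(self) -> int:
        return self.design.shape[1] - 1


CODINGS: dict[str, GenotypeCoding] = {
    "null": GenotypeCoding("null", np.array([[1.0], [1.0], [1.0]])),
    "multiplicative_trend": GenotypeCoding(
        "multiplicative_trend", np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
    ),
    "dominant": GenotypeCoding("dominant", np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 1.0]])),
    "recessive": GenotypeCoding("recessive", np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 1.0]])),
    "general": GenotypeCoding(
        "general", np.array([[1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [1.0, 0.0, 1.0]])
    ),
}


def coding_for_moi(pen: PenetranceModel) -> GenotypeCoding:
    """The coding that matches a penetrance model's mode of inheritance."""
    if pen.moi == "multiplicative":
        return CODINGS["multiplicative_trend"]
    if pen.moi in ("dominant", "recessive"):
        return CODINGS[pen.moi]
    return CODINGS["general"]


@dataclass(frozen=True)
class FitResult:
    """A fitted genotype coding.

    ``expected_loglik`` is the maximised expected per-individual
    log-likelihood; ``pseudo_r2`` is measured against the intercept-only
    null on the same distribution.  ``or_het`` / ``or_hom`` are the fitted
    odds ratios of genotypes 1 and 2 relative to genotype 0.
    """

    coding: GenotypeCoding
    coefficients: np.ndarray
    expected_loglik: float
    pseudo_r2: float
    or_het: float
    or_hom: float

    def fitted_case_probs(self) -> np.ndarray:
        """P(case | genotype) under the fitted model, for g = 0, 1, 2."""
        eta = self.coding.design @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))

    def to_dict(self) -> dict:
        return {
            "coding": self.coding.name,
            "coefficients": list(map(float, self.coefficients)),
            "expected_loglik": self.expected_loglik,
            "pseudo_r2": self.pseudo_r2,
            "or_het": self.or_het,
            "or_hom": self.or_hom,
        }


@dataclass(frozen=True)
class FitComparison:
    """Pseudo-r^2 of the true-MOI coding relative to the multiplicative coding."""

    ratio: float
    fit_true: FitResult
    fit_mult: FitResult
    defined: bool = True


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def fit_weighted_logistic(
    w1: np.ndarray, w0: np.ndarray, design: np.ndarray
) -> tuple[np.ndarray, float]:
    """Maximise sum_g [w1 log pi_g + w0 log(1-pi_g)] over logistic pi = expit(X beta).

    Rows with w1 + w0 = 0 are dropped.  Used for both the expected
    (infinite-population) likelihood, where the weights are half the
    case/control genotype probabilities, and finite-sample counts.

    Returns (coefficients, maximised weighted log-likelihood).
    """
    w1 = np.asarray(w1, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    w = w1 + w0
    keep = w > 0.0
    if keep.sum() < design.shape[1]:
        raise ConvergenceError("fewer populated classes than parameters")
    X, w1k, w0k, wk = design[keep], w1[keep], w0[keep], w[keep]

    # separation check: a fitted probability would be 0 or 1, and with the
    # saturated/binary codings the MLE is then at infinity
    levels = {}
    for row, a, b in zip(map(tuple, X[:, 1:]), w1k, w0k):
        c = levels.setdefault(row, [0.0, 0.0])
        c[0] += a
        c[1] += b
    if design.shape[1] > 1 and any(a == 0.0 or b == 0.0 for a, b in levels.values()):
        raise ConvergenceError("complete separation: a covariate level has only cases or only controls")

    if design.shape[1] == 1:  # intercept only: closed form
        beta = np.array([_logit(w1k.sum() / wk.sum())])
    elif len(levels) == X.shape[1]:  # saturated in the collapsed levels: closed form
        beta = _solve_saturated(X, levels)
    else:
        beta = _newton(X, w1k, wk)
    ll = float(np.sum(w1k * (X @ beta)) - np.sum(wk * np.logaddexp(0.0, X @ beta)))
    return beta, ll


def _solve_saturated(X: np.ndarray, levels: dict) -> np.ndarray:
    rows = np.array([(1.0,) + lv for lv in levels])
    eta = np.array([_logit(a / (a + b)) for a, b in levels.values()])
    return np.linalg.solve(rows, eta)


def _newton(X: np.ndarray, w1: np.ndarray, w: np.ndarray) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(NEWTON_MAX_ITER):
        pi = 1.0 / (1.0 + np.exp(-(X @ beta)))
        grad = X.T @ (w1 - w * pi)
        if np.linalg.norm(grad) < NEWTON_TOL:
            return beta
        hess = (X * (w * pi * (1.0 - pi))[:, None]).T @ X
        try:
            beta = beta + np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as err:  # pragma: no cover - degenerate design
            raise ConvergenceError(f"singular Hessian: {err}") from err
    raise ConvergenceError(f"Newton iteration did not reach gradient norm {NEWTON_TOL}")


def fit_expected(
    dist: MarkerCaseControlDistribution,
    coding: GenotypeCoding,
    pseudo_r2_method: str = "mcfadden",
    case_fraction: float = 0.5,
) -> FitResult:
    """Fit one genotype coding to the expected case-control distribution.

    ``case_fraction`` is the sampling weight of cases (0.5 = equal numbers of
    cases and controls, the study design assumed throughout).
    """
    w1 = case_fraction * dist.case_probs
    w0 = (1.0 - case_fraction) * dist.control_probs
    beta, ll = fit_weighted_logistic(w1, w0, coding.design)
    _, ll_null = fit_weighted_logistic(w1, w0, CODINGS["null"].design)
    eta = coding.design @ beta
    return FitResult(
        coding=coding,
        coefficients=beta,
        expected_loglik=ll,
        pseudo_r2=pseudo_r2(ll, ll_null, pseudo_r2_method),
        or_het=float(np.exp(eta[1] - eta[0])),
        or_hom=float(np.exp(eta[2] - eta[0])),
    )


def pseudo_r2(loglik_model: float, loglik_null: float, method: str = "mcfadden") -> float:
    """Likelihood-based explained-variation measure on per-individual log-likelihoods.

    ``mcfadden``:  1 - l_model / l_null
    ``coxsnell``:  1 - exp(2 (l_null - l_model))
    """
    if method == "mcfadden":
        r2 = 1.0 - loglik_model / loglik_null
    elif method == "coxsnell":
        r2 = 1.0 - math.exp(2.0 * (loglik_null - loglik_model))
    else:
        raise ValueError(f"unknown pseudo-r2 method {method!r}")
    return max(r2, 0.0)  # guard tiny negative round-off at the null


def fit_ratio(
    dist: MarkerCaseControlDistribution,
    true_moi: PenetranceModel,
    pseudo_r2_method: str = "mcfadden",
) -> FitComparison:
    """Pseudo-r^2 ratio of the true mode-of-inheritance coding to the multiplicative.

    A ratio near 1 means the trend coding fits (essentially) as well as the
    truth; large ratios mean the multiplicative model is unsuitable.  When
    both pseudo-r^2 values are below ``PSEUDO_R2_FLOOR`` (no association) the
    0/0 ratio is undefined: ``defined`` is False and ``ratio`` is NaN.
    """
    fit_true = fit_expected(dist, coding_for_moi(true_moi), pseudo_r2_method)
    fit_mult = fit_expected(dist, CODINGS["multiplicative_trend"], pseudo_r2_method)
    if fit_true.pseudo_r2 < PSEUDO_R2_FLOOR and fit_mult.pseudo_r2 < PSEUDO_R2_FLOOR:
        return FitComparison(math.nan, fit_true, fit_mult, defined=False)
    return FitComparison(fit_true.pseudo_r2 / fit_mult.pseudo_r2, fit_true, fit_mult)


def estimate_risks(
    dist: MarkerCaseControlDistribution, codings: list[GenotypeCoding]
) -> list[FitResult]:
    """Fit several codings to one distribution; one FitResult per coding."""
    return [fit_expected(dist, c) for c in codings]
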