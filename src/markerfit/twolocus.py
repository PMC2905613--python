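"""Two biallelic loci in linkage disequilibrium, with penetrance at one of them.

This module builds the population-genetic side of the analysis: a causal
locus A carrying risk alleles with some mode of inheritance, and a marker
locus B correlated with it (LD measured by the squared allelic correlation
r^2).  Random mating is assumed, so genotypes arise from two independent
haplotype draws, and the expected genotype distribution at the marker among
cases and among controls follows from Bayes' rule applied to the penetrances.

Genotypes are coded as counts of the risk allele (locus A) or the associated
allele (locus B), g in {0, 1, 2}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "MOI_CHOICES",
    "FeasibilityError",
    "PenetranceModel",
    "TwoLocusScenario",
    "HaplotypeDistribution",
    "JointGenotypeDistribution",
    "MarkerCaseControlDistribution",
    "haplotype_freqs",
    "max_achievable_r2",
    "feasible_marker_freq_range",
    "joint_genotype_dist",
    "marker_case_control_dist",
    "expected_marker_distribution",
]

MOI_CHOICES = ("dominant", "recessive", "multiplicative", "general")

#: requests within this distance of the LD feasibility boundary are clipped
#: onto it rather than rejected
FEASIBILITY_TOL = 1e-9

_PROB_ATOL = 1e-12


class FeasibilityError(ValueError):
    """The requested r^2 cannot be realised for the given allele frequencies."""


def _check_prob_open(name: str, x: float) -> None:
    if not (0.0 < x < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {x!r}")


@dataclass(frozen=True)
class PenetranceModel:
    """Mode of inheritance at the causal locus.

    Parameters
    ----------
    moi
        One of ``dominant``, ``recessive``, ``multiplicative``, ``general``.
    grr
        Genotype relative risk of the high-risk genotype(s): risk of the
        high-risk homozygote (and, for dominant, the heterozygote) relative
        to the low-risk homozygote.
    baseline
        Disease risk of the low-risk homozygote (default 0.05).
    grr_het
        Heterozygote relative risk; required for (and only for) the
        ``general`` mode.
    """

    moi: str
    grr: float
    baseline: float = 0.05
    grr_het: float | None = None

    def __post_init__(self) -> None:
        if self.moi not in MOI_CHOICES:
            raise ValueError(f"moi must be one of {MOI_CHOICES}, got {self.moi!r}")
        if self.grr <= 0:
            raise ValueError("grr must be positive")
        _check_prob_open("baseline", self.baseline)
        if self.moi == "general":
            if self.grr_het is None or self.grr_het <= 0:
                raise ValueError("general mode requires a positive grr_het")
        elif self.grr_het is not None:
            raise ValueError("grr_het is only meaningful for moi='general'")
        f = self.penetrances()
        if not np.all((f > 0.0) & (f < 1.0)):
            raise ValueError(f"penetrances must lie strictly in (0, 1), got {f}")
        if not np.all(np.diff(f) >= 0.0):
            raise ValueError(f"penetrances must be non-decreasing in genotype, got {f}")

    def penetrances(self) -> np.ndarray:
        """Disease probability for genotype g = 0, 1, 2 at the causal locus."""
        b, r = self.baseline, self.grr
        if self.moi == "dominant":
            f = (b, r * b, r * b)
        elif self.moi == "recessive":
            f = (b, b, r * b)
        elif self.moi == "multiplicative":
            f = (b, r * b, r * r * b)
        else:  # general
            f = (b, self.grr_het * b, r * b)
        return np.asarray(f, dtype=float)


@dataclass(frozen=True)
class TwoLocusScenario:
    """Allele frequencies and LD linking causal locus A and marker locus B.

    ``d_sign`` sets the sign of the disequilibrium coefficient D; with the
    default ``+1`` the risk allele at A is positively correlated with the
    "associated" allele at B (the opposite sign is equivalent to relabelling
    the marker alleles).
    """

    p_a: float
    p_b: float
    r2: float
    d_sign: int = 1

    def __post_init__(self) -> None:
        _check_prob_open("p_a", self.p_a)
        _check_prob_open("p_b", self.p_b)
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2!r}")
        if self.d_sign not in (1, -1):
            raise ValueError("d_sign must be +1 or -1")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "TwoLocusScenario":
        return cls(**{f.name: d[f.name] for f in fields(cls) if f.name in d})


@dataclass(frozen=True)
class HaplotypeDistribution:
    """Frequencies of the four two-locus haplotypes (capital = risk/associated allele)."""

    h_AB: float
    h_Ab: float
    h_aB: float
    h_ab: float

    def __post_init__(self) -> None:
        h = self.as_array()
        if np.any(h < -_PROB_ATOL) or abs(h.sum() - 1.0) > _PROB_ATOL:
            raise ValueError(f"invalid haplotype frequencies {h}")

    def as_array(self) -> np.ndarray:
        """2x2 array indexed by (allele at A, allele at B), 1 = risk/associated."""
        return np.array([[self.h_ab, self.h_aB], [self.h_Ab, self.h_AB]], dtype=float)

    @property
    def p_a(self) -> float:
        return self.h_AB + self.h_Ab

    @property
    def p_b(self) -> float:
        return self.h_AB + self.h_aB

    @property
    def d(self) -> float:
        """Disequilibrium coefficient D = h_AB - p_a * p_b."""
        return self.h_AB - self.p_a * self.p_b

    @property
    def r2(self) -> float:
        pa, pb = self.p_a, self.p_b
        return self.d ** 2 / (pa * (1.0 - pa) * pb * (1.0 - pb))


@dataclass(frozen=True)
class JointGenotypeDistribution:
    """3x3 table P(G_A = i, G_B = j) under random mating."""

    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (3, 3) or np.any(p < -_PROB_ATOL) or abs(p.sum() - 1.0) > _PROB_ATOL:
            raise ValueError("probs must be a non-negative 3x3 table summing to 1")
        object.__setattr__(self, "probs", p)

    @property
    def marginal_a(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    @property
    def marginal_b(self) -> np.ndarray:
        return self.probs.sum(axis=0)


@dataclass(frozen=True)
class MarkerCaseControlDistribution:
    """Expected marker-genotype distribution among cases and among controls.

    ``zero_mass`` flags genotype classes carrying no probability in either
    group (possible at LD boundaries); downstream fitting drops such classes
    from the design rather than failing here.
    """

    case_probs: np.ndarray = field(repr=False)
    control_probs: np.ndarray = field(repr=False)
    prevalence: float = 0.0

    def __post_init__(self) -> None:
        for name in ("case_probs", "control_probs"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or np.any(v < -_PROB_ATOL) or abs(v.sum() - 1.0) > _PROB_ATOL:
                raise ValueError(f"{name} must be a 3-vector of probabilities summing to 1")
            object.__setattr__(self, name, v)
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")

    @property
    def zero_mass(self) -> np.ndarray:
        """Boolean mask of genotype classes absent from both cases and controls."""
        return (self.case_probs <= 0.0) & (self.control_probs <= 0.0)


def _d_bounds(p_a: float, p_b: float) -> tuple[float, float]:
    """(|D|max for D<0, Dmax for D>0) keeping all four haplotype frequencies in [0,1]."""
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    return min(p_a * p_b, q_a * q_b), min(p_a * q_b, q_a * p_b)


def max_achievable_r2(p_a: float, p_b: float, d_sign: int = 1) -> float:
    """Largest r^2 realisable for the given allele frequencies and sign of D."""
    lo, hi = _d_bounds(p_a, p_b)
    d_max = hi if d_sign > 0 else lo
    return d_max ** 2 / (p_a * (1.0 - p_a) * p_b * (1.0 - p_b))


def haplotype_freqs(scenario: TwoLocusScenario) -> HaplotypeDistribution:
    """Haplotype frequencies implied by (p_a, p_b, r^2, sign of D).

    D = d_sign * sqrt(r^2 * p_a (1-p_a) p_b (1-p_b)); the remaining
    haplotypes follow by marginal consistency.  Requests within
    ``FEASIBILITY_TOL`` of the boundary are clipped onto it.

    Raises
    ------
    FeasibilityError
        If r^2 exceeds the maximum achievable for these frequencies, the
        error message names that maximum.
    """
    p_a, p_b, r2 = scenario.p_a, scenario.p_b, scenario.r2
    r2_max = max_achievable_r2(p_a, p_b, scenario.d_sign)
    if r2 > r2_max + FEASIBILITY_TOL:
        raise FeasibilityError(
            f"r2={r2:g} is not achievable for p_a={p_a:g}, p_b={p_b:g} "
            f"(maximal achievable r2 = {r2_max:.12g})"
        )
    r2 = min(r2, r2_max)
    d = scenario.d_sign * math.sqrt(r2 * p_a * (1.0 - p_a) * p_b * (1.0 - p_b))
    h = np.array(
        [
            p_a * p_b + d,
            p_a * (1.0 - p_b) - d,
            (1.0 - p_a) * p_b - d,
            (1.0 - p_a) * (1.0 - p_b) + d,
        ]
    )
    h = np.clip(h, 0.0, 1.0)  # boundary scenarios may round to tiny negatives
    return HaplotypeDistribution(*(h / h.sum()))


def feasible_marker_freq_range(p_a: float, r2: float, d_sign: int = 1) -> tuple[float, float]:
    """Closed interval of marker allele frequencies compatible with (p_a, r^2).

    A marker frequency p_b is feasible when |D| = sqrt(r^2 p_a q_a p_b q_b)
    keeps all four haplotype frequencies in [0, 1].  For D > 0 the Lewontin
    bounds give the closed form

        r^2 p_a / (q_a + r^2 p_a)  <=  p_b  <=  p_a / (p_a + r^2 q_a)

    (with q = 1 - p); the D < 0 case is the mirror image about 1/2.  The
    interval always contains p_a (D > 0) and collapses to {p_a} at r^2 = 1.
    """
    _check_prob_open("p_a", p_a)
    if not (0.0 < r2 <= 1.0):
        raise ValueError(f"r2 must lie in (0, 1], got {r2!r}")
    q_a = 1.0 - p_a
    lo = r2 * p_a / (q_a + r2 * p_a)
    hi = p_a / (p_a + r2 * q_a)
    if d_sign < 0:
        lo, hi = 1.0 - hi, 1.0 - lo
    return lo, hi


def joint_genotype_dist(hap: HaplotypeDistribution) -> JointGenotypeDistribution:
    """Joint genotype table from the random union of two independent gametes."""
    h = hap.as_array()
    p = np.zeros((3, 3))
    for i1 in range(2):
        for j1 in range(2):
            for i2 in range(2):
                for j2 in range(2):
                    p[i1 + i2, j1 + j2] += h[i1, j1] * h[i2, j2]
    return JointGenotypeDistribution(p / p.sum())


def marker_case_control_dist(
    joint: JointGenotypeDistribution, pen: PenetranceModel
) -> MarkerCaseControlDistribution:
    """Marker-genotype distribution in cases and controls of an infinite population.

    case_probs[j]    ∝ Σ_i P(i, j) f(i)
    control_probs[j] ∝ Σ_i P(i, j) (1 - f(i))
    """
    f = pen.penetrances()
    case = (joint.probs * f[:, None]).sum(axis=0)
    ctrl = (joint.probs * (1.0 - f)[:, None]).sum(axis=0)
    prevalence = float(case.sum())
    return MarkerCaseControlDistribution(case / case.sum(), ctrl / ctrl.sum(), prevalence)


def expected_marker_distribution(
    scenario: TwoLocusScenario, pen: PenetranceModel
) -> MarkerCaseControlDistribution:
    """Convenience chain: haplotypes -> joint genotypes -> case/control marker distribution."""
    return marker_case_control_dist(joint_genotype_dist(haplotype_freqs(scenario)), pen)
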