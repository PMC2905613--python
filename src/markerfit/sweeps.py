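"""Scenario grids: model-fit ratios, sample sizes and risk estimates vs allele frequency.

These sweeps orchestrate the two-locus model, the expected-likelihood fits
and the power machinery over the study's parameter grids and return tidy
pandas tables, one row per grid point.  Infeasible or degenerate points are
kept in the table with an explicit ``status`` flag rather than silently
dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import fit_ratio
from .power import (
    GENOME_WIDE_ALPHA,
    PowerQuery,
    UnreachablePowerError,
    lrt_noncentrality,
    min_sample_size,
    power_from_noncentrality,
)
from .twolocus import (
    FeasibilityError,
    PenetranceModel,
    TwoLocusScenario,
    expected_marker_distribution,
    feasible_marker_freq_range,
)

__all__ = [
    "SWEEP_COLUMNS",
    "MismatchSummary",
    "default_freq_grid",
    "sweep_matched_frequency",
    "sweep_fit_and_samplesize",
    "sweep_risk_estimates",
    "sweep_mismatch",
]

SWEEP_COLUMNS = [
    "moi",
    "grr",
    "baseline",
    "p_a",
    "p_b",
    "r2",
    "fit_ratio",
    "pseudo_r2_true",
    "pseudo_r2_mult",
    "or_het_true",
    "or_het_mult",
    "n_required",
    "power_at_reference_n",
    "status",
]


def default_freq_grid(step: float = 0.01) -> np.ndarray:
    """Allele-frequency grid 0.01 ... 0.99 (by default)."""
    return np.round(np.arange(step, 1.0, step), 10)


def _row(
    moi: str,
    grr: float,
    baseline: float,
    p_a: float,
    p_b: float,
    r2: float,
    reference_n: int | None,
    alpha: float,
    with_n_required: bool,
) -> dict:
    pen = PenetranceModel(moi, grr, baseline)
    row = dict(
        moi=moi, grr=grr, baseline=baseline, p_a=p_a, p_b=p_b, r2=r2,
        fit_ratio=math.nan, pseudo_r2_true=math.nan, pseudo_r2_mult=math.nan,
        or_het_true=math.nan, or_het_mult=math.nan, n_required=math.nan,
        power_at_reference_n=math.nan, status="ok",
    )
    try:
        scenario = TwoLocusScenario(p_a, p_b, r2)
        dist = expected_marker_distribution(scenario, pen)
    except FeasibilityError:
        row["status"] = "infeasible_r2"
        return row
    cmp = fit_ratio(dist, pen)
    row.update(
        fit_ratio=cmp.ratio,
        pseudo_r2_true=cmp.fit_true.pseudo_r2,
        pseudo_r2_mult=cmp.fit_mult.pseudo_r2,
        or_het_true=cmp.fit_true.or_het,
        or_het_mult=cmp.fit_mult.or_het,
    )
    if not cmp.defined:
        row["status"] = "undefined_ratio"
    coding = cmp.fit_true.coding
    if reference_n is not None:
        lam = lrt_noncentrality(dist, coding, reference_n)
        row["power_at_reference_n"] = power_from_noncentrality(lam, coding.df, alpha)
    if with_n_required:
        try:
            row["n_required"] = min_sample_size(
                PowerQuery(scenario, pen, alpha=alpha)
            ).n_required
        except UnreachablePowerError:
            row["status"] = "unreachable_power"
    return row


def sweep_matched_frequency(
    mois=("dominant", "recessive"),
    grrs=(1.1, 1.3, 2.0),
    r2s=(1.0, 0.8, 0.5),
    freqs: np.ndarray | None = None,
    baseline: float = 0.05,
    reference_n: int | None = None,
    alpha: float = GENOME_WIDE_ALPHA,
    n_required_at_r2: float | None = 1.0,
) -> pd.DataFrame:
    """Full grid with the marker allele frequency matched to the risk allele's.

    One row per (moi, grr, r2, frequency); ``n_required`` is solved only at
    ``n_required_at_r2`` (complete LD by default, where the sample-size curve
    is reported), ``power_at_reference_n`` at every point when a reference
    sample size is given.
    """
    if freqs is None:
        freqs = default_freq_grid()
    rows = [
        _row(moi, grr, baseline, p, p, r2, reference_n, alpha,
             with_n_required=(n_required_at_r2 is not None and r2 == n_required_at_r2))
        for moi in mois
        for grr in grrs
        for r2 in r2s
        for p in freqs
    ]
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def sweep_fit_and_samplesize(**kwargs) -> pd.DataFrame:
    """Fit-ratio curves for each r^2 plus the complete-LD sample-size curve."""
    kwargs.setdefault("n_required_at_r2", 1.0)
    return sweep_matched_frequency(**kwargs)


def sweep_risk_estimates(**kwargs) -> pd.DataFrame:
    """Heterozygote odds-ratio estimates under the true and multiplicative codings."""
    kwargs.setdefault("n_required_at_r2", None)
    return sweep_matched_frequency(**kwargs)


@dataclass(frozen=True)
class MismatchSummary:
    """How the fit ratio moves when the marker allele frequency differs from p_a.

    Deviations are relative to the matched-frequency (p_b = p_a) fit ratio
    and computed only over the feasible p_b interval for the given r^2.
    """

    moi: str
    grr: float
    p_a: float
    r2: float
    n_points: int
    max_relative_deviation: float
    mean_relative_change: float


def sweep_mismatch(
    p_as=(0.3, 0.5, 0.7),
    grrs=(1.1, 1.3, 2.0),
    r2s=(0.3, 0.5, 0.8),
    mois=("dominant", "recessive"),
    baseline: float = 0.05,
    p_b_step: float = 0.005,
) -> pd.DataFrame:
    """Allele-frequency-mismatch sweep.

    For each (moi, grr, p_a, r^2), the marker frequency p_b runs over its
    feasible interval (step ``p_b_step``, endpoints included) and the fit
    ratio at each p_b is compared with the matched-frequency value.
    """
    out = []
    for moi in mois:
        for grr in grrs:
            for p_a in p_as:
                pen = PenetranceModel(moi, grr, baseline)
                for r2 in r2s:
                    lo, hi = feasible_marker_freq_range(p_a, r2)
                    grid = np.arange(lo, hi, p_b_step)
                    grid = np.unique(np.concatenate([grid, [lo, hi, p_a]]))
                    ref = fit_ratio(
                        expected_marker_distribution(TwoLocusScenario(p_a, p_a, r2), pen), pen
                    ).ratio
                    ratios = np.array(
                        [
                            fit_ratio(
                                expected_marker_distribution(
                                    TwoLocusScenario(p_a, pb, r2), pen
                                ),
                                pen,
                            ).ratio
                            for pb in grid
                        ]
                    )
                    rel = (ratios - ref) / ref
                    out.append(
                        MismatchSummary(
                            moi=moi, grr=grr, p_a=p_a, r2=r2, n_points=len(grid),
                            max_relative_deviation=float(np.max(np.abs(rel))),
                            mean_relative_change=float(np.mean(rel)),
                        )
                    )
    return pd.DataFrame([vars(s) for s in out])
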