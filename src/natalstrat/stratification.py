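"""Population stratification in allele-based case-control tests.

A worked example of confounding by structure: UK regions differ in both
multiple sclerosis prevalence and the frequency of the rs1042712 lactase-gene
C allele.  Cases are drawn disproportionately from high-prevalence (northern,
low-frequency) regions, so the prevalence-weighted case allele frequency is
pulled below the population-weighted control frequency.  A case-control
allele test then detects this purely demographic difference with high power,
manufacturing a spurious "protective" (or, for single-region case series, a
"risk") association.

Alleles are counted as two independent draws per person (Hardy-Weinberg
independence); power is computed through the product-margin noncentrality
parameter of the 1-df Pearson test, consistent with the month-of-birth
machinery in :mod:`natalstrat.confounding`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .confounding import ncp_2x2, power_chi2_1df
from .io import RegionStat

__all__ = [
    "StratPowerResult",
    "overall_prevalence",
    "population_frequency",
    "case_frequency",
    "interpolate_prevalence",
    "allele_test_power",
    "whole_population_power",
]


@dataclass(frozen=True)
class StratPowerResult:
    """Power of an allele-based case-control test under structure.

    Frequencies are in percent; ``direction`` is "risk" when the case
    frequency exceeds the control frequency and "protective" otherwise.
    """

    freq_cases: float
    freq_controls: float
    n_cases: float
    n_controls: float
    ncp: float
    power: float
    tails: int
    alpha: float
    direction: str


def overall_prevalence(regions: Sequence[RegionStat]) -> float:
    """Population-weighted mean prevalence (per 100,000)."""
    if not regions:
        raise ValueError("need at least one region")
    pop = np.array([r.population for r in regions], dtype=float)
    prev = np.array([r.prevalence for r in regions], dtype=float)
    return float((pop * prev).sum() / pop.sum())


def population_frequency(regions: Sequence[RegionStat]) -> float:
    """Population-weighted mean exposure/allele frequency (%) — the
    frequency expected in controls sampled uniformly from the population."""
    if not regions:
        raise ValueError("need at least one region")
    pop = np.array([r.population for r in regions], dtype=float)
    freq = np.array([r.exposure_freq for r in regions], dtype=float)
    return float((pop * freq).sum() / pop.sum())


def case_frequency(regions: Sequence[RegionStat]) -> float:
    """Prevalence-weighted case exposure/allele frequency (%).

    Each region contributes in proportion to its expected case count
    (population x prevalence), so high-prevalence regions dominate.
    """
    if not regions:
        raise ValueError("need at least one region")
    pop = np.array([r.population for r in regions], dtype=float)
    prev = np.array([r.prevalence for r in regions], dtype=float)
    freq = np.array([r.exposure_freq for r in regions], dtype=float)
    cases = pop * prev
    if cases.sum() <= 0:
        raise ValueError("all prevalences are zero; case frequency undefined")
    return float((cases * freq).sum() / cases.sum())


def interpolate_prevalence(
    latitude: float,
    ref_low: tuple[float, float],
    ref_high: tuple[float, float],
) -> float:
    """Linear interpolation (or extrapolation) of prevalence in latitude
    between two reference (latitude, prevalence) points."""
    (lat0, prev0), (lat1, prev1) = ref_low, ref_high
    if lat0 == lat1:
        raise ValueError("reference latitudes must be distinct")
    return prev0 + (prev1 - prev0) * (latitude - lat0) / (lat1 - lat0)


def allele_test_power(
    freq_cases: float,
    freq_controls: float,
    n_cases: float,
    n_controls: float,
    alpha: float = 0.05,
    tails: int = 2,
) -> StratPowerResult:
    """Power of the allele-based 2x2 Pearson test with the given per-person
    sample sizes (2 alleles per person).

    Two-tailed power is the noncentral chi-square(1) tail above the central
    critical value; one-tailed power is the normal form
    ``Phi(sqrt(lambda) - z_{1-alpha})`` with the direction fixed by the sign
    of the case-control frequency difference.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if not (0 < freq_cases < 100 and 0 < freq_controls < 100):
        raise ValueError("frequencies must lie strictly in (0, 100) percent")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("counts must be > 0")
    p1, p0 = freq_cases / 100.0, freq_controls / 100.0
    if p1 == p0:
        lam = 0.0
    else:
        lam = ncp_2x2(p1, p0, 2.0 * n_cases, 2.0 * n_controls)
    if tails == 2:
        power = power_chi2_1df(lam, alpha)
    else:
        power = float(stats.norm.cdf(np.sqrt(lam) - stats.norm.ppf(1 - alpha)))
    return StratPowerResult(
        freq_cases=freq_cases,
        freq_controls=freq_controls,
        n_cases=n_cases,
        n_controls=n_controls,
        ncp=lam,
        power=float(power),
        tails=tails,
        alpha=alpha,
        direction="risk" if freq_cases > freq_controls else "protective",
    )


def whole_population_power(
    regions: Sequence[RegionStat], alpha: float = 0.05, tails: int = 2
) -> StratPowerResult:
    """Power of the allele test when every case in the population is compared
    with every non-case.

    Case count is ``sum(population x prevalence / 100,000)``; the case
    frequency is the prevalence-weighted mean and the control frequency its
    complement in the remaining population.
    """
    pop = np.array([r.population for r in regions], dtype=float)
    freq = np.array([r.exposure_freq for r in regions], dtype=float) / 100.0
    prev = np.array([r.prevalence for r in regions], dtype=float)
    n_cases = float((pop * prev / 1e5).sum())
    if n_cases <= 0:
        raise ValueError("zero expected cases; power undefined")
    n_controls = float(pop.sum() - n_cases)
    p_case = case_frequency(regions) / 100.0
    # complement: total allele mass minus the case share
    p_ctrl = ((pop * freq).sum() - n_cases * p_case) / n_controls
    return allele_test_power(
        freq_cases=p_case * 100.0,
        freq_controls=p_ctrl * 100.0,
        n_cases=n_cases,
        n_controls=n_controls,
        alpha=alpha,
        tails=tails,
    )
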