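"""Synthetic birth registries, region tables and structured case collections.

Real national birth statistics show ubiquitous within-year seasonality whose
amplitude grows with latitude and has declined over recent decades.  The
generator reproduces that structure with a single-harmonic daily birth rate

    r(d) = base * (1 + A * cos(2*pi*(d - peak_day) / days_in_year)),

where the realized amplitude ``A`` varies linearly with latitude (anchored
at 50 deg N) and calendar year, clamped to [0, 0.95] so daily rates stay
positive.  Monthly birth-count tables are multinomial draws over the exact
day-by-day monthly integrals of r(d), with 366-day leap years.

Region tables mimic the UK pattern: prevalence rising and exposure/allele
frequency falling with latitude.  Case collections draw each case's stratum
with probability proportional to population x prevalence x year-of-birth
weight and its month from that stratum's observed month distribution,
emulating the structured case series that confound month-of-birth studies.

No demographic realism beyond this (no maternal age, weekday or
registration-lag effects) is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import CaseMixture, MonthOfBirthTable, RegionStat
from .seasonality import days_in_year

__all__ = [
    "SeasonalityParams",
    "realized_amplitude",
    "month_probabilities",
    "simulate_birth_table",
    "simulate_registry",
    "simulate_region_stats",
    "simulate_case_collection",
    "simulate_control_collection",
]

_AMPLITUDE_CAP = 0.95
_LATITUDE_ANCHOR = 50.0


@dataclass(frozen=True)
class SeasonalityParams:
    """Parameters of the single-harmonic seasonal birth-rate model.

    ``amplitude`` is the relative seasonal amplitude at the 50 deg N anchor
    in the reference year; ``peak_day`` the day of year (1-based) of the
    rate maximum; the two slopes grade the amplitude per degree latitude and
    per calendar year.
    """

    base_daily_rate: float = 1000.0
    amplitude: float = 0.10
    peak_day: float = 100.0  # ~ April 10, a spring peak
    amplitude_latitude_slope: float = 0.0
    amplitude_year_slope: float = 0.0
    reference_year: int = 1960

    def __post_init__(self) -> None:
        if self.base_daily_rate <= 0:
            raise ValueError("base_daily_rate must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def realized_amplitude(
    params: SeasonalityParams, latitude: float, year: int
) -> tuple[float, bool]:
    """Amplitude at a (latitude, year) point and whether clamping applied."""
    a = (
        params.amplitude
        + params.amplitude_latitude_slope * (latitude - _LATITUDE_ANCHOR)
        + params.amplitude_year_slope * (year - params.reference_year)
    )
    clamped = a < 0 or a > _AMPLITUDE_CAP
    return float(np.clip(a, 0.0, _AMPLITUDE_CAP)), clamped


def _month_day_slices(year: Optional[int]):
    from .seasonality import days_in_month

    lengths = [days_in_month(year, m) for m in range(1, 13)]
    edges = np.concatenate([[0], np.cumsum(lengths)])
    return lengths, edges


def month_probabilities(
    params: SeasonalityParams, latitude: float, year: int
) -> np.ndarray:
    """Monthly birth probabilities from the exact day-by-day rate integral.

    With zero realized amplitude the probabilities are proportional to month
    lengths; a spring ``peak_day`` concentrates mass in the spring months.
    """
    n_days = days_in_year(year)
    a, _ = realized_amplitude(params, latitude, year)
    days = np.arange(1, n_days + 1, dtype=float)
    rate = params.base_daily_rate * (
        1.0 + a * np.cos(2.0 * np.pi * (days - params.peak_day) / n_days)
    )
    _, edges = _month_day_slices(year)
    monthly = np.add.reduceat(rate, edges[:-1].astype(int))
    return monthly / monthly.sum()


def check_parameter_grid(
    params: SeasonalityParams,
    latitudes: Sequence[float],
    years: Sequence[int],
) -> None:
    """Reject configurations where amplitude clamping dominates the grid.

    If more than half of the (latitude, year) combinations need clamping,
    the configuration no longer expresses the requested gradients and is
    treated as degenerate.
    """
    combos = [(lat, yr) for lat in latitudes for yr in years]
    n_clamped = sum(realized_amplitude(params, lat, yr)[1] for lat, yr in combos)
    if combos and n_clamped / len(combos) > 0.5:
        raise ValueError(
            "degenerate seasonality configuration: amplitude clamped on "
            f"{n_clamped}/{len(combos)} grid points"
        )


def simulate_birth_table(
    params: SeasonalityParams,
    label: str,
    latitude: float,
    year: int,
    total: int,
    seed,
) -> MonthOfBirthTable:
    """One multinomial month-of-birth table for a (region, year) stratum."""
    if total <= 0:
        raise ValueError("total must be > 0")
    rng = np.random.default_rng(seed)
    probs = month_probabilities(params, latitude, year)
    counts = rng.multinomial(int(total), probs)
    return MonthOfBirthTable(
        label=label, year=year, counts=counts.astype(float), latitude=latitude
    )


def simulate_registry(
    params: SeasonalityParams,
    labels: Sequence[str],
    latitudes: Sequence[float],
    years: Sequence[int],
    total_per_stratum: int,
    seed,
) -> list[MonthOfBirthTable]:
    """A registry of tables for every (region, year) combination."""
    check_parameter_grid(params, latitudes, years)
    rng = np.random.default_rng(seed)
    tables = []
    for label, lat in zip(labels, latitudes, strict=True):
        for year in years:
            probs = month_probabilities(params, lat, year)
            counts = rng.multinomial(int(total_per_stratum), probs)
            tables.append(
                MonthOfBirthTable(
                    label=label, year=year, counts=counts.astype(float), latitude=lat
                )
            )
    return tables


def simulate_region_stats(
    k: int = 11,
    latitude_range: tuple[float, float] = (50.5, 57.5),
    prevalence_gradient: float = 16.0,
    freq_gradient: float = -0.65,
    noise_sd: float = 0.0,
    seed=0,
    base_prevalence: float = 115.0,
    base_freq: float = 14.0,
    population: float = 5_500_000.0,
) -> list[RegionStat]:
    """Synthetic region table with UK-like opposing latitude gradients.

    Latitudes are evenly spaced across ``latitude_range``; prevalence rises
    and exposure frequency falls with latitude (defaults span roughly
    115-227 per 100,000 and 14.0-9.5%, matching the UK regional ranges).
    ``noise_sd`` adds independent Gaussian noise, in the units of each
    column, before clamping to valid ranges.
    """
    if k < 2:
        raise ValueError("need at least 2 regions")
    rng = np.random.default_rng(seed)
    lats = np.linspace(latitude_range[0], latitude_range[1], k)
    rel = lats - latitude_range[0]
    prev = base_prevalence + prevalence_gradient * rel + rng.normal(0, noise_sd, k)
    freq = base_freq + freq_gradient * rel + rng.normal(0, noise_sd, k)
    prev = np.maximum(prev, 0.0)
    freq = np.clip(freq, 0.0, 100.0)
    return [
        RegionStat(
            name=f"R{i+1:02d}",
            population=population,
            prevalence=float(prev[i]),
            exposure_freq=float(freq[i]),
            latitude=float(lats[i]),
        )
        for i in range(k)
    ]


def _mixture_weights(
    tables: Sequence[MonthOfBirthTable],
    regions: Sequence[RegionStat],
    year_weights: Optional[Mapping[int, float]],
) -> CaseMixture:
    by_region = {r.name: r for r in regions}
    weights = {}
    for t in tables:
        r = by_region.get(t.label)
        if r is None:
            continue
        yw = 1.0 if year_weights is None else float(year_weights.get(t.year, 0.0))
        w = r.population * r.prevalence * yw
        if w > 0:
            weights[(t.label, t.year)] = w
    if not weights:
        raise ValueError("no stratum received positive weight")
    return CaseMixture(weights=weights)


def simulate_case_collection(
    tables: Sequence[MonthOfBirthTable],
    regions: Sequence[RegionStat],
    year_weights: Optional[Mapping[int, float]],
    n: int,
    seed,
) -> MonthOfBirthTable:
    """Draw a pooled case collection from a structured population.

    Each case's stratum is drawn with probability proportional to
    population x prevalence x year weight; its birth month follows that
    stratum's observed month distribution.  The pooled table has
    ``year=None`` (it spans birth years).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    mixture = _mixture_weights(tables, regions, year_weights)
    by_key = {(t.label, t.year): t for t in tables}
    rng = np.random.default_rng(seed)
    keys = list(mixture.weights)
    probs = np.array([mixture.weights[k] for k in keys])
    stratum_counts = rng.multinomial(int(n), probs)
    counts = np.zeros(12)
    for key, m in zip(keys, stratum_counts):
        if m == 0:
            continue
        counts += rng.multinomial(int(m), by_key[key].proportions)
    return MonthOfBirthTable(label="cases", year=None, counts=counts)


def uk_like_population(seed=0, total_per_stratum: int = 50_000):
    """A structured synthetic population emulating the UK regional setting.

    Eleven regions spanning 50.5-57.5 deg N with opposing prevalence and
    exposure-frequency latitude gradients, thirty birth years (1950-1979)
    with a secular decline in seasonal amplitude (0.19 falling by 0.003 per
    year), a latitude-graded amplitude (+0.012 per degree), and a case
    year-of-birth distribution concentrated on the earlier cohorts
    (Gaussian weights centered on 1958, sd 8 years) — the typical structure
    of a prevalent-disease case series against naively averaged controls.

    Returns ``(tables, regions, year_weights)`` ready for the
    mixture/type-I-error machinery.
    """
    params = SeasonalityParams(
        amplitude=0.19,
        peak_day=100.0,
        amplitude_latitude_slope=0.012,
        amplitude_year_slope=-0.003,
        reference_year=1950,
    )
    regions = simulate_region_stats(k=11, seed=seed)
    years = range(1950, 1980)
    tables = simulate_registry(
        params,
        labels=[r.name for r in regions],
        latitudes=[r.latitude for r in regions],
        years=years,
        total_per_stratum=total_per_stratum,
        seed=seed,
    )
    yr = np.arange(1950, 1980)
    w = np.exp(-0.5 * ((yr - 1958) / 8.0) ** 2)
    year_weights = dict(zip((int(y) for y in yr), w / w.sum()))
    return tables, regions, year_weights


def simulate_control_collection(
    month_distribution: np.ndarray, n: int, seed
) -> MonthOfBirthTable:
    """Multinomial control collection from a given month distribution
    (typically the unweighted national average)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(n), np.asarray(month_distribution, dtype=float))
    return MonthOfBirthTable(label="controls", year=None, counts=counts.astype(float))
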