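"""Seasonality and comparison statistics on month-of-birth tables.

The central null model is a uniform daily birth rate: expected monthly
counts are proportional to the Gregorian length of each month (29-day
February in leap years), and a Pearson chi-square with 11 df tests the
observed counts against that expectation.  Pairwise comparisons between
tables, twelve one-month-versus-rest 2x2 tests, and the directional
spring-excess / winter-deficit pattern test used in multiple sclerosis
replication studies are built on the same machinery.  No continuity
correction is applied anywhere, for consistency with the noncentrality
theory in :mod:`natalstrat.confounding`.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import MonthOfBirthTable

__all__ = [
    "SPRING_MONTHS",
    "WINTER_MONTHS",
    "days_in_month",
    "days_in_year",
    "expected_uniform",
    "daily_rate_profile",
    "seasonality_test",
    "adjust_february",
    "compare_tables",
    "scale_table",
    "one_vs_rest_tests",
    "ms_pattern",
    "excess_prevalence_correlation",
    "SeasonalityResult",
    "CompareResult",
    "MonthTestResult",
    "PatternVerdict",
]

#: Months tested for a case excess in the replication pattern (Mar/Apr/May).
SPRING_MONTHS = (3, 4, 5)
#: Months tested for a case deficit in the replication pattern (Nov/Dec/Jan).
WINTER_MONTHS = (11, 12, 1)


def days_in_month(year: Optional[int], month: int) -> int:
    """Gregorian month length; ``year=None`` means a generic non-leap year."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    if year is None:
        year = 1950  # any non-leap year
    return calendar.monthrange(year, month)[1]


def days_in_year(year: Optional[int]) -> int:
    if year is not None and calendar.isleap(year):
        return 366
    return 365


def _month_days(year: Optional[int]) -> np.ndarray:
    return np.array([days_in_month(year, m) for m in range(1, 13)], dtype=float)


@dataclass(frozen=True)
class SeasonalityResult:
    """Chi-square test of a table against the uniform-daily-rate expectation."""

    chi2: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    excess_pct: np.ndarray


@dataclass(frozen=True)
class CompareResult:
    """Pearson chi-square comparison of two month-of-birth tables (df 11)."""

    chi2: float
    df: int
    p_value: float


@dataclass(frozen=True)
class MonthTestResult:
    """One-month-versus-rest 2x2 case/control test for a single month."""

    month: int
    odds_ratio: float
    chi2: float
    p_value: float
    direction: str  # "excess" or "deficit"
    testable: bool = True


@dataclass(frozen=True)
class PatternVerdict:
    """Outcome of the spring-excess / winter-deficit pattern test."""

    significant: bool
    months: tuple


def expected_uniform(table: MonthOfBirthTable) -> np.ndarray:
    """Expected monthly counts under a uniform daily birth rate.

    ``expected[m] = total * days_in_month / days_in_year``; conserves the
    table total exactly.
    """
    total = table.total
    if total <= 0:
        raise ValueError("table total must be > 0")
    days = _month_days(table.year)
    return total * days / days.sum()


def daily_rate_profile(table: MonthOfBirthTable) -> np.ndarray:
    """Normalized daily birth rates: monthly count per day over the year's
    mean daily rate.  The day-weighted mean of the 12 rates is exactly 1."""
    total = table.total
    if total <= 0:
        raise ValueError("table total must be > 0")
    days = _month_days(table.year)
    return (table.counts / days) / (total / days.sum())


def seasonality_test(table: MonthOfBirthTable) -> SeasonalityResult:
    """Pearson chi-square (11 df) against the uniform-rate expectation.

    ``excess_pct`` reports the per-month percentage deviation of the
    normalized daily rate from 1.
    """
    expected = expected_uniform(table)
    chi2 = float(((table.counts - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, 11))
    return SeasonalityResult(
        chi2=chi2,
        df=11,
        p_value=p,
        observed=table.counts.copy(),
        expected=expected,
        excess_pct=(daily_rate_profile(table) - 1.0) * 100.0,
    )


def adjust_february(table: MonthOfBirthTable) -> MonthOfBirthTable:
    """Reduce February by 1/29 in leap years so comparisons rest on 365 days.

    Non-leap tables (including pooled ``year=None`` tables) are returned
    unchanged.
    """
    if table.year is None or not calendar.isleap(table.year):
        return table
    counts = table.counts.copy()
    counts[1] *= 28.0 / 29.0
    return table.replace(counts=counts)


def compare_tables(a: MonthOfBirthTable, b: MonthOfBirthTable) -> CompareResult:
    """Pearson chi-square on the 2x12 contingency of two tables (df 11).

    Leap-year tables are February-adjusted first so both rows describe 365
    days.  A month with zero combined count makes the product-margin
    expectation degenerate and raises an error advising pooling.
    """
    a = adjust_february(a)
    b = adjust_february(b)
    if a.total <= 0 or b.total <= 0:
        raise ValueError("both tables need a positive total")
    obs = np.vstack([a.counts, b.counts])
    zero = np.flatnonzero(obs.sum(axis=0) == 0)
    if zero.size:
        raise ValueError(
            f"months {[int(m) + 1 for m in zero]} have zero combined count; "
            "pool adjacent months before comparing"
        )
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return CompareResult(chi2=float(chi2), df=int(df), p_value=float(p))


def scale_table(table: MonthOfBirthTable, target_total: float) -> MonthOfBirthTable:
    """Rescale counts to a target total (fractional counts retained).

    Scaling leaves the daily-rate profile, and hence every shape statistic,
    unchanged; it equalizes the leverage of tables of different sizes.
    """
    if target_total <= 0:
        raise ValueError("target_total must be > 0")
    total = table.total
    if total <= 0:
        raise ValueError("cannot scale an empty table")
    return table.replace(counts=table.counts * (target_total / total))


def _chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson statistic for a 2x2 table, no continuity correction."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan")
    return n * (a * d - b * c) ** 2 / denom


def one_vs_rest_tests(
    case_table: MonthOfBirthTable, control_table: MonthOfBirthTable
) -> list[MonthTestResult]:
    """Twelve 2x2 tests comparing case and control births in each month
    against the other eleven.

    For month *m* the table is {cases, controls} x {month m, rest}; the odds
    ratio is ``(case_m/case_rest) / (control_m/control_rest)``.  A zero
    margin makes a month untestable; it is flagged rather than dropped.
    """
    if case_table.total <= 0 or control_table.total <= 0:
        raise ValueError("both tables need a positive total")
    out = []
    case_total = case_table.total
    ctrl_total = control_table.total
    for m in range(12):
        a = case_table.counts[m]
        b = case_total - a
        c = control_table.counts[m]
        d = ctrl_total - c
        chi2 = _chi2_2x2(a, b, c, d)
        if not np.isfinite(chi2):
            out.append(
                MonthTestResult(
                    month=m + 1,
                    odds_ratio=float("nan"),
                    chi2=float("nan"),
                    p_value=float("nan"),
                    direction="excess",
                    testable=False,
                )
            )
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            case_odds = a / b if b > 0 else np.inf
            ctrl_odds = c / d if d > 0 else np.inf
            oratio = case_odds / ctrl_odds if ctrl_odds > 0 else np.inf
        out.append(
            MonthTestResult(
                month=m + 1,
                odds_ratio=float(oratio),
                chi2=chi2,
                p_value=float(stats.chi2.sf(chi2, 1)),
                direction="excess" if oratio > 1 else "deficit",
            )
        )
    return out


def ms_pattern(
    results: Sequence[MonthTestResult], alpha: float = 0.05
) -> PatternVerdict:
    """Directional pattern verdict: a nominally significant excess in any of
    March/April/May, or a nominally significant deficit in any of
    November/December/January.

    The direction must match — a significant spring *deficit* does not
    trigger the verdict.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    by_month = {r.month: r for r in results}
    if set(by_month) != set(range(1, 13)):
        raise ValueError("results must cover all 12 months")
    hits = []
    for m in SPRING_MONTHS:
        r = by_month[m]
        if r.testable and r.p_value < alpha and r.direction == "excess":
            hits.append(m)
    for m in WINTER_MONTHS:
        r = by_month[m]
        if r.testable and r.p_value < alpha and r.direction == "deficit":
            hits.append(m)
    return PatternVerdict(significant=bool(hits), months=tuple(hits))


def excess_prevalence_correlation(
    tables: Sequence[MonthOfBirthTable],
    prevalences: Sequence[float],
    month: int,
) -> float:
    """Pearson correlation across regions between the month-specific
    percentage excess in the normalized daily birth rate and disease
    prevalence."""
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    if len(tables) != len(prevalences):
        raise ValueError("need one prevalence per table")
    if len(tables) < 3:
        raise ValueError("need at least 3 regions")
    excess = np.array(
        [(daily_rate_profile(t)[month - 1] - 1.0) * 100.0 for t in tables]
    )
    prev = np.asarray(prevalences, dtype=float)
    if np.std(prev) == 0 or np.std(excess) == 0:
        raise ValueError("correlation undefined: zero variance input")
    r, _ = stats.pearsonr(excess, prev)
    return float(r)
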