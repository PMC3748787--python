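import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from natalstrat.io import MonthOfBirthTable
from natalstrat.seasonality import (
    adjust_february,
    compare_tables,
    daily_rate_profile,
    days_in_month,
    days_in_year,
    excess_prevalence_correlation,
    expected_uniform,
    ms_pattern,
    one_vs_rest_tests,
    scale_table,
    seasonality_test,
    MonthTestResult,
)


def month_length_probs(year):
    days = np.array([days_in_month(year, m) for m in range(1, 13)], float)
    return days / days.sum()


counts_strategy = st.lists(
    st.floats(min_value=1.0, max_value=1e6, allow_nan=False),
    min_size=12,
    max_size=12,
)


class TestCalendar:
    @pytest.mark.parametrize(
        "year,month,days",
        [(1960, 2, 29), (1950, 2, 28), (1970, 9, 30), (2000, 2, 29), (1900, 2, 28)],
    )
    def test_gregorian_month_lengths(self, year, month, days):
        assert days_in_month(year, month) == days

    def test_month_out_of_range(self):
        with pytest.raises(ValueError):
            days_in_month(1960, 13)

    def test_pooled_year_is_365_days(self):
        assert days_in_year(None) == 365
        assert days_in_month(None, 2) == 28


class TestExpectedUniform:
    def test_leap_year_daily_rate(self):
        table = MonthOfBirthTable("X", 1960, np.full(12, 366000 / 12))
        expected = expected_uniform(table)
        assert expected[0] == pytest.approx(31000)  # January
        assert expected[1] == pytest.approx(29000)  # leap February

    def test_non_leap_february(self):
        table = MonthOfBirthTable("X", 1950, np.full(12, 365 / 12))
        assert expected_uniform(table)[1] == pytest.approx(28)

    @given(counts=counts_strategy)
    def test_conserves_total(self, counts):
        table = MonthOfBirthTable("X", 1964, np.array(counts))
        assert expected_uniform(table).sum() == pytest.approx(table.total, rel=1e-12)


class TestDailyRateProfile:
    def test_uniform_daily_births_give_unit_rates(self):
        table = MonthOfBirthTable("X", 1950, month_length_probs(1950) * 365000)
        assert np.allclose(daily_rate_profile(table), 1.0)

    def test_doubled_march_rate(self):
        counts = month_length_probs(1970) * 365.0
        counts[2] *= 2  # double March's daily rate
        table = MonthOfBirthTable("X", 1970, counts)
        profile = daily_rate_profile(table)
        assert profile[2] / profile[0] == pytest.approx(2.0)

    @given(counts=counts_strategy)
    def test_day_weighted_mean_is_one(self, counts):
        table = MonthOfBirthTable("X", 1972, np.array(counts))
        days = np.array([days_in_month(1972, m) for m in range(1, 13)])
        mean = (daily_rate_profile(table) * days).sum() / days.sum()
        assert mean == pytest.approx(1.0, rel=1e-12)


class TestSeasonalityTest:
    def test_month_length_proportional_counts_are_null(self):
        table = MonthOfBirthTable("X", 1950, month_length_probs(1950) * 10000)
        res = seasonality_test(table)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)
        assert np.allclose(res.excess_pct, 0.0, atol=1e-9)

    def test_flat_monthly_counts_deviate(self):
        res = seasonality_test(MonthOfBirthTable("X", 1950, np.full(12, 1000.0)))
        assert res.chi2 > 0
        assert res.expected.sum() == pytest.approx(res.observed.sum(), rel=1e-9)

    def test_detects_april_excess(self):
        """A 20% April excess at n=100,000 is detected far below p=1e-6."""
        rng = np.random.default_rng(42)
        probs = month_length_probs(1950)
        probs[3] *= 1.2
        probs /= probs.sum()
        for _ in range(20):
            counts = rng.multinomial(100_000, probs).astype(float)
            res = seasonality_test(MonthOfBirthTable("X", 1950, counts))
            assert res.p_value < 1e-6


class TestAdjustFebruary:
    def test_leap_february_reduced_by_one_29th(self):
        counts = np.full(12, 1000.0)
        counts[1] = 2900.0
        adjusted = adjust_february(MonthOfBirthTable("X", 1960, counts))
        assert adjusted.counts[1] == pytest.approx(2800.0)
        assert np.array_equal(adjusted.counts[2:], counts[2:])

    def test_non_leap_untouched(self):
        table = MonthOfBirthTable("X", 1950, np.full(12, 1000.0))
        assert adjust_february(table) is table


class TestCompareTables:
    def test_self_comparison_is_null(self, flat_table):
        res = compare_tables(flat_table, flat_table)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 11

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = MonthOfBirthTable("A", 1950, rng.integers(500, 1500, 12).astype(float))
        b = MonthOfBirthTable("B", 1951, rng.integers(500, 1500, 12).astype(float))
        assert compare_tables(a, b).chi2 == pytest.approx(compare_tables(b, a).chi2)

    def test_zero_combined_month_advises_pooling(self):
        counts = np.full(12, 100.0)
        counts[5] = 0.0
        a = MonthOfBirthTable("A", 1950, counts)
        with pytest.raises(ValueError, match="pool"):
            compare_tables(a, a)

    def test_leap_pairs_are_null_after_adjustment(self):
        """Tables from identical daily rates in leap vs non-leap years
        compare as null once February is put on a 365-day basis."""
        rng = np.random.default_rng(5)
        p_nonleap = month_length_probs(1961)
        p_leap = month_length_probs(1960)
        stats_ = []
        for _ in range(400):
            a = MonthOfBirthTable("A", 1961, rng.multinomial(20000, p_nonleap).astype(float))
            b = MonthOfBirthTable("B", 1960, rng.multinomial(20000, p_leap).astype(float))
            stats_.append(compare_tables(a, b).chi2)
        mean = np.mean(stats_)
        se = np.std(stats_, ddof=1) / np.sqrt(len(stats_))
        assert abs(mean - 11.0) < 3 * se


class TestScaleTable:
    def test_halving(self):
        table = MonthOfBirthTable("X", 1950, np.full(12, 23004 / 12))
        scaled = scale_table(table, 11502)
        assert np.allclose(scaled.counts, table.counts / 2)

    def test_profile_invariant(self):
        rng = np.random.default_rng(2)
        table = MonthOfBirthTable("X", 1950, rng.integers(100, 900, 12).astype(float))
        scaled = scale_table(table, 11502)
        assert np.allclose(daily_rate_profile(scaled), daily_rate_profile(table))

    def test_identity(self):
        table = MonthOfBirthTable("X", 1950, np.arange(1.0, 13.0))
        assert np.allclose(scale_table(table, table.total).counts, table.counts)


class TestOneVsRest:
    def _tables(self):
        case = np.full(12, 1080.0 / 11)
        case[2] = 120.0
        ctrl = np.full(12, 1100.0 / 11)
        ctrl[2] = 100.0
        return (
            MonthOfBirthTable("cases", None, case),
            MonthOfBirthTable("ctrl", None, ctrl),
        )

    def test_march_odds_ratio_and_chi2(self):
        """120/1,200 case births vs 100/1,200 control births in March:
        OR = (120/1080)/(100/1100) = 1.222, chi2 = 2.00 by direct 2x2
        arithmetic."""
        results = one_vs_rest_tests(*self._tables())
        march = results[2]
        assert march.odds_ratio == pytest.approx(1.222, abs=5e-4)
        assert march.chi2 == pytest.approx(2.00, abs=5e-3)
        assert march.direction == "excess"

    def test_identical_tables_are_null(self, flat_table):
        for r in one_vs_rest_tests(flat_table, flat_table):
            assert r.odds_ratio == pytest.approx(1.0)
            assert r.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_matches_collapsed_2x2_contingency(self):
        """Each month's statistic equals scipy's uncorrected Pearson test on
        the collapsed 2x2 table (oracle equivalence)."""
        rng = np.random.default_rng(3)
        a = MonthOfBirthTable("a", None, rng.integers(50, 500, 12).astype(float))
        b = MonthOfBirthTable("b", None, rng.integers(50, 500, 12).astype(float))
        for r in one_vs_rest_tests(a, b):
            m = r.month - 1
            obs = np.array(
                [
                    [a.counts[m], a.total - a.counts[m]],
                    [b.counts[m], b.total - b.counts[m]],
                ]
            )
            chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
            assert r.chi2 == pytest.approx(chi2, rel=1e-10)
            assert r.p_value == pytest.approx(p, rel=1e-10)

    def test_zero_margin_flagged_untestable(self):
        counts = np.full(12, 100.0)
        counts[4] = 0.0
        a = MonthOfBirthTable("a", None, counts)
        b = MonthOfBirthTable("b", None, counts)
        results = one_vs_rest_tests(a, b)
        assert not results[4].testable
        assert all(r.testable for r in results if r.month != 5)


class TestMsPattern:
    @staticmethod
    def _null_results(overrides=None):
        overrides = overrides or {}
        results = []
        for m in range(1, 13):
            kwargs = dict(
                month=m, odds_ratio=1.0, chi2=0.0, p_value=1.0, direction="excess"
            )
            kwargs.update(overrides.get(m, {}))
            results.append(MonthTestResult(**kwargs))
        return results

    def test_march_excess_triggers(self):
        results = self._null_results({3: {"p_value": 0.01, "odds_ratio": 1.3}})
        verdict = ms_pattern(results, 0.05)
        assert verdict.significant and verdict.months == (3,)

    def test_march_deficit_does_not_trigger(self):
        results = self._null_results(
            {3: {"p_value": 0.01, "odds_ratio": 0.7, "direction": "deficit"}}
        )
        assert not ms_pattern(results, 0.05).significant

    def test_november_deficit_triggers(self):
        results = self._null_results(
            {11: {"p_value": 0.04, "odds_ratio": 0.8, "direction": "deficit"}}
        )
        verdict = ms_pattern(results, 0.05)
        assert verdict.significant and verdict.months == (11,)

    def test_requires_all_months(self):
        with pytest.raises(ValueError):
            ms_pattern(self._null_results()[:11], 0.05)


class TestExcessPrevalenceCorrelation:
    def test_zero_variance_prevalence_rejected(self):
        tables = [
            MonthOfBirthTable(f"R{i}", 1950, np.random.default_rng(i).integers(100, 900, 12).astype(float))
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="variance"):
            excess_prevalence_correlation(tables, [100.0] * 4, 4)

    def test_exactly_linear_gives_one(self):
        tables, prev = [], []
        base = month_length_probs(1950) * 100000
        for i in range(5):
            counts = base.copy()
            counts[3] *= 1 + 0.02 * i
            tables.append(MonthOfBirthTable(f"R{i}", 1950, counts))
            prev.append(daily_rate_profile(tables[-1])[3])
        assert excess_prevalence_correlation(tables, prev, 4) == pytest.approx(1.0)

    def test_latitude_graded_regions(self):
        """Amplitude and prevalence both rising with latitude makes the April
        excess correlate positively and the November excess negatively with
        prevalence."""
        from natalstrat.simulate import (
            SeasonalityParams,
            simulate_birth_table,
            simulate_region_stats,
        )

        params = SeasonalityParams(
            amplitude=0.05, peak_day=100.0, amplitude_latitude_slope=0.02
        )
        regions = simulate_region_stats(k=12, seed=9)
        tables = [
            simulate_birth_table(params, r.name, r.latitude, 1950, 200_000, 100 + i)
            for i, r in enumerate(regions)
        ]
        prev = [r.prevalence for r in regions]
        assert excess_prevalence_correlation(tables, prev, 4) > 0.5
        assert excess_prevalence_correlation(tables, prev, 11) < -0.5
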