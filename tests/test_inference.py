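"""Averaging, bootstrap CIs, the period comparison and descriptive contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from surgrisk import (
    LifetimeRiskEstimate,
    average_years,
    compare_periods,
    max_successive_increase,
    round_half_up,
    sex_difference,
    single_year_ci,
    simulate_registry,
    CohortSpec,
)
from surgrisk.datasets import (
    england_lifetime_risk_2016_2019,
    england_pandemic_headline,
)


def _est(value, curve=None, sex="F", method="lifetable", event_definition="first",
         period="2016", ci=None):
    if curve is None:
        curve = [value]
    s = pd.Series(
        np.asarray(curve, dtype=float),
        index=pd.Index([f"b{i}" for i in range(len(curve))], name="band"),
    )
    kw = {}
    if ci is not None:
        kw = {"ci_low": ci[0], "ci_high": ci[1]}
    return LifetimeRiskEstimate(
        value=value, method=method, event_definition=event_definition,
        sex=sex, period=period, risk_by_age=s, **kw,
    )


class TestAverageYears:
    def test_t_interval_on_four_years(self):
        # mean 61.5, SD 1.290994, t(0.975, 3) = 3.182446
        yearly = [_est(v, period=str(2016 + i)) for i, v in enumerate([60, 61, 62, 63])]
        avg = average_years(yearly, level=0.95)
        assert avg.value == pytest.approx(61.5)
        assert avg.ci_low == pytest.approx(59.446, abs=1e-3)
        assert avg.ci_high == pytest.approx(63.554, abs=1e-3)

    def test_zero_variance_collapses_interval(self):
        yearly = [_est(59.1, period=str(2016 + i)) for i in range(4)]
        avg = average_years(yearly)
        assert avg.ci_low == pytest.approx(59.1)
        assert avg.ci_high == pytest.approx(59.1)

    def test_permutation_invariant(self):
        vals = [58.0, 61.0, 60.0, 63.0]
        a = average_years([_est(v, period=str(2016 + i)) for i, v in enumerate(vals)])
        b = average_years(
            [_est(v, period=str(2016 + i)) for i, v in enumerate(reversed(vals))]
        )
        assert a.value == b.value
        assert a.ci_low == pytest.approx(b.ci_low)

    def test_curve_averaged_bandwise(self):
        yearly = [
            _est(30.0, [10.0, 30.0], period="2016"),
            _est(40.0, [20.0, 40.0], period="2017"),
        ]
        avg = average_years(yearly)
        assert avg.risk_by_age.tolist() == [15.0, 35.0]

    def test_single_year_rejected(self):
        with pytest.raises(ValueError, match="two yearly"):
            average_years([_est(60.0)])

    def test_ci_width_scales_inverse_sqrt_years(self):
        """With fixed yearly dispersion, the t-interval half-width shrinks
        as 1/sqrt(k) (modulo the t quantile)."""
        rng = np.random.default_rng(3)
        widths = {}
        for k in (4, 16):
            vals = 60 + rng.standard_normal(k)
            yearly = [_est(v, period=str(2000 + i)) for i, v in enumerate(vals)]
            avg = average_years(yearly)
            tq = stats.t.ppf(0.975, k - 1)
            widths[k] = (avg.ci_high - avg.ci_low) / tq * np.sqrt(k)
        # normalised widths estimate the same yearly SD
        assert widths[4] == pytest.approx(widths[16], rel=0.75)


class TestComparePeriods:
    def test_paired_t_on_band_curves(self):
        pre = _est(30.0, [10, 20, 30], period="pre")
        post = _est(27.0, [8, 19, 27], period="post")
        comp = compare_periods(pre, post)
        assert comp.absolute_change == pytest.approx(3.0)
        assert comp.t_statistic == pytest.approx(3.4641, abs=1e-4)
        assert comp.p_value == pytest.approx(0.0742, abs=1e-4)
        assert comp.pairing_unit == "age band"

    def test_identical_estimates(self):
        pre = _est(30.0, [10, 20, 30], period="pre")
        post = _est(30.0, [10, 20, 30], period="post")
        comp = compare_periods(pre, post)
        assert comp.absolute_change == 0.0
        assert comp.t_statistic == 0.0
        assert comp.p_value == 1.0

    def test_relative_change_matches_reported_pandemic_decrease(self):
        """79.5% -> 72.2% is a 9% relative decrease (nearest integer)."""
        pre = _est(79.5, [70, 79.5], period="pre", event_definition="all")
        post = _est(72.2, [64, 72.2], period="post", event_definition="all")
        comp = compare_periods(pre, post)
        assert round_half_up(comp.relative_change) == 9

    def test_relative_change_recovers_fraction_exactly(self):
        for r in (0.1, 0.25, 0.5, 0.9):
            pre = _est(60.0, [50, 60], period="pre")
            post = _est(60.0 * (1 - r), [50 * (1 - r), 60 * (1 - r)], period="post")
            comp = compare_periods(pre, post)
            assert comp.relative_change == pytest.approx(100 * r, rel=1e-12)

    def test_agrees_with_one_sample_t_on_differences(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(10, 80, 19)
        b = a - rng.uniform(0, 5, 19)
        comp = compare_periods(_est(a[-1], a, period="pre"), _est(b[-1], b, period="post"))
        ref = stats.ttest_1samp(a - b, 0.0)
        assert comp.t_statistic == pytest.approx(ref.statistic)
        assert comp.p_value == pytest.approx(ref.pvalue)

    def test_ci_overlap_flag(self):
        pre = _est(60.0, [54, 60], period="pre", ci=(58, 62))
        post_far = _est(40.0, [36, 40], period="post", ci=(38, 42))
        post_near = _est(59.0, [54, 59], period="post", ci=(57, 61))
        assert compare_periods(pre, post_far).ci_overlap is False
        assert compare_periods(pre, post_near).ci_overlap is True

    def test_zero_variance_nonzero_difference_warns(self):
        pre = _est(30.0, [10, 20, 30], period="pre")
        post = _est(29.0, [9, 19, 29], period="post")
        with pytest.warns(UserWarning, match="zero-variance"):
            comp = compare_periods(pre, post)
        assert comp.p_value == 0.0

    def test_mismatched_strata_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            compare_periods(_est(30.0, sex="F"), _est(20.0, sex="M"))


class TestDescriptiveContrasts:
    def test_largest_epoch_increase_women_all_surgery(self):
        col = england_lifetime_risk_2016_2019().set_index("band")["F_all"]
        frm, to, inc = max_successive_increase(col)
        assert (frm, to) == ("25-29", "30-34")
        assert round_half_up(inc, 1) == 6.6

    def test_largest_epoch_increase_men_first_surgery_tie_broken_older(self):
        # 65-69 -> 70-74 and 70-74 -> 75-79 both rise by 4.6 points; the
        # older pair is reported
        col = england_lifetime_risk_2016_2019().set_index("band")["M_first"]
        frm, to, inc = max_successive_increase(col)
        assert (frm, to) == ("70-74", "75-79")
        assert round_half_up(inc, 1) == 4.6

    def test_constant_curve_gives_zero(self):
        s = pd.Series([5.0, 5.0, 5.0], index=["a", "b", "c"])
        assert max_successive_increase(s)[2] == 0.0

    def test_sex_difference_at_45_49_all_surgery(self):
        tbl = england_lifetime_risk_2016_2019().set_index("band")
        f = LifetimeRiskEstimate(
            value=79.5, method="lifetable", event_definition="all", sex="F",
            period="pre", risk_by_age=tbl["F_all"],
        )
        m = LifetimeRiskEstimate(
            value=80.0, method="lifetable", event_definition="all", sex="M",
            period="pre", risk_by_age=tbl["M_all"],
        )
        assert sex_difference(f, m, "45-49") == pytest.approx(8.0)
        # antisymmetric in its arguments
        assert sex_difference(m, f, "45-49") == pytest.approx(-8.0)

    def test_sex_difference_identical_inputs_zero(self):
        a = _est(60.0, [50, 60], sex="F")
        b = LifetimeRiskEstimate(
            value=60.0, method="lifetable", event_definition="first", sex="M",
            period="2016", risk_by_age=a.risk_by_age,
        )
        assert sex_difference(a, b, "b0") == 0.0

    def test_sex_difference_unknown_band_rejected(self):
        a = _est(60.0, [50, 60], sex="F")
        b = LifetimeRiskEstimate(
            value=60.0, method="lifetable", event_definition="first", sex="M",
            period="2016", risk_by_age=a.risk_by_age,
        )
        with pytest.raises(KeyError):
            sex_difference(a, b, "zz")


class TestRounding:
    @pytest.mark.parametrize(
        "x,nd,expected",
        [(5.75, 0, 6.0), (31.64, 0, 32.0), (9.182, 0, 9.0), (4.55, 1, 4.6), (2.5, 0, 3.0)],
    )
    def test_round_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected


@pytest.fixture(scope="module")
def one_year_registry():
    spec = CohortSpec(cohort_size=30_000, years=(2020,), seed=21)
    return spec, simulate_registry(spec)


class TestSingleYearCI:
    def test_deterministic_given_seed(self, one_year_registry):
        _, reg = one_year_registry
        a = single_year_ci(reg.events, reg.population, reg.deaths, 2020, "F",
                           reps=1000, seed=42)
        b = single_year_ci(reg.events, reg.population, reg.deaths, 2020, "F",
                           reps=1000, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        c = single_year_ci(reg.events, reg.population, reg.deaths, 2020, "F",
                           reps=1000, seed=43)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_ci_brackets_point_estimate(self, one_year_registry):
        _, reg = one_year_registry
        est = single_year_ci(reg.events, reg.population, reg.deaths, 2020, "M",
                             reps=1000, seed=1)
        assert est.ci_low <= est.value <= est.ci_high

    def test_more_information_narrows_interval(self, one_year_registry):
        """Scaling all counts and person-years x100 shrinks the CI width."""
        from surgrisk import EventTable, MortalityTable, PopulationTable

        _, reg = one_year_registry
        small = single_year_ci(reg.events, reg.population, reg.deaths, 2020, "F",
                               reps=2000, seed=2)
        ev = reg.events.data.copy()
        ev[["all_events", "first_events"]] *= 100
        po = reg.population.data.copy()
        po["midyear_population"] *= 100
        de = reg.deaths.data.copy()
        de["deaths"] *= 100
        schema = reg.events.schema
        big = single_year_ci(
            EventTable(ev, schema), PopulationTable(po, schema),
            MortalityTable(de, schema), 2020, "F", reps=2000, seed=2,
        )
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)
        assert big.value == pytest.approx(small.value)

    def test_too_few_reps_rejected(self, one_year_registry):
        _, reg = one_year_registry
        with pytest.raises(ValueError, match="reps"):
            single_year_ci(reg.events, reg.population, reg.deaths, 2020, "F", reps=10)
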