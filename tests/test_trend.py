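import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lakeanomaly.trend import (
    TrendFit,
    assess_trend,
    classify_trend,
    criterion_magnitude,
    criterion_pattern,
    criterion_statistical,
    detection_limit_sensitivity,
    first_exceedance_day,
    fit_trend,
    leave_year_out,
    threshold_derivations,
)

from conftest import build_samples, random_cohort


def yearly_frame(years, anomalies, parameter="temperature"):
    return pd.DataFrame({
        "year": list(years),
        "parameter": parameter,
        "median_anomaly": list(anomalies),
        "p25": 0.0, "p75": 0.0, "min": 0.0, "max": 0.0,
        "n_sites": 10, "low_n_flag": False,
    })


class TestFitTrend:
    def test_exact_line(self):
        years = np.arange(1993, 2017)
        y = yearly_frame(years, 0.05 * (years - 2000))
        fit = fit_trend(y)
        assert fit.slope == pytest.approx(0.05)
        assert fit.p_value < 1e-12
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_years == 24 and fit.df_resid == 22

    def test_constant_series_is_null(self):
        fit = fit_trend(yearly_frame(range(2000, 2010), [0.0] * 10))
        assert fit.slope == 0.0 and fit.p_value == 1.0 and fit.r_squared == 0.0

    def test_too_few_years(self):
        with pytest.raises(ValueError, match=">=3 years"):
            fit_trend(yearly_frame([2000, 2001], [0.0, 1.0]))

    def test_constant_year_errors(self):
        with pytest.raises(ValueError, match="constant"):
            fit_trend(yearly_frame([2000, 2000, 2000], [0.0, 1.0, 2.0]))

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(8)
        years = np.arange(1993, 2017)
        vals = 0.03 * years + rng.normal(0, 1, len(years))
        fit = fit_trend(yearly_frame(years, vals))
        res = sm.OLS(vals, sm.add_constant(years.astype(float))).fit()
        assert fit.slope == pytest.approx(res.params[1])
        assert fit.intercept == pytest.approx(res.params[0])
        assert fit.p_value == pytest.approx(res.pvalues[1])
        assert fit.r_squared == pytest.approx(res.rsquared)

    def test_type_one_error_near_nominal(self):
        """Empirical size of the slope test on null data ~ alpha (MC oracle)."""
        rng = np.random.default_rng(123)
        years = np.arange(1993, 2017)
        n_reps, alpha = 1000, 0.05
        rejections = 0
        for _ in range(n_reps):
            vals = rng.normal(0, 1, len(years))
            if fit_trend(yearly_frame(years, vals)).p_value < alpha:
                rejections += 1
        rate = rejections / n_reps
        se = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert abs(rate - alpha) <= 2 * se

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(4)
        years = np.arange(2000, 2015)
        vals = rng.normal(0, 1, len(years))
        base = fit_trend(yearly_frame(years, vals))
        scaled = fit_trend(yearly_frame(years, vals * c))
        assert scaled.slope == pytest.approx(base.slope * c, rel=1e-9)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-6)


class TestCriteria:
    def test_statistical_published_cases(self):
        fit = lambda p: TrendFit("temperature", 0.1, 0, p, 0.5, 20, 18, 0.01)
        assert criterion_statistical(fit(0.065))       # counted as support
        assert not criterion_statistical(fit(0.14))    # not counted
        assert criterion_statistical(fit(0.013))

    def test_pattern_separated_halves(self):
        y = yearly_frame(range(2000, 2012),
                         [-1, -1, -1, -1, -1, -1, 1, 1, 1, 1, 1, 1])
        assert criterion_pattern(y)

    def test_pattern_alternating(self):
        y = yearly_frame(range(2000, 2012), [1, -1] * 6)
        assert not criterion_pattern(y)

    def test_pattern_two_thirds_boundary(self):
        # 12 years; 9 positive of which exactly 6 late; 3 negatives all early
        anoms = [1, 1, 1, -1, -1, -1, 1, 1, 1, 1, 1, 1]
        assert criterion_pattern(yearly_frame(range(2000, 2012), anoms))
        # 5 of 9 positives late -> below the 2/3 fraction
        anoms = [1, 1, 1, 1, -1, -1, -1, 1, 1, 1, 1, 1]
        assert not criterion_pattern(yearly_frame(range(2000, 2012), anoms))

    def test_pattern_zero_anomalies_excluded(self):
        y = yearly_frame(range(2000, 2008), [0, 0, 0, 0, 0, 0, 1, 1])
        assert criterion_pattern(y)  # the only nonzero years are late positives
        assert not criterion_pattern(yearly_frame(range(2000, 2008), [0.0] * 8))

    def test_pattern_needs_four_years(self):
        with pytest.raises(ValueError):
            criterion_pattern(yearly_frame([2000, 2001, 2002], [1, 0, -1]))

    def test_magnitude_published_cases(self):
        reg = threshold_derivations()
        temp = TrendFit("temperature", 0.044, 0, 0.065, 0.5, 24, 22, 0.01)
        assert criterion_magnitude(temp, reg)
        tp = TrendFit("tp", 0.05, 0, 0.013, 0.5, 21, 19, 0.01)
        assert not criterion_magnitude(tp, reg)

    def test_magnitude_boundary_is_inclusive(self):
        reg = threshold_derivations()
        at = TrendFit("chla", 0.035, 0, 0.5, 0.1, 20, 18, 0.01)
        assert criterion_magnitude(at, reg)

    def test_magnitude_unknown_parameter(self):
        reg = threshold_derivations()
        with pytest.raises(ValueError):
            criterion_magnitude(TrendFit("secchi", 1, 0, 0.5, 0, 9, 7, 1), reg)


class TestThresholds:
    def test_derived_values(self):
        reg = threshold_derivations()
        assert reg["temperature"] == 2.0 / 100
        assert reg["chla"] == 3.5 / 100
        assert reg["tn"] == 350.0 / 100
        assert reg["tp"] == 10.0 / 100
        assert reg["np_ratio"] == (61.0 - 35.0) / 100
        assert set(reg.provenance) == set(reg.thresholds)


class TestAssessTrend:
    def test_all_three_criteria(self):
        years = np.arange(1993, 2017)
        y = yearly_frame(years, 0.05 * (years - years.mean()))
        a = assess_trend(y)
        assert (a.crit_statistical, a.crit_pattern, a.crit_magnitude) == \
            (True, True, True)
        assert a.classification == "trend" and a.direction == "increasing"
        assert a.symbol == "++"

    def test_decreasing_trend(self):
        years = np.arange(1993, 2017)
        y = yearly_frame(years, -0.05 * (years - years.mean()))
        a = assess_trend(y)
        assert a.classification == "trend" and a.direction == "decreasing"
        assert a.symbol == "--"

    def test_no_trend_on_flat_series(self):
        a = assess_trend(yearly_frame(range(2000, 2012), [0.0] * 12))
        assert a.classification == "no_trend" and a.direction == "none"
        assert a.symbol == "0"

    def test_weak_trend_single_criterion(self):
        a = classify_trend("tp", slope=0.05, p_value=0.013, pattern=False)
        assert a.n_criteria_met == 1
        assert a.classification == "weak_trend" and a.symbol == "+"

    def test_multiparameter_frame_requires_selection(self):
        y = pd.concat([
            yearly_frame(range(2000, 2012), [0.0] * 12, "tn"),
            yearly_frame(range(2000, 2012), [0.0] * 12, "tp"),
        ])
        with pytest.raises(ValueError, match="exactly one parameter"):
            assess_trend(y)
        assert assess_trend(y, parameter="tn").parameter == "tn"


class TestLeaveYearOut:
    def test_point_on_line_does_not_move_slope(self):
        years = np.arange(2000, 2012)
        y = yearly_frame(years, 0.1 * (years - 2000))
        full, reduced = leave_year_out(y, 2005)
        assert reduced.slope == pytest.approx(full.slope)

    def test_refit_matches_oracle(self):
        from scipy import stats
        years = np.arange(2000, 2012)
        vals = 0.1 * (years - 2000)
        vals[0] = -5.0  # influential low year
        y = yearly_frame(years, vals)
        _, reduced = leave_year_out(y, 2000)
        oracle = stats.linregress(years[1:].astype(float), vals[1:])
        assert reduced.slope == pytest.approx(oracle.slope)
        assert reduced.p_value == pytest.approx(oracle.pvalue)

    def test_missing_year_warns_and_noops(self):
        y = yearly_frame(range(2000, 2012), range(12))
        with pytest.warns(UserWarning, match="not in the retained series"):
            full, reduced = leave_year_out(y, 1990)
        assert full == reduced


class TestDetectionLimitSensitivity:
    def test_identical_without_censoring(self):
        rng = np.random.default_rng(6)
        s = random_cohort(rng, n_sites=5, n_years=8)
        out = detection_limit_sensitivity(s, min_sites_per_year=3)
        assert out["agree"].all()

    def test_heavy_censoring_reported_not_suppressed(self):
        rng = np.random.default_rng(7)
        s = random_cohort(rng, n_sites=5, n_years=8)
        censored = s.copy()
        mask = censored["value"] < censored["value"].quantile(0.5)
        censored.loc[mask, "below_detection"] = True
        out = detection_limit_sensitivity(censored, min_sites_per_year=3)
        assert {"all", "above_detection", "agree"} <= set(out.columns)
        assert len(out) == 1  # one parameter, agreement either way is reported


class TestFirstExceedanceDay:
    def test_single_site_year(self):
        s = build_samples([
            ("a", "2000-05-15", "temperature", 20.0),
            ("a", "2000-06-10", "temperature", 26.0),  # day 162 in 2000
            ("a", "2000-07-01", "temperature", 27.0),
        ])
        res = first_exceedance_day(s)
        assert res.mean_day_of_year == pytest.approx(162)
        assert res.n_site_years == 1 and res.n_without_exceedance == 0

    def test_mean_across_site_years(self):
        s = build_samples([
            ("a", "2001-06-01", "temperature", 26.0),   # day 152
            ("b", "2001-06-21", "temperature", 26.0),   # day 172
        ])
        assert first_exceedance_day(s).mean_day_of_year == pytest.approx(162)

    def test_no_exceedance_counted(self):
        s = build_samples([
            ("a", "2001-06-01", "temperature", 26.0),
            ("b", "2001-06-01", "temperature", 20.0),
        ])
        res = first_exceedance_day(s)
        assert res.n_without_exceedance == 1

    def test_all_below_threshold_errors(self):
        s = build_samples([("a", "2001-06-01", "temperature", 20.0)])
        with pytest.raises(ValueError, match="no sample exceeds"):
            first_exceedance_day(s)

    def test_warming_series_advances_exceedance(self):
        # early window first exceeds in July, late window already in May
        rows = []
        for year, month in [(1993, 7), (1994, 7), (1995, 7),
                            (2014, 5), (2015, 5), (2016, 5)]:
            rows.append(("a", f"{year}-05-01", "temperature",
                         26.0 if month == 5 else 20.0))
            rows.append(("a", f"{year}-07-01", "temperature", 26.0))
        s = build_samples(rows)
        early = first_exceedance_day(s, year_range=(1993, 1995))
        late = first_exceedance_day(s, year_range=(2014, 2016))
        assert late.mean_day_of_year < early.mean_day_of_year
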