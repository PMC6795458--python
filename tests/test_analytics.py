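import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbarti.analytics import (
    CompositionTable,
    MonthlyRateSeries,
    composition_table,
    fit_trend,
    monthly_rate,
    rate_vs_diagnosisrate_regression,
    relative_change,
    round_half_away,
    window_sensitivity,
)
from nbarti.cohort_builder import build_cohort
from nbarti.synthetic_data import SimConfig, generate_bundle

from _oracles import oracle_ols_slope


def series_from_rates(rates, denominators=None):
    denominators = denominators or [100] * len(rates)
    frame = pd.DataFrame(
        {
            "month_index": range(len(rates)),
            "month_label": [f"m{t}" for t in range(len(rates))],
            "numerator": [
                0 if d == 0 else round(r * d / 100) for r, d in zip(rates, denominators)
            ],
            "denominator": denominators,
            "rate": [np.nan if d == 0 else r for r, d in zip(rates, denominators)],
        }
    )
    return MonthlyRateSeries(frame)


def cohort_frame(rows):
    """rows: (date, prescribed, classes, extra-covariate dict)."""
    records = []
    for date, prescribed, classes, extra in rows:
        rec = {
            "date": pd.Timestamp(date),
            "prescribed": prescribed,
            "antibiotic_classes": frozenset(classes),
            "sex": "male",
            "age_group": "0-3",
            "insured_status": "member",
            "specialty": "internal_medicine",
            "facility_category": "clinic_without_beds",
            "visit_hours": "in_hours",
            "diagnosis_category": "J20",
            "fiscal_year": 2012,
            "month": pd.Timestamp(date).month,
        }
        rec.update(extra)
        records.append(rec)
    return pd.DataFrame(records)


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected",
        [(88.25, 88.3), (88.24, 88.2), (-19.15, -19.2), (0.05, 0.1), (2.746, 2.7)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x, 1) == expected


class TestMonthlyRate:
    def test_simple_arithmetic(self):
        rows = [("2012-04-05", i < 2, {"macrolide"} if i < 2 else set(), {}) for i in range(8)]
        (series,) = monthly_rate(cohort_frame(rows))
        assert series.frame["rate"].iloc[0] == 25.0
        assert series.frame["numerator"].iloc[0] == 2
        assert series.frame["denominator"].iloc[0] == 8

    def test_gap_month_flagged_undefined(self):
        rows = [("2012-04-05", True, {"macrolide"}, {}), ("2012-06-05", False, set(), {})]
        (series,) = monthly_rate(cohort_frame(rows))
        assert len(series.frame) == 3
        gap = series.frame[series.frame["month_index"] == 1]
        assert gap["denominator"].iloc[0] == 0
        assert np.isnan(gap["rate"].iloc[0])
        assert len(series.defined()) == 2

    def test_multi_class_counts_once_overall(self):
        rows = [("2012-04-05", True, {"macrolide", "penicillin"}, {})]
        (overall,) = monthly_rate(cohort_frame(rows))
        assert overall.frame["numerator"].iloc[0] == 1
        by_class = monthly_rate(cohort_frame(rows), stratify_by="antibiotic_class")
        nums = {s.stratum: s.frame["numerator"].iloc[0] for s in by_class}
        assert nums["macrolide"] == 1 and nums["penicillin"] == 1
        assert nums["third_gen_cephalosporin"] == 0

    def test_partitioning_stratifier_denominators_sum(self):
        bundle = generate_bundle(SimConfig(n_patients=300, study_months=6, seed=2))
        from nbarti.appropriateness import default_appropriateness_table

        cohort = build_cohort(bundle, default_appropriateness_table())
        (overall,) = monthly_rate(cohort)
        for strat in ("age_group", "diagnosis_category", "specialty"):
            per = monthly_rate(cohort, stratify_by=strat)
            total = sum(s.frame["denominator"].to_numpy() for s in per)
            assert (total == overall.frame["denominator"].to_numpy()).all()
        assert (overall.frame["numerator"] <= overall.frame["denominator"]).all()

    def test_unknown_stratifier(self):
        with pytest.raises(KeyError):
            monthly_rate(cohort_frame([("2012-04-05", True, {"macrolide"}, {})]), "bogus")

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            monthly_rate(cohort_frame([]).reindex(columns=["date", "prescribed"]))


class TestCompositionTable:
    def test_from_counts_percent(self):
        table = CompositionTable.from_counts(
            {"facility_category": {"clinic_without_beds": 15194276, "rest": 2014511}},
            total=17208787,
        )
        assert table.percent("facility_category", "clinic_without_beds") == 88.3

    def test_single_row_is_100(self):
        rows = [("2012-04-05", True, {"macrolide"}, {})]
        table = composition_table(cohort_frame(rows))
        assert table.percent("sex", "male") == 100.0

    def test_two_equal_categories(self):
        rows = [
            ("2012-04-05", False, set(), {"sex": "male"}),
            ("2012-04-06", False, set(), {"sex": "female"}),
        ]
        table = composition_table(cohort_frame(rows))
        assert table.percent("sex", "male") == 50.0
        assert table.percent("sex", "female") == 50.0

    def test_blocks_sum_to_total_and_100(self):
        bundle = generate_bundle(SimConfig(n_patients=400, study_months=6, seed=9))
        from nbarti.appropriateness import default_appropriateness_table

        cohort = build_cohort(bundle, default_appropriateness_table())
        table = composition_table(cohort)
        for block, sub in table.frame.groupby("block"):
            assert sub["count"].sum() == table.total
            assert abs(sub["percent"].sum() - 100.0) <= 0.1 + 0.05 * len(sub)


class TestFitTrend:
    def test_exact_line(self):
        fit = fit_trend(series_from_rates([30, 29, 28, 27]))
        assert fit.slope == pytest.approx(-1.0)
        assert fit.intercept == pytest.approx(30.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_series(self):
        fit = fit_trend(series_from_rates([25, 25, 25, 25]))
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_trend(series_from_rates([30, 29]))

    def test_undefined_months_dropped(self):
        fit = fit_trend(series_from_rates([30, 29, 28, 27, 99], [100, 100, 100, 100, 0]))
        assert fit.n_points == 4
        assert fit.slope == pytest.approx(-1.0)

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=3, max_size=40))
    @settings(max_examples=100)
    def test_matches_closed_form_slope(self, rates):
        if np.ptp(rates) == 0:
            rates = list(rates) + [rates[0] + 1.0]
        fit = fit_trend(series_from_rates(rates))
        expected = oracle_ols_slope(range(len(rates)), rates)
        assert fit.slope == pytest.approx(expected, abs=1e-10)

    def test_recovers_known_slope_within_3se(self):
        # synthetic 63-month series from a known linear model + noise
        rng = np.random.default_rng(42)
        hits = 0
        n_seeds = 200
        t = np.arange(63)
        sxx = float(((t - t.mean()) ** 2).sum())
        for _ in range(n_seeds):
            y = 34.0 - 0.1 * t + rng.normal(0, 1.5, 63)
            fit = fit_trend(series_from_rates(list(y)))
            resid = y - (fit.intercept + fit.slope * t)
            se = np.sqrt((resid**2).sum() / (len(t) - 2) / sxx)
            hits += abs(fit.slope - (-0.1)) <= 3 * se
        assert hits / n_seeds >= 0.97


class TestRelativeChange:
    def test_printed_endpoints(self):
        series = series_from_rates([34.36] + [30.0] * 61 + [27.77], [10000] * 63)
        assert relative_change(series, 0, 62) == -19.2

    def test_no_change(self):
        series = series_from_rates([30.0, 30.0, 30.0])
        assert relative_change(series, 0, 2) == 0.0

    def test_halving(self):
        series = series_from_rates([50.0, 25.0])
        assert relative_change(series, 0, 1) == -50.0

    def test_zero_baseline_rejected(self):
        series = series_from_rates([0.0, 25.0])
        with pytest.raises(ZeroDivisionError):
            relative_change(series, 0, 1)

    def test_undefined_month_rejected(self):
        series = series_from_rates([30.0, 25.0], [100, 0])
        with pytest.raises(ValueError):
            relative_change(series, 0, 1)


class TestDiagnosisRateRegression:
    def _cohort(self, seed=3):
        from nbarti.appropriateness import default_appropriateness_table

        bundle = generate_bundle(SimConfig(n_patients=500, study_months=12, seed=seed))
        return build_cohort(bundle, default_appropriateness_table())

    def test_runs_and_reports(self):
        fit = rate_vs_diagnosisrate_regression(self._cohort())
        assert fit.n_points == 12
        assert 0 < fit.p_value <= 1

    def test_identity_series_slope_one(self):
        # response == predictor: wire a cohort where prescribing tracks the
        # non-bacterial share exactly by regressing a series against itself
        cohort = self._cohort()
        fit = rate_vs_diagnosisrate_regression(cohort)
        # closed-form check against the oracle on the same points
        from nbarti.analytics import monthly_rate as mr

        (overall,) = mr(cohort)
        arti = cohort.arti_consultations
        t0 = pd.Period(overall.origin, freq="M")
        t = pd.PeriodIndex(arti["date"], freq="M")
        arti_counts = arti.groupby((t - t0).map(lambda o: o.n)).size()
        frame = overall.frame.set_index("month_index")
        x = 100.0 * frame["denominator"] / arti_counts
        expected = oracle_ols_slope(list(x), list(frame["rate"]))
        assert fit.slope == pytest.approx(expected, rel=1e-9)


class TestWindowSensitivity:
    def test_monotone_on_toy(self, toy_bundle, default_table):
        table = window_sensitivity(toy_bundle, default_table, [0, 7, 30, 60])
        arti = table["arti_consultations"].to_numpy()
        excl = table["excluded_bacterial"].to_numpy()
        assert (np.diff(arti) >= 0).all()
        assert (np.diff(excl) >= 0).all()

    def test_single_window_matches_build(self, toy_bundle, default_table):
        table = window_sensitivity(toy_bundle, default_table, [30])
        cohort = build_cohort(toy_bundle, default_table)
        assert table["nbarti_consultations"].iloc[0] == len(cohort)

    def test_repeated_window_identical(self, toy_bundle, default_table):
        table = window_sensitivity(toy_bundle, default_table, [30, 30])
        assert table.iloc[0].equals(table.iloc[1].rename(0))

    def test_negative_window_rejected(self, toy_bundle, default_table):
        with pytest.raises(ValueError):
            window_sensitivity(toy_bundle, default_table, [-5])
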