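"""Interval construction, KM estimation, log-rank, Fisher, Wilcoxon-MW,
and response summaries."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from rrdkit.survival import (
    DAYS_PER_MONTH,
    IntervalDefinition,
    SurvivalRecord,
    build_intervals,
    fisher_exact,
    km_estimate,
    logrank_test,
    round_percent,
    summarize_responses,
    wilcoxon_mw,
)


def rec(time, event=True, group="g", sid="s"):
    return SurvivalRecord(subject_id=sid, group=group, time=time, event=event)


def anchors_row(**kw):
    base = dict(
        subject_id="P1",
        group="all",
        mono_start=pd.Timestamp("2020-01-01"),
        salvage_start=pd.Timestamp("2020-06-01"),
        progression_date=pd.NaT,
        death_date=pd.NaT,
        last_followup=pd.Timestamp("2021-01-01"),
    )
    base.update(kw)
    return pd.DataFrame([base])


class TestBuildIntervals:
    def test_death_after_365_days_is_11_99_months_event(self):
        df = anchors_row(death_date=pd.Timestamp("2020-12-31"))
        (r,) = build_intervals(df, IntervalDefinition.OS1)
        assert r.event is True
        assert r.time == pytest.approx(365 / DAYS_PER_MONTH)
        assert round(r.time, 2) == 11.99

    def test_alive_at_last_followup_censored(self):
        (r,) = build_intervals(anchors_row(), IntervalDefinition.OS1)
        assert r.event is False
        assert r.time == pytest.approx(366 / DAYS_PER_MONTH)

    def test_progression_on_start_day_is_time_zero_event(self):
        df = anchors_row(progression_date=pd.Timestamp("2020-01-01"))
        (r,) = build_intervals(df, IntervalDefinition.PFS1)
        assert r.time == 0.0 and r.event is True

    def test_pfs2_uses_earliest_of_progression_and_death(self):
        df = anchors_row(
            progression_date=pd.Timestamp("2020-08-01"),
            death_date=pd.Timestamp("2020-09-01"),
        )
        (r,) = build_intervals(df, IntervalDefinition.PFS2)
        assert r.time == pytest.approx(61 / DAYS_PER_MONTH)  # salvage->progression

    def test_os2_anchored_at_salvage_start(self):
        df = anchors_row(death_date=pd.Timestamp("2020-12-31"))
        (r,) = build_intervals(df, IntervalDefinition.OS2)
        assert r.time == pytest.approx(213 / DAYS_PER_MONTH)

    def test_subject_without_salvage_start_skipped_for_os2(self):
        df = anchors_row(salvage_start=pd.NaT)
        assert build_intervals(df, IntervalDefinition.OS2) == []

    def test_stop_before_start_names_subject(self):
        df = anchors_row(death_date=pd.Timestamp("2019-12-01"))
        with pytest.raises(ValueError, match="P1"):
            build_intervals(df, IntervalDefinition.OS1)


class TestKM:
    def test_no_censoring_median_is_first_time_s_below_half(self):
        records = [rec(t, sid=str(t)) for t in range(1, 11)]
        est = km_estimate(records)
        assert est.median == pytest.approx(5.0)

    def test_km_equals_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(10, 200)
        est = km_estimate([rec(t, sid=str(i)) for i, t in enumerate(times)])
        sf = est.survival_function["KM_estimate"]
        for t in (1.0, 5.0, 12.0):
            empirical = (times > t).mean()
            km_at_t = sf[sf.index <= t].iloc[-1]
            assert km_at_t == pytest.approx(empirical, abs=1e-12)

    def test_all_censored_survival_one_median_undefined(self):
        est = km_estimate([rec(t, event=False, sid=str(t)) for t in (1, 2, 3)])
        assert est.status == "median_undefined"
        assert est.median is None
        assert (est.survival_function["KM_estimate"] == 1.0).all()

    def test_exponential_median_recovered_within_10pct(self, rng):
        true_median = 12.0
        times = rng.exponential(true_median / np.log(2), 2000)
        est = km_estimate([rec(t, sid=str(i)) for i, t in enumerate(times)])
        assert est.median == pytest.approx(true_median, rel=0.10)
        lo, hi = est.median_ci
        assert lo < est.median < hi


class TestLogrank:
    def test_identical_groups_statistic_zero_p_one(self):
        a = [rec(t, group="A", sid=f"a{t}") for t in (1, 2, 3, 4, 5)]
        b = [rec(t, group="B", sid=f"b{t}") for t in (1, 2, 3, 4, 5)]
        res = logrank_test(a + b)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_p_invariant_under_group_relabeling(self, rng):
        records = [
            rec(t, group=g, sid=str(i))
            for i, (t, g) in enumerate(
                zip(rng.exponential(5, 60), rng.choice(["A", "B"], 60))
            )
        ]
        swapped = [
            SurvivalRecord(r.subject_id, "B" if r.group == "A" else "A",
                           r.time, r.event)
            for r in records
        ]
        assert logrank_test(records).p_value == pytest.approx(
            logrank_test(swapped).p_value
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([rec(1), rec(2)])

    def test_strong_survival_contrast_highly_significant(self, rng):
        # medians 12 vs 1.2 months at the study's arm sizes, light censoring
        a = [
            rec(t, group="continued", sid=f"a{i}",
                event=bool(rng.random() > 0.15))
            for i, t in enumerate(rng.exponential(12 / np.log(2), 38))
        ]
        b = [
            rec(t, group="stopped", sid=f"b{i}",
                event=bool(rng.random() > 0.15))
            for i, t in enumerate(rng.exponential(1.2 / np.log(2), 17))
        ]
        assert logrank_test(a + b).p_value < 0.001


class TestFisher:
    def test_perfect_separation_matches_hypergeometric_point_mass(self):
        res = fisher_exact([[0, 10], [10, 0]])
        assert res.p_value == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_zero_margin_p_one(self):
        assert fisher_exact([[0, 0], [3, 7]]).p_value == pytest.approx(1.0)

    def test_conditional_mle_odds_ratio_reported(self):
        res = fisher_exact([[8, 2], [1, 5]])
        assert res.odds_ratio > 1

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])


class TestWilcoxonMW:
    def test_identical_samples_u_half_and_p_one_region(self):
        res = wilcoxon_mw([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.u_statistic == pytest.approx(8.0)  # n1*n2/2
        assert res.p_value > 0.9

    def test_complete_separation_exact_p(self):
        res = wilcoxon_mw([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2/C(6,3)=2/20

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.5, 1, 18)
        res1 = wilcoxon_mw(x, y)
        res2 = wilcoxon_mw(np.exp(x), np.exp(y))
        assert res1.u_statistic == res2.u_statistic
        assert res1.p_value == pytest.approx(res2.p_value)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_mw([], [1.0])


class TestResponses:
    def test_dual_ici_cohort_percentages(self):
        # 3 CR/PR + 15 SD + 6 PD of 24: disease control 18 (75%)
        responses = ["CR/PR"] * 3 + ["SD"] * 15 + ["PD"] * 6
        table = summarize_responses(responses, decimals=1).set_index("category")
        assert table.loc["disease_control", "n"] == 18
        assert table.loc["disease_control", "percent"] == 75.0
        assert table.loc["CR/PR", "percent"] == 12.5
        assert table.loc["SD", "percent"] == 62.5

    def test_three_of_five_responders(self):
        table = summarize_responses(
            ["CR/PR", "CR/PR", "CR/PR", "PD", "PD"]
        ).set_index("category")
        assert table.loc["CR/PR", "percent"] == 60

    def test_zero_of_n(self):
        table = summarize_responses(["PD"] * 7).set_index("category")
        assert table.loc["disease_control", "percent"] == 0

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            summarize_responses(["CR", "SD"])

    @pytest.mark.parametrize(
        "num,den,decimals,expected",
        [(55, 75, 0, 73), (20, 75, 0, 27), (17, 55, 0, 31), (38, 55, 0, 69),
         (3, 24, 1, 12.5), (1, 8, 0, 13)],  # half rounds away from zero
    )
    def test_percentage_rounding_half_away_from_zero(
        self, num, den, decimals, expected
    ):
        assert round_percent(num, den, decimals) == expected
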