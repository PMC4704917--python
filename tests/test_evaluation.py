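import datetime as dt

import numpy as np
import pandas as pd
import pytest

from dietval.errors import (
    InsufficientDataError,
    PairingError,
    SingularityError,
    UndefinedStatisticError,
)
from dietval.evaluation import (
    EIDay,
    accuracy_regression,
    bland_altman,
    classify_reporting,
    correlations,
    evaluate_participant,
    filter_ei_days,
    filter_swa_days,
    group_compare,
    method_comparison,
    mixed_model_check,
    paired_compare,
    sample_size,
)
from dietval.physiology import MINUTES_PER_DAY, Participant, SWADayRecord


def ei_day(kj, pid="p1", date=dt.date(2013, 5, 15)):
    return EIDay(pid, date, kj)


def flat_trace(total_kj, on_minutes=1440, pid="p1", date=dt.date(2013, 5, 15)):
    """Trace whose on-body minutes sum to total_kj."""
    on = np.zeros(MINUTES_PER_DAY, bool)
    on[:on_minutes] = True
    ee = np.where(on, total_kj / max(on_minutes, 1), 0.0)
    return SWADayRecord(pid, date, ee, on)


class TestFilters:
    def test_ei_threshold_semantics(self):
        days = [ei_day(2091.0), ei_day(2092.0), ei_day(2000.0)]
        included, log = filter_ei_days(days)
        assert [d.energy_kj for d in included] == [2092.0]
        assert {e["energy_kj"] for e in log} == {2091.0, 2000.0}

    def test_ei_filter_empty_input(self):
        assert filter_ei_days([]) == ([], [])

    def test_ei_filter_idempotent(self):
        days = [ei_day(v) for v in (1500.0, 2092.0, 9000.0)]
        once, _ = filter_ei_days(days)
        twice, log = filter_ei_days(once)
        assert twice == once and log == []

    def test_wear_threshold_semantics(self):
        rec_in = flat_trace(8000, on_minutes=1140)   # 19.0 h
        rec_out = flat_trace(8000, on_minutes=1139)  # 18.98 h
        included, log = filter_swa_days([rec_in, rec_out])
        assert included == [rec_in]
        assert log[0]["wear_hours"] == pytest.approx(1139 / 60)

    def test_fully_worn_included(self):
        included, log = filter_swa_days([flat_trace(9000)])
        assert len(included) == 1 and log == []


class TestClassification:
    def test_boundaries_inclusive(self):
        assert classify_reporting(95.0, 100.0) == "plausible"
        assert classify_reporting(105.0, 100.0) == "plausible"
        assert classify_reporting(100.0, 100.0) == "plausible"

    def test_under_and_over(self):
        assert classify_reporting(70.0, 100.0) == "under"
        assert classify_reporting(106.0, 100.0) == "over"

    def test_partition(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            ei, tee = rng.uniform(100, 20000, 2)
            assert classify_reporting(ei, tee) in {"under", "plausible", "over"}

    def test_nonpositive_tee_rejected(self):
        with pytest.raises(ValueError):
            classify_reporting(5000.0, 0.0)


@pytest.fixture()
def girl():
    return Participant("p1", "female", dt.date(1997, 11, 15), 57.4, 164.9)


class TestEvaluateParticipant:
    def test_mean_based_arithmetic(self, girl):
        ei = [ei_day(8000.0, date=dt.date(2013, 5, 13)),
              ei_day(10000.0, date=dt.date(2013, 5, 14))]
        swa = [flat_trace(12000.0, date=dt.date(2013, 5, 14))]
        ev = evaluate_participant(ei, swa, girl, dt.date(2013, 5, 13))
        assert ev.ei_kj == pytest.approx(9000.0)
        assert ev.ei_minus_tee == pytest.approx(-3000.0)
        assert ev.ei_over_tee == pytest.approx(0.75)
        assert ev.reporting_class == "under"
        assert ev.has_weekend_ei_day is False  # Mon + Tue

    def test_equal_ei_and_tee_is_plausible(self, girl):
        ei = [ei_day(11000.0)]
        swa = [flat_trace(11000.0)]
        ev = evaluate_participant(ei, swa, girl, dt.date(2013, 5, 15))
        assert ev.ei_minus_tee == pytest.approx(0.0, abs=1e-6)
        assert ev.reporting_class == "plausible"

    def test_weekend_detection(self, girl):
        ei = [ei_day(9000.0, date=dt.date(2013, 5, 18))]  # a Saturday
        ev = evaluate_participant(ei, [flat_trace(9000.0)], girl, dt.date(2013, 5, 18))
        assert ev.has_weekend_ei_day is True

    def test_ratio_and_difference_fields_consistent(self, girl):
        ev = evaluate_participant(
            [ei_day(7500.0)], [flat_trace(10400.0)], girl, dt.date(2013, 5, 15)
        )
        assert ev.ei_over_tee == pytest.approx(
            1.0 + ev.ei_minus_tee / ev.tee_swa_kj, rel=1e-9
        )
        assert ev.rel_accuracy == pytest.approx(ev.ei_over_tee - 1.0, rel=1e-9)

    def test_no_days_is_insufficient(self, girl):
        with pytest.raises(InsufficientDataError):
            evaluate_participant([], [flat_trace(9000.0)], girl, dt.date(2013, 5, 15))


class TestBlandAltman:
    def test_hand_computed_example(self):
        # diffs {2, -2}: mean 0, sample SD 2*sqrt(2), LoA = +/-1.96*SD
        res = bland_altman([10.0, 12.0], [8.0, 14.0], ids=["a", "b"])
        assert res.mean_diff == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(2.8284271, abs=1e-6)
        assert res.loa_high == pytest.approx(5.5437172, abs=1e-6)
        assert res.loa_low == pytest.approx(-5.5437172, abs=1e-6)

    def test_degenerate_equal_pairs(self):
        res = bland_altman([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.mean_diff == 0.0 and res.sd_diff == 0.0
        assert res.outside_loa_ids == ()

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(10, 2, 30), rng.normal(9, 2, 30)
        ab, ba = bland_altman(x, y), bland_altman(y, x)
        assert ab.mean_diff == pytest.approx(-ba.mean_diff)
        assert ab.loa_low == pytest.approx(-ba.loa_high)
        assert ab.loa_high == pytest.approx(-ba.loa_low)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([1.0], [1.0])

    def test_normal_coverage_near_95_percent(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=10_000)
        res = bland_altman(y + 5.0, np.full(10_000, 5.0))
        inside = 1.0 - len(res.outside_loa_ids) / res.n
        assert inside == pytest.approx(0.95, abs=0.01)


class TestAssociations:
    def test_monotone_series(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 4, 9, 16, 30]})
        rho, _ = correlations(df, [("x", "y")])[("x", "y")]
        assert rho == pytest.approx(1.0)
        df["y"] = df["y"][::-1].to_numpy()
        assert correlations(df, [("x", "y")])[("x", "y")][0] == pytest.approx(-1.0)

    def test_tied_example_matches_average_rank_oracle(self):
        # x=[1,2,2,3], y=[1,2,3,3]: average-rank Pearson by hand = 5/6
        df = pd.DataFrame({"x": [1, 2, 2, 3], "y": [1, 2, 3, 3]})
        rho, _ = correlations(df, [("x", "y")])[("x", "y")]
        assert rho == pytest.approx(5 / 6)

    def test_constant_vector_undefined(self):
        df = pd.DataFrame({"x": [1, 1, 1, 1], "y": [1, 2, 3, 4]})
        with pytest.raises(UndefinedStatisticError):
            correlations(df, [("x", "y")])

    def test_identical_groups_high_p(self):
        vals = list(range(10)) * 2
        groups = ["a"] * 10 + ["b"] * 10
        assert group_compare(vals, groups) > 0.9

    def test_separated_groups_small_p(self):
        vals = list(range(10)) + list(range(100, 110))
        groups = ["a"] * 10 + ["b"] * 10
        assert group_compare(vals, groups) < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1, 2, 3], ["a", "a", "a"])

    def test_identical_pairs_convention(self):
        assert paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (1.0, 1.0)

    def test_shift_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 1, 25)
        w_p, t_p = paired_compare(a + 3.0, a)
        assert w_p < 0.001 and t_p < 0.001


class TestSampleSize:
    def test_formula_values(self):
        assert sample_size(1.0, 1.0) == 16
        assert sample_size(1000.0 / 2.8, 1000.0) == 2
        assert sample_size(1000.0, 837.0) == 23

    @pytest.mark.parametrize("sd,diff", [(0, 1), (1, 0), (-1, 1)])
    def test_nonpositive_rejected(self, sd, diff):
        with pytest.raises(ValueError):
            sample_size(sd, diff)


class TestMethodComparison:
    def frame(self, shift=0.0):
        rng = np.random.default_rng(4)
        idx = [f"p{i}" for i in range(15)]
        a = pd.DataFrame(
            {"energy_kj": rng.normal(8000, 900, 15), "iron_mg": rng.normal(11, 2, 15)},
            index=idx,
        )
        b = a + shift
        return a, b

    def test_identical_methods(self):
        a, b = self.frame()
        res = method_comparison(a, b)
        assert res["spearman_rho"].to_numpy() == pytest.approx(1.0)
        assert res["wilcoxon_p"].to_numpy() == pytest.approx(1.0)

    def test_constant_shift_detected_but_perfectly_correlated(self):
        a, b = self.frame(shift=600.0)
        res = method_comparison(a, b)
        assert res["spearman_rho"].to_numpy() == pytest.approx(1.0)
        assert (res["wilcoxon_p"] < 0.001).all()

    def test_missing_variable_is_pairing_error(self):
        a, b = self.frame()
        with pytest.raises(PairingError):
            method_comparison(a, b.drop(columns=["iron_mg"]), variables=["iron_mg"])

    def test_unmatched_participants_is_pairing_error(self):
        a, b = self.frame()
        with pytest.raises(PairingError):
            method_comparison(a, b.iloc[:10])


class TestAccuracyRegression:
    def noise_free_frame(self, n=40):
        rng = np.random.default_rng(9)
        z = rng.normal(0, 1, n)
        return pd.DataFrame({"bmi_zscore": z, "ei_minus_tee": 2.0 * z})

    def test_exact_fit_recovered_and_selected(self):
        df = self.noise_free_frame()
        res = accuracy_regression(df, "ei_minus_tee", candidates=["bmi_zscore"])
        coef = res.univariable["bmi_zscore"]["coefficients"][0]
        assert coef["coef"] == pytest.approx(2.0, abs=1e-9)
        assert res.selected == ["bmi_zscore"]
        assert res.stepwise_coefficients[0]["coef"] == pytest.approx(2.0, abs=1e-9)

    def test_pure_noise_yields_empty_model_in_most_replicates(self):
        # a pure-noise candidate enters only at the 5% false-entry rate,
        # so the stepwise model stays empty in well over 90% of replicates
        empty = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "ei_minus_tee": rng.normal(size=200),
                    "bmi_zscore": rng.normal(size=200),
                }
            )
            res = accuracy_regression(df, "ei_minus_tee", candidates=["bmi_zscore"])
            empty += not res.selected
        assert empty >= 0.9 * n_rep

    def test_tee_not_a_candidate_for_relative_outcome(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "rel_accuracy": rng.normal(size=30),
                "tee_swa_kj": rng.normal(10000, 1500, 30),
                "bmi_zscore": rng.normal(size=30),
            }
        )
        res = accuracy_regression(df, "rel_accuracy")
        assert "tee_swa_kj" not in res.univariable

    def test_rank_deficiency_names_columns(self):
        # a strong predictor plus its exact duplicate: once the first is
        # selected, adding the duplicate makes the design rank deficient
        rng = np.random.default_rng(11)
        z = rng.normal(size=30)
        df = pd.DataFrame(
            {
                "ei_minus_tee": 1500.0 * z + rng.normal(0, 10, 30),
                "bmi_zscore": z,
                "conscientiousness": 2 * z,
            }
        )
        with pytest.raises(SingularityError, match="bmi_zscore|conscientiousness"):
            accuracy_regression(
                df, "ei_minus_tee", candidates=["bmi_zscore", "conscientiousness"]
            )

    def test_too_few_observations(self):
        df = self.noise_free_frame(n=5)
        with pytest.raises(InsufficientDataError):
            accuracy_regression(df, "ei_minus_tee", candidates=["bmi_zscore"])


def test_mixed_model_keeps_well_conditioned_fixed_effect():
    rng = np.random.default_rng(21)
    n = 120
    school = rng.choice([f"s{i}" for i in range(6)], n)
    z = rng.normal(0, 1, n)
    y = 1500.0 * z + rng.normal(0, 500, n)
    df = pd.DataFrame({"ei_minus_tee": y, "bmi_zscore": z, "school": school})
    ols = accuracy_regression(df, "ei_minus_tee", candidates=["bmi_zscore"])
    mixed = mixed_model_check(df, "ei_minus_tee", ["bmi_zscore"])
    b_ols = ols.univariable["bmi_zscore"]["coefficients"][0]["coef"]
    assert mixed.params["bmi_zscore"] == pytest.approx(b_ols, rel=0.05)
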