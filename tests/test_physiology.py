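import datetime as dt

import numpy as np
import pytest

from dietval.diet_record import ACTIVITY_LEVELS
from dietval.errors import AgeRangeError
from dietval.physiology import (
    MINUTES_PER_DAY,
    PAL_TABLE,
    Participant,
    SWADayRecord,
    bmi,
    bmi_zscore,
    load_participants,
    pal_value,
    save_participants,
    schofield_bmr,
    tee_app,
    tee_swa,
    wear_hours,
    weight_status,
)


class TestBMI:
    def test_formula(self):
        assert bmi(60, 170) == pytest.approx(20.76, abs=0.005)

    def test_unit_height(self):
        assert bmi(55, 100) == pytest.approx(55.0)

    def test_linearity_in_weight(self):
        assert bmi(100, 180) == pytest.approx(2 * bmi(50, 180))

    @pytest.mark.parametrize("w,h", [(0, 170), (60, 0), (-5, 170)])
    def test_nonpositive_rejected(self, w, h):
        with pytest.raises(ValueError):
            bmi(w, h)


class TestSchofield:
    def test_adolescent_girl_hand_value(self):
        # 10-17 y female weight-only coefficients: 56*W + 2898 kJ/day
        assert schofield_bmr("female", 15.5, 57.4) == pytest.approx(6112.4)

    def test_deterministic(self):
        assert schofield_bmr("male", 15.0, 66.1) == schofield_bmr("male", 15.0, 66.1)

    def test_strictly_increasing_in_weight(self):
        assert schofield_bmr("male", 15.0, 70) > schofield_bmr("male", 15.0, 60)

    def test_age_band_boundary_uses_upper_band(self):
        # exactly 18 falls in the adult 18-30 band (documented convention)
        assert schofield_bmr("female", 18.0, 60) == pytest.approx(62 * 60 + 2036)

    def test_uncovered_age_is_range_error(self):
        with pytest.raises(AgeRangeError):
            schofield_bmr("female", 200.0, 60)

    def test_agrees_with_independent_table_lookup(self):
        # independently hand-coded coefficient table (kJ/day), 20 random triples
        table = {
            ("male", 10, 18): (74.0, 2754.0),
            ("male", 18, 30): (63.0, 2896.0),
            ("female", 10, 18): (56.0, 2898.0),
            ("female", 18, 30): (62.0, 2036.0),
        }
        rng = np.random.default_rng(42)
        for _ in range(20):
            sex = str(rng.choice(["female", "male"]))
            age = float(rng.uniform(10, 30))
            w = float(rng.uniform(35, 95))
            (a, b) = next(
                v for (s, lo, hi), v in table.items() if s == sex and lo <= age < hi
            )
            assert schofield_bmr(sex, age, w) == pytest.approx(a * w + b)


class TestPAL:
    @pytest.mark.parametrize(
        "gender,level,expected",
        [
            ("female", "very_light", 1.3), ("male", "very_light", 1.4),
            ("female", "light", 1.5), ("male", "light", 1.6),
            ("female", "moderate", 1.7), ("male", "moderate", 1.8),
            ("female", "heavy", 1.9), ("male", "heavy", 2.0),
            ("female", "very_heavy", 2.1), ("male", "very_heavy", 2.2),
        ],
    )
    def test_table_values(self, gender, level, expected):
        assert pal_value(gender, level) == pytest.approx(expected)

    def test_boy_offset_is_exactly_point_one(self):
        for level in ACTIVITY_LEVELS:
            assert pal_value("male", level) - pal_value("female", level) == pytest.approx(0.1)

    def test_strictly_increasing_across_levels(self):
        for sex in PAL_TABLE:
            vals = [pal_value(sex, lv) for lv in ACTIVITY_LEVELS]
            assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            pal_value("female", "extreme")


class TestTeeApp:
    def girl(self):
        return Participant("g1", "female", dt.date(1997, 11, 15), 57.4, 164.9)

    def test_is_bmr_times_pal(self, a_date):
        p = self.girl()
        bmr = schofield_bmr("female", p.age_years(a_date), p.weight_kg)
        assert tee_app(p, "moderate", a_date) == pytest.approx(bmr * 1.7)

    def test_monotone_in_level(self, a_date):
        p = self.girl()
        assert tee_app(p, "heavy", a_date) > tee_app(p, "moderate", a_date)

    def test_sex_ratio_at_equal_bmr(self):
        # very_light: 1.4/1.3 between a boy and a girl with identical BMR
        assert pal_value("male", "very_light") / pal_value("female", "very_light") == (
            pytest.approx(1.4 / 1.3)
        )


class TestZScore:
    def test_median_bmi_gives_zero_and_normal(self, lms):
        L, M, S = lms.lms("female", 15.0)
        assert bmi_zscore(M, 15.0, "female", lms) == pytest.approx(0.0, abs=1e-12)
        assert weight_status(M, 15.0, "female", lms) == "normal"

    def test_hand_computed_lms_transform(self, lms):
        # fixture row female/15.0: L=-1.38, M=19.55, S=0.114; BMI 22
        assert bmi_zscore(22.0, 15.0, "female", lms) == pytest.approx(0.9557057, abs=1e-6)

    def test_overweight_cutoff_boundary_inclusive(self, lms):
        cut = lms.cutoffs("female", 15.0)["overweight"]
        assert weight_status(cut, 15.0, "female", lms) == "overweight"
        assert weight_status(cut - 1e-9, 15.0, "female", lms) == "normal"

    def test_exactly_one_category_per_bmi(self, lms):
        for b in np.linspace(12, 40, 57):
            assert weight_status(float(b), 15.5, "male", lms) in {
                "thinness_grade_2", "thinness_grade_1", "normal", "overweight", "obese",
            }

    def test_categories_ordered_in_bmi(self, lms):
        order = ["thinness_grade_2", "thinness_grade_1", "normal", "overweight", "obese"]
        cats = [weight_status(b, 15.0, "male", lms) for b in (13.0, 15.0, 20.0, 24.5, 31.0)]
        assert cats == order

    def test_age_outside_table_is_range_error(self, lms):
        with pytest.raises(AgeRangeError):
            bmi_zscore(20.0, 12.0, "female", lms)


def trace(on_minutes, ee_per_minute=5.0):
    on = np.zeros(MINUTES_PER_DAY, bool)
    on[:on_minutes] = True
    ee = np.where(on, ee_per_minute, 0.0)
    return SWADayRecord("p1", dt.date(2013, 5, 15), ee, on)


class TestArmband:
    def test_wear_hours(self):
        assert wear_hours(trace(1440)) == 24.0
        assert wear_hours(trace(1140)) == 19.0
        assert wear_hours(trace(0)) == 0.0

    def test_fully_worn_is_plain_sum(self):
        assert tee_swa(trace(1440), bmr_kj=6000) == pytest.approx(1440 * 5.0)

    def test_off_body_hour_imputed_at_basal_rate(self):
        rec = trace(1380)  # 60 minutes off, zero recorded EE there
        assert tee_swa(rec, bmr_kj=6000) == pytest.approx(1380 * 5.0 + 6000 / 24)

    def test_all_off_body_day_equals_bmr(self):
        assert tee_swa(trace(0), bmr_kj=6000) == pytest.approx(6000.0)

    def test_imputation_never_reduces_total(self):
        rec = trace(1000)
        assert tee_swa(rec, 7000) >= rec.ee_kj[rec.on_body].sum()

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            SWADayRecord("p", dt.date(2013, 1, 1), np.zeros(100), np.ones(100, bool))


def test_participant_csv_round_trip(tmp_path):
    parts = [
        Participant("p1", "female", dt.date(1997, 8, 1), 57.4, 164.9,
                    parental_education="high", born_outside_sweden="none",
                    school="school_01"),
        Participant("p2", "male", dt.date(1998, 2, 10), 66.1, 176.5),
    ]
    p = tmp_path / "participants.csv"
    save_participants(parts, p)
    again = load_participants(p)
    assert again == parts
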