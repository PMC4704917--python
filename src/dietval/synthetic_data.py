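"""Seeded generator of a complete synthetic validation study.

Emulates the data a mobile food-record validation study of adolescents
produces: a food-composition database, a cohort with anthropometrics and
demographics, per-day meal records with evening questions, minute-level
armband energy-expenditure traces, and questionnaire responses — plus a
truth table so every pipeline stage can be checked by parameter recovery.

The default :class:`SimConfig` encodes the study conditions the package
targets: 81 adolescents (50 girls / 31 boys) around age 15.5, mostly
3 recording days with ~40% weekend days, armband wear averaging ~23 h/day,
a group-level reporting ratio (EI over measured TEE) of 0.71 with
log-normal between-person spread, a BMI-z gradient and a weekend shift in
reporting accuracy, and questionnaire-based TEE overstated 1.19-fold.

Structure of the generative model, per participant i and day d:

* ``TEE_true(i,d) = BMR_i x PAL_true(i,d)``, with PAL_true(i) drawn around
  the cohort activity level and a small day-to-day wobble;
* the armband trace integrates to ``TEE_true x`` mean-one log-normal noise
  (CV ``swa_noise_cv``), distributed over a diurnal minute profile, with a
  contiguous off-body gap (mean ~1 h);
* ``EI(i,d) = TEE_true(i,d) x ratio_i x`` mean-one day noise, where
  ``log ratio_i`` is centred so the cohort *median* of ratio_i equals
  ``underreport_ratio`` and shifted by the BMI-z gradient
  (``bmi_z_bias_slope``, expressed on the EI/TEE-per-z scale);
* records containing a weekend day receive a total accuracy shift of
  ``weekend_bias`` kJ/day, placed on the weekend days and centred across
  the cohort so the group-level ratio target is preserved — the
  participant-level weekend effect the accuracy regression estimates
  equals ``weekend_bias`` exactly;
* meals are composed greedily from the generated food database so that
  the record's computed energy matches EI(i,d) to well within 1%;
* the evening activity answer is the level whose PAL multiplier is
  nearest to ``PAL_true x pal_overstatement x`` noise, so questionnaire
  TEE overstates measured TEE by the configured factor at the median.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diet_record import (
    DailyQuestions,
    DietDay,
    MealItem,
    MealRecord,
    save_diet_days,
)
from .errors import GenerationError
from .evaluation import EIDay
from .food_db import FoodDatabase, FoodItem, PortionUnit, save_food_db
from .physiology import (
    MINUTES_PER_DAY,
    PAL_TABLE,
    LMSTable,
    Participant,
    SWADayRecord,
    load_lms_table,
    pal_value,
    save_swa_records,
    schofield_bmr,
)
from .questionnaire import QuestionnaireResponse, save_responses

__all__ = [
    "SimConfig",
    "SyntheticStudy",
    "generate_study",
    "generate_food_db",
    "generate_questionnaires",
    "write_study",
    "computed_ei_days",
    "app_tee_days",
    "evaluation_frame",
]

#: Energy factors used by the generator (kJ per gram of macronutrient).
KJ_PER_G_PROTEIN = 17.0
KJ_PER_G_CARB = 17.0
KJ_PER_G_FAT = 37.0

_FOOD_GROUPS = (
    "Dairy", "Bread and cereals", "Fruit", "Vegetables", "Meat", "Fish",
    "Poultry", "Legumes", "Sweets and snacks", "Beverages", "Fats and oils",
    "Prepared dishes",
)

# (protein, carbohydrate, fat) ranges per 100 g for each group
_MACRO_RANGES = {
    "Dairy": ((3, 10), (3, 8), (0.5, 10)),
    "Bread and cereals": ((6, 12), (40, 70), (1, 8)),
    "Fruit": ((0.3, 1.5), (8, 18), (0.1, 0.5)),
    "Vegetables": ((1, 4), (3, 10), (0.1, 1)),
    "Meat": ((17, 25), (0, 2), (5, 25)),
    "Fish": ((15, 22), (0, 2), (2, 15)),
    "Poultry": ((18, 24), (0, 1), (2, 12)),
    "Legumes": ((6, 10), (10, 20), (0.5, 3)),
    "Sweets and snacks": ((2, 8), (45, 70), (10, 30)),
    "Beverages": ((0, 3), (4, 12), (0, 2)),
    "Fats and oils": ((0, 1), (0, 1), (40, 82)),
    "Prepared dishes": ((5, 12), (10, 25), (3, 15)),
}

#: 49 nutrient column labels used by the generated database.
NUTRIENT_NAMES = (
    "protein_g", "carbohydrate_g", "fat_g", "sucrose_g", "monosaccharides_g",
    "saturated_fat_g", "monounsaturated_fat_g", "polyunsaturated_fat_g",
    "fibre_g", "alcohol_g", "water_g", "ash_g", "vitamin_a_ug", "vitamin_d_ug",
    "vitamin_e_mg", "vitamin_k_ug", "thiamin_mg", "riboflavin_mg", "niacin_mg",
    "vitamin_b6_mg", "vitamin_b12_ug", "folate_ug", "vitamin_c_mg",
    "pantothenic_acid_mg", "biotin_ug", "carotene_ug", "retinol_ug",
    "calcium_mg", "iron_mg", "magnesium_mg", "phosphorus_mg", "potassium_mg",
    "sodium_mg", "zinc_mg", "copper_mg", "iodine_ug", "selenium_ug",
    "manganese_mg", "chromium_ug", "molybdenum_ug", "cholesterol_mg",
    "trans_fat_g", "omega3_g", "omega6_g", "starch_g", "whole_grain_g",
    "salt_g", "caffeine_mg", "lactose_g",
)

_SCHOOLS = tuple(f"school_{i:02d}" for i in range(1, 13))

_EDU_LEVELS = ("low", "medium", "high")
_EDU_PROBS = (0.18, 0.32, 0.50)  # collapsed five-level answer
_BORN_LEVELS = ("none", "only_parents", "only_participant", "participant_and_parents")
_BORN_PROBS = (0.72, 0.25, 0.01, 0.02)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study; the defaults are the study
    conditions described in the module docstring."""

    seed: int = 0
    n_participants: int = 81
    prop_girls: float = 50.0 / 81.0
    age_mean: float = 15.5
    age_sd: float = 0.37
    age_range: tuple[float, float] = (14.0, 16.5)
    height_cm_mean: Mapping[str, float] = field(
        default_factory=lambda: {"female": 164.9, "male": 176.5}
    )
    height_cm_sd: Mapping[str, float] = field(
        default_factory=lambda: {"female": 10.0, "male": 8.9}
    )
    bmi_z_mean: float = 0.44
    bmi_z_sd: float = 0.62
    record_day_probs: tuple[float, ...] = (0.12, 0.14, 0.67, 0.05, 0.015, 0.005)
    prop_weekend_days: float = 0.4
    true_pal_mean: float = 1.48
    true_pal_sd: float = 0.15
    pal_day_cv: float = 0.05
    underreport_ratio: float = 0.71
    reporting_ratio_sigma: float = 0.33
    ei_day_cv: float = 0.25
    bmi_z_bias_slope: float = -0.13
    weekend_bias: float = 1557.0
    swa_noise_cv: float = 0.10
    wear_gap_mean_min: float = 60.0
    wear_gap_sd_min: float = 45.0
    pal_overstatement: float = 1.19
    pal_report_cv: float = 0.08
    daily_question_prob: float = 0.85
    missingness_scale: float = 1.0
    n_foods: int = 60

    def __post_init__(self) -> None:
        for name in ("prop_girls", "prop_weekend_days", "daily_question_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.underreport_ratio <= 0 or self.pal_overstatement <= 0:
            raise ValueError("ratio targets must be positive")
        if abs(sum(self.record_day_probs) - 1.0) > 1e-9:
            raise ValueError("record_day_probs must sum to 1")


@dataclass
class SyntheticStudy:
    """A full generated study plus its ground truth."""

    config: SimConfig
    food_db: FoodDatabase
    participants: list[Participant]
    diet_days: list[DietDay]
    swa_records: list[SWADayRecord]
    questionnaire_responses: list[QuestionnaireResponse]
    truth: pd.DataFrame  # one row per participant


def _lognormal_mean_one(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    s2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2), size=size)


# ---------------------------------------------------------------------------
# food database


def generate_food_db(config: SimConfig, rng: np.random.Generator | None = None) -> FoodDatabase:
    """Generate a >=50-item food database across >=10 food groups.

    Energy is computed from the drawn macronutrients with the generator's
    factors (17 kJ/g protein and carbohydrate, 37 kJ/g fat), so every item
    satisfies the energy-macronutrient consistency invariant exactly.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_per_group = max(1, config.n_foods // len(_FOOD_GROUPS))
    items = []
    k = 0
    for group in _FOOD_GROUPS:
        (plo, phi), (clo, chi), (flo, fhi) = _MACRO_RANGES[group]
        for j in range(n_per_group):
            k += 1
            protein = round(float(rng.uniform(plo, phi)), 2)
            carb = round(float(rng.uniform(clo, chi)), 2)
            fat = round(float(rng.uniform(flo, fhi)), 2)
            energy = round(
                KJ_PER_G_PROTEIN * protein + KJ_PER_G_CARB * carb + KJ_PER_G_FAT * fat, 1
            )
            nutrients = {"protein_g": protein, "carbohydrate_g": carb, "fat_g": fat}
            for name in NUTRIENT_NAMES[3:]:
                nutrients[name] = round(float(rng.gamma(1.5, 8.0)), 3)
            units = [PortionUnit("gram", 1.0), PortionUnit("tablespoon", 15.0),
                     PortionUnit("teaspoon", 5.0)]
            if group in ("Beverages", "Dairy"):
                units.append(PortionUnit("deciliter", round(float(rng.uniform(98, 105)), 1)))
            if group not in ("Beverages", "Fats and oils"):
                units.append(PortionUnit("piece", round(float(rng.uniform(20, 150)), 1)))
            items.append(
                FoodItem(
                    food_id=f"F{k:03d}",
                    name=f"Synthetic {group.lower()} {j + 1}",
                    food_group=group,
                    energy_kj_per_100g=energy,
                    nutrients_per_100g=nutrients,
                    units=tuple(units),
                )
            )
    return FoodDatabase.from_items(items, version="synthetic-1")


# ---------------------------------------------------------------------------
# cohort


def _draw_participants(
    config: SimConfig,
    rng: np.random.Generator,
    lms: LMSTable,
    anchor_dates: Sequence[dt.date],
) -> tuple[list[Participant], np.ndarray, np.ndarray]:
    """Participants plus their (age, BMI z) draws.

    BMI z is drawn directly and inverted through the LMS reference, so the
    cohort's z distribution is exact by construction and weight follows
    from height and BMI.  Each birth date is anchored to the participant's
    own first recording day, so the age at evaluation equals the drawn age
    and stays within the LMS reference coverage.
    """
    n = config.n_participants
    n_girls = int(round(config.prop_girls * n))
    genders = np.array(["female"] * n_girls + ["male"] * (n - n_girls))
    rng.shuffle(genders)
    lo, hi = config.age_range
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), lo + 0.1, hi - 0.1)
    zs = np.clip(rng.normal(config.bmi_z_mean, config.bmi_z_sd, n), -3.5, 3.5)
    participants = []
    for i in range(n):
        sex = str(genders[i])
        height = float(
            np.clip(rng.normal(config.height_cm_mean[sex], config.height_cm_sd[sex]), 140, 205)
        )
        bmi = lms.bmi_from_z(sex, float(ages[i]), float(zs[i]))
        weight = round(bmi * (height / 100.0) ** 2, 1)
        birth = anchor_dates[i] - dt.timedelta(days=round(float(ages[i]) * 365.2425))
        participants.append(
            Participant(
                participant_id=f"P{i + 1:03d}",
                gender=sex,
                birth_date=birth,
                weight_kg=weight,
                height_cm=round(height, 1),
                parental_education=str(rng.choice(_EDU_LEVELS, p=_EDU_PROBS)),
                born_outside_sweden=str(rng.choice(_BORN_LEVELS, p=_BORN_PROBS)),
                special_diet=None,
                school=str(rng.choice(_SCHOOLS)),
            )
        )
    return participants, ages, zs


def _draw_record_dates(
    config: SimConfig, rng: np.random.Generator, n_days: int
) -> list[dt.date]:
    """Distinct dates within one calendar week of 2013, with weekday
    weights tuned so the marginal weekend share matches the target."""
    p_w = config.prop_weekend_days
    weights = np.array([(1 - p_w) / 5] * 5 + [p_w / 2] * 2)
    week_start = dt.date(2013, 1, 7) + dt.timedelta(weeks=int(rng.integers(0, 50)))
    idx = rng.choice(7, size=n_days, replace=False, p=weights)
    return sorted(week_start + dt.timedelta(days=int(i)) for i in idx)


# ---------------------------------------------------------------------------
# meals


_MEAL_PLAN = (("breakfast", dt.time(7, 30)), ("lunch", dt.time(12, 0)),
              ("dinner", dt.time(18, 0)), ("snack", dt.time(15, 0)))


def _compose_meals(
    target_kj: float, date: dt.date, db: FoodDatabase, rng: np.random.Generator
) -> tuple[MealRecord, ...]:
    """Greedy knapsack: random foods in gram portions until each meal hits
    its share of the day's energy; the last portion is scaled exactly."""
    food_ids = list(db.items)
    min_energy = min(db.items[f].energy_kj_per_100g for f in food_ids)
    if target_kj < min_energy * 0.01:  # less than 1 g of the lightest food
        raise GenerationError(
            f"daily energy target {target_kj:.0f} kJ below smallest composable item"
        )
    shares = rng.dirichlet((5.0, 6.0, 6.0, 3.0))
    meals = []
    for (mtype, mtime), share in zip(_MEAL_PLAN, shares):
        meal_target = share * target_kj
        items: list[MealItem] = []
        remaining = meal_target
        for _ in range(6):
            food = db.items[food_ids[int(rng.integers(len(food_ids)))]]
            e100 = food.energy_kj_per_100g
            if e100 <= 0:
                continue
            grams = float(rng.uniform(40, 220))
            if grams / 100.0 * e100 >= remaining or len(items) == 5:
                grams = remaining / e100 * 100.0
                if grams > 0.05:
                    items.append(MealItem(food.food_id, "gram", round(grams, 2)))
                remaining = 0.0
                break
            items.append(MealItem(food.food_id, "gram", round(grams, 2)))
            remaining -= grams / 100.0 * e100
        if remaining > 0.0 and remaining > 0.005 * target_kj:
            # top up with the last drawn food
            food = db.items[food_ids[int(rng.integers(len(food_ids)))]]
            if food.energy_kj_per_100g > 0:
                items.append(
                    MealItem(food.food_id, "gram",
                             round(remaining / food.energy_kj_per_100g * 100.0, 2))
                )
        meals.append(MealRecord(date=date, time=mtime, meal_type=mtype, items=tuple(items)))
    return tuple(meals)


# ---------------------------------------------------------------------------
# armband traces


def _diurnal_profile(rng: np.random.Generator) -> np.ndarray:
    """Relative minute weights: low overnight, higher during the day."""
    minutes = np.arange(MINUTES_PER_DAY)
    hours = minutes / 60.0
    base = np.where((hours < 7.0) | (hours >= 23.0), 0.55, 1.15)
    return base * (1.0 + 0.08 * np.sin(2 * np.pi * (hours - 12) / 24))


def _make_trace(
    pid: str,
    date: dt.date,
    total_kj: float,
    bmr_kj: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> SWADayRecord:
    mu, sd = config.wear_gap_mean_min, config.wear_gap_sd_min
    if mu > 0 and sd > 0:
        shape = (mu / sd) ** 2
        n_off = int(np.clip(round(rng.gamma(shape, mu / shape)), 0, 420))
    else:
        n_off = 0
    on_body = np.ones(MINUTES_PER_DAY, dtype=bool)
    if n_off:
        start = int(rng.integers(0, MINUTES_PER_DAY - n_off + 1))
        on_body[start:start + n_off] = False
    on_target = max(total_kj - n_off * bmr_kj / MINUTES_PER_DAY, 0.1 * bmr_kj)
    weights = _diurnal_profile(rng)[on_body]
    ee = np.zeros(MINUTES_PER_DAY)
    ee[on_body] = on_target * weights / weights.sum()
    ee[~on_body] = 0.0
    return SWADayRecord(participant_id=pid, date=date, ee_kj=ee, on_body=on_body)


# ---------------------------------------------------------------------------
# questionnaires


def generate_questionnaires(
    participants: Sequence[Participant],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[QuestionnaireResponse]:
    """Item-level responses with missingness at the study's observed rates.

    Per-field missingness probabilities mirror the anchor study's counts
    (out of 81: figure-rating 2, breakfast+lunch 1, conscientiousness 7,
    social desirability 3, uncontrolled eating 2, cognitive restraint 3),
    scaled by ``missingness_scale`` (0 disables missingness).
    """
    rng = rng or np.random.default_rng(config.seed + 7)
    s = config.missingness_scale
    p = {"frs": 2 / 81 * s, "meals": 1 / 81 * s, "consc": 7 / 81 * s,
         "sds": 3 / 81 * s, "ue": 2 / 81 * s, "cr": 3 / 81 * s}
    cr_ids = {2, 11, 12, 15, 16, 18}
    ue_ids = {1, 4, 5, 7, 8, 9, 13, 14, 17}
    out = []
    for part in participants:
        trait = rng.normal(0.0, 0.8)

        def ordinal(center: float, lo: int, hi: int, n: int) -> list[float]:
            vals = np.clip(np.rint(rng.normal(center + trait, 0.9, n)), lo, hi)
            return [float(v) for v in vals]

        consc = ordinal(3.6, 1, 5, 15)
        fne = ordinal(2.2, 1, 5, 5)
        sds = [float(v) for v in (rng.random(7) < 0.62).astype(float)]
        tfeq = ordinal(2.0, 1, 4, 18)
        frs_cur = float(np.clip(round(rng.normal(5.0, 1.4)), 1, 9))
        frs_ideal = float(np.clip(round(frs_cur + rng.normal(-0.5, 1.0)), 1, 9))
        breakfast = float(rng.choice([7, 6, 5, 4, 3], p=[0.67, 0.12, 0.09, 0.07, 0.05]))
        lunch = float(rng.choice([5, 4, 3, 2], p=[0.69, 0.15, 0.10, 0.06]))

        def attitude(p_yes, p_some):
            return str(rng.choice(["yes", "somewhat", "no"],
                                  p=[p_yes, p_some, 1 - p_yes - p_some]))

        # inject missingness
        if rng.random() < p["frs"]:
            frs_ideal = None
        if rng.random() < p["meals"]:
            breakfast, lunch = None, None
        if rng.random() < p["consc"]:
            for i in rng.choice(15, size=int(rng.integers(1, 4)), replace=False):
                consc[i] = None
        if rng.random() < p["sds"]:
            sds[int(rng.integers(7))] = None
        if rng.random() < p["ue"]:
            tfeq[list(ue_ids)[int(rng.integers(len(ue_ids)))] - 1] = None
        if rng.random() < p["cr"]:
            ids = rng.choice(sorted(cr_ids), size=int(rng.integers(1, 4)), replace=False)
            for i in ids:
                tfeq[i - 1] = None
        out.append(
            QuestionnaireResponse(
                participant_id=part.participant_id,
                conscientiousness_items=tuple(consc),
                fne_items=tuple(fne),
                sds_items=tuple(sds),
                tfeq_items=tuple(tfeq),
                frs_current=frs_cur,
                frs_ideal=frs_ideal,
                breakfast_days_per_week=breakfast,
                school_lunch_days_per_week=lunch,
                eat_important=attitude(0.51, 0.42),
                comprehensible=attitude(0.77, 0.22),
                manageable=attitude(0.79, 0.20),
                meaningful=attitude(0.62, 0.32),
            )
        )
    return out


# ---------------------------------------------------------------------------
# the study


def generate_study(config: SimConfig | None = None, lms_table: LMSTable | None = None) -> SyntheticStudy:
    """Generate a full study; deterministic for a fixed config (incl. seed)."""
    config = config or SimConfig()
    lms = lms_table or load_lms_table()
    rng = np.random.default_rng(config.seed)
    db = generate_food_db(config, rng)

    n = config.n_participants
    n_days = rng.choice(
        np.arange(1, len(config.record_day_probs) + 1), size=n, p=config.record_day_probs
    )
    dates = [_draw_record_dates(config, rng, int(k)) for k in n_days]
    participants, ages, zs = _draw_participants(
        config, rng, lms, [ds[0] for ds in dates]
    )
    has_weekend = np.array([any(d.weekday() >= 5 for d in ds) for ds in dates])
    p_has = float(has_weekend.mean())

    r0 = config.underreport_ratio
    log_shift = (config.bmi_z_bias_slope / r0) * (zs - config.bmi_z_mean)
    ratios = r0 * np.exp(log_shift + rng.normal(0.0, config.reporting_ratio_sigma, n))

    diet_days: list[DietDay] = []
    swa_records: list[SWADayRecord] = []
    truth_rows = []
    for i, part in enumerate(participants):
        ref_date = dates[i][0]
        bmr = schofield_bmr(part.gender, part.age_years(ref_date), part.weight_kg)
        pal_i = float(np.clip(rng.normal(config.true_pal_mean, config.true_pal_sd), 1.15, 2.4))
        day_list = dates[i]
        n_weekend = sum(d.weekday() >= 5 for d in day_list)
        # centred record-level weekend shift, placed on weekend days
        if n_weekend:
            per_weekend_day = config.weekend_bias * (1 - p_has) * len(day_list) / n_weekend
            per_weekday = 0.0
        else:
            per_weekend_day = 0.0
            per_weekday = -config.weekend_bias * p_has
        tee_true_days = []
        reported_levels = []
        for d in day_list:
            pal_day = pal_i * float(_lognormal_mean_one(rng, config.pal_day_cv))
            tee_true = bmr * pal_day
            tee_true_days.append(tee_true)
            # armband
            measured = tee_true * float(_lognormal_mean_one(rng, config.swa_noise_cv))
            swa_records.append(_make_trace(part.participant_id, d, measured, bmr, config, rng))
            # reported intake
            ei = tee_true * ratios[i] * float(_lognormal_mean_one(rng, config.ei_day_cv))
            ei += per_weekend_day if d.weekday() >= 5 else per_weekday
            ei = max(ei, 350.0)
            meals = _compose_meals(ei, d, db, rng)
            questions = None
            if rng.random() < config.daily_question_prob:
                target_pal = pal_day * config.pal_overstatement * float(
                    _lognormal_mean_one(rng, config.pal_report_cv)
                )
                table = PAL_TABLE[part.gender]
                level = min(table, key=lambda lv: abs(table[lv] - target_pal))
                reported_levels.append(level)
                questions = DailyQuestions(
                    supplements=(),
                    fraction_recorded=str(
                        rng.choice(["95_to_100", "75_to_95", "50_to_75"],
                                   p=[0.76, 0.18, 0.06])
                    ),
                    tried_change_weight=bool(rng.random() < 0.3),
                    activity_level=level,
                    diet_higher_lower_than_usual=int(rng.integers(-1, 2)),
                    activity_higher_lower_than_usual=int(rng.integers(-1, 2)),
                    felt_stressed=bool(rng.random() < 0.43),
                    felt_anxious=bool(rng.random() < 0.42),
                )
            diet_days.append(
                DietDay(participant_id=part.participant_id, date=d, meals=meals,
                        questions=questions)
            )
        truth_rows.append(
            {
                "participant_id": part.participant_id,
                "age_years": float(ages[i]),
                "bmi_z": float(zs[i]),
                "bmr_kj": bmr,
                "true_pal": pal_i,
                "true_tee_mean_kj": float(np.mean(tee_true_days)),
                "reporting_ratio": float(ratios[i]),
                "n_record_days": int(n_days[i]),
                "has_weekend_day": bool(has_weekend[i]),
                "reported_levels": "|".join(reported_levels),
            }
        )

    responses = generate_questionnaires(participants, config, rng)
    return SyntheticStudy(
        config=config,
        food_db=db,
        participants=participants,
        diet_days=diet_days,
        swa_records=swa_records,
        questionnaire_responses=responses,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# pipeline adapters


def computed_ei_days(study: SyntheticStudy) -> list[EIDay]:
    """Per-day EI recomputed from the meal records through the food DB
    (the same path real records take), not read from the truth table."""
    from .diet_record import compute_day_intake

    out = []
    for day in study.diet_days:
        summary = compute_day_intake(day, study.food_db)
        out.append(EIDay(day.participant_id, day.date, summary.energy_kj))
    return out


def app_tee_days(study: SyntheticStudy) -> dict[str, list[tuple[dt.date, float]]]:
    """Per-day questionnaire-based TEE from the evening activity answers."""
    by_pid: dict[str, list[tuple[dt.date, float]]] = {}
    first_date = {
        p.participant_id: min(d.date for d in study.diet_days
                              if d.participant_id == p.participant_id)
        for p in study.participants
    }
    part_by_id = {p.participant_id: p for p in study.participants}
    for day in study.diet_days:
        if day.questions is None or day.questions.activity_level is None:
            continue
        part = part_by_id[day.participant_id]
        bmr = schofield_bmr(
            part.gender, part.age_years(first_date[day.participant_id]), part.weight_kg
        )
        tee = bmr * pal_value(part.gender, day.questions.activity_level)
        by_pid.setdefault(day.participant_id, []).append((day.date, tee))
    return by_pid


def evaluation_frame(study: SyntheticStudy, lms_table: LMSTable | None = None) -> pd.DataFrame:
    """End-to-end pipeline on a synthetic study.

    Recomputes EI from meals, filters days, evaluates participants, and
    merges imputed questionnaire scores — the frame the agreement and
    regression analyses run on.
    """
    from .evaluation import evaluate_study
    from .questionnaire import impute_missing, score_response

    lms = lms_table or load_lms_table()
    frame = evaluate_study(
        study.participants,
        computed_ei_days(study),
        study.swa_records,
        lms_table=lms,
        app_tee_days=app_tee_days(study),
    )
    completed, _ = impute_missing(study.questionnaire_responses)
    scores = pd.DataFrame([vars(score_response(r)) for r in completed])
    return frame.merge(scores, on="participant_id", how="left")


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the study as the package's CSV dialects plus truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "food_db": outdir / "foods.csv",
        "participants": outdir / "participants.csv",
        "diet_records": outdir / "diet_records.csv",
        "daily_questions": outdir / "daily_questions.csv",
        "swa_minutes": outdir / "swa_minutes.csv",
        "questionnaire": outdir / "questionnaire.csv",
        "truth": outdir / "truth.csv",
    }
    save_food_db(study.food_db, paths["food_db"])
    from .physiology import save_participants

    save_participants(study.participants, paths["participants"])
    save_diet_days(study.diet_days, paths["diet_records"])
    q_rows = []
    for day in study.diet_days:
        if day.questions is None:
            continue
        q = day.questions
        q_rows.append(
            {
                "participant_id": day.participant_id,
                "date": day.date.isoformat(),
                "supplements": ";".join(q.supplements),
                "fraction_recorded": q.fraction_recorded,
                "tried_change_weight": q.tried_change_weight,
                "activity_level": q.activity_level,
                "diet_higher_lower_than_usual": q.diet_higher_lower_than_usual,
                "activity_higher_lower_than_usual": q.activity_higher_lower_than_usual,
                "felt_stressed": q.felt_stressed,
                "felt_anxious": q.felt_anxious,
            }
        )
    pd.DataFrame(q_rows).to_csv(paths["daily_questions"], index=False, encoding="utf-8")
    save_swa_records(study.swa_records, paths["swa_minutes"])
    save_responses(study.questionnaire_responses, paths["questionnaire"])
    study.truth.to_csv(paths["truth"], index=False, encoding="utf-8")
    return paths
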