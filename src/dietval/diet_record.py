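"""Meal/day food records and their energy and nutrient aggregation.

The unit of analysis downstream is one participant-day (:class:`DietDay`):
a list of meals (breakfast/lunch/dinner/snack), each a list of
(food, unit, amount) entries, optionally accompanied by the evening
questions (:class:`DailyQuestions`).  :func:`compute_day_intake` turns a
day into an :class:`IntakeSummary` — daily energy (kJ), the daily nutrient
vector, per-meal energy and grams per food group.

Supplement use is recorded in the daily questions but never contributes to
energy or nutrient totals.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from .errors import SchemaError
from .food_db import FoodDatabase, to_grams

__all__ = [
    "MealItem",
    "MealRecord",
    "DailyQuestions",
    "DietDay",
    "IntakeSummary",
    "MEAL_TYPES",
    "ACTIVITY_LEVELS",
    "compute_meal_summary",
    "compute_day_intake",
    "feedback_report",
    "edit_day",
    "load_diet_days",
    "save_diet_days",
]

MEAL_TYPES = ("breakfast", "lunch", "dinner", "snack")

#: The five self-reported activity levels, in increasing order of exertion.
ACTIVITY_LEVELS = ("very_light", "light", "moderate", "heavy", "very_heavy")

#: Ordinal answer categories for "how much of your intake did you record?".
FRACTION_RECORDED_LEVELS = (
    "less_than_25",
    "25_to_50",
    "50_to_75",
    "75_to_95",
    "95_to_100",
)


@dataclass(frozen=True)
class MealItem:
    food_id: str
    unit_name: str
    amount: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be >= 0")


@dataclass(frozen=True)
class MealRecord:
    date: dt.date
    time: dt.time
    meal_type: Literal["breakfast", "lunch", "dinner", "snack"]
    items: tuple[MealItem, ...] = ()
    photo_ref: str | None = None  # inert metadata

    def __post_init__(self) -> None:
        if self.meal_type not in MEAL_TYPES:
            raise ValueError(f"meal_type must be one of {MEAL_TYPES}")


@dataclass(frozen=True)
class DailyQuestions:
    """Answers to the evening questions for one recorded day."""

    supplements: tuple[str, ...] = ()
    fraction_recorded: str | None = None
    tried_change_weight: bool | None = None
    activity_level: str | None = None
    diet_higher_lower_than_usual: int | None = None  # -1 lower, 0 usual, +1 higher
    activity_higher_lower_than_usual: int | None = None
    felt_stressed: bool | None = None
    felt_anxious: bool | None = None

    def __post_init__(self) -> None:
        if self.activity_level is not None and self.activity_level not in ACTIVITY_LEVELS:
            raise ValueError(f"activity_level must be one of {ACTIVITY_LEVELS}")
        if (
            self.fraction_recorded is not None
            and self.fraction_recorded not in FRACTION_RECORDED_LEVELS
        ):
            raise ValueError(
                f"fraction_recorded must be one of {FRACTION_RECORDED_LEVELS}"
            )


@dataclass(frozen=True)
class DietDay:
    participant_id: str
    date: dt.date
    meals: tuple[MealRecord, ...] = ()
    questions: DailyQuestions | None = None

    def __post_init__(self) -> None:
        for m in self.meals:
            if m.date != self.date:
                raise ValueError(
                    f"meal dated {m.date} does not belong to day {self.date}"
                )


@dataclass(frozen=True)
class IntakeSummary:
    """Daily totals for one participant-day."""

    energy_kj: float
    nutrients: Mapping[str, float]
    per_meal_energy_kj: Mapping[tuple[int, str], float]
    food_group_grams: Mapping[str, float]


def compute_meal_summary(
    meal: MealRecord, db: FoodDatabase
) -> tuple[float, dict[str, float]]:
    """Energy (kJ) and nutrient vector of one meal.

    Each item contributes grams/100 x its per-100 g composition; the result
    is additive over items and zero for an empty meal.
    """
    energy = 0.0
    nutrients: dict[str, float] = {}
    for item in meal.items:
        food = db.get(item.food_id)
        grams = to_grams(food, item.unit_name, item.amount)
        scale = grams / 100.0
        energy += scale * food.energy_kj_per_100g
        for k, v in food.nutrients_per_100g.items():
            nutrients[k] = nutrients.get(k, 0.0) + scale * v
    return energy, nutrients


def compute_day_intake(day: DietDay, db: FoodDatabase) -> IntakeSummary:
    """Aggregate a day's meals into an :class:`IntakeSummary`.

    Per-meal energies are keyed by (meal position, meal type) so repeated
    meal types stay distinguishable; food-group grams aggregate the
    gram-converted amounts by each item's food group.
    """
    energy = 0.0
    nutrients: dict[str, float] = {}
    per_meal: dict[tuple[int, str], float] = {}
    group_grams: dict[str, float] = {}
    for pos, meal in enumerate(day.meals):
        e, nut = compute_meal_summary(meal, db)
        per_meal[(pos, meal.meal_type)] = e
        energy += e
        for k, v in nut.items():
            nutrients[k] = nutrients.get(k, 0.0) + v
        for item in meal.items:
            food = db.get(item.food_id)
            grams = to_grams(food, item.unit_name, item.amount)
            group_grams[food.food_group] = group_grams.get(food.food_group, 0.0) + grams
    return IntakeSummary(
        energy_kj=energy,
        nutrients=nutrients,
        per_meal_energy_kj=per_meal,
        food_group_grams=group_grams,
    )


def feedback_report(
    summary: IntakeSummary, recommendations: Mapping[str, float]
) -> dict:
    """Intake relative to recommended daily amounts.

    Returns ``{"ratios": {nutrient: intake/recommended},
    "meal_energy_pct": {(pos, type): kJ / recommended daily kJ * 100}}``.
    The special recommendation key ``energy_kj`` drives the per-meal
    percentages.  Every recommendation consulted must be positive.
    """
    for k, v in recommendations.items():
        if v <= 0:
            raise ValueError(f"recommendation for {k!r} must be > 0, got {v!r}")
    ratios = {
        k: summary.nutrients.get(k, 0.0) / v
        for k, v in recommendations.items()
        if k != "energy_kj"
    }
    meal_pct = {}
    if "energy_kj" in recommendations:
        rec_e = recommendations["energy_kj"]
        meal_pct = {
            key: 100.0 * e / rec_e for key, e in summary.per_meal_energy_kj.items()
        }
    return {"ratios": ratios, "meal_energy_pct": meal_pct}


def edit_day(
    day: DietDay,
    action: Literal["add", "delete", "update"],
    meal_index: int,
    item: MealItem | None = None,
    item_index: int | None = None,
) -> DietDay:
    """Return a new day with one item added, deleted or updated.

    ``add`` appends ``item`` to the meal; ``delete`` removes the item at
    ``item_index``; ``update`` replaces it with ``item``.  Add followed by
    delete of the same item is the identity.
    """
    if not 0 <= meal_index < len(day.meals):
        raise IndexError(f"no meal at index {meal_index}")
    meal = day.meals[meal_index]
    items = list(meal.items)
    if action == "add":
        if item is None:
            raise ValueError("add requires an item")
        items.append(item)
    elif action in ("delete", "update"):
        if item_index is None or not 0 <= item_index < len(items):
            raise IndexError(f"no item at index {item_index} in meal {meal_index}")
        if action == "delete":
            del items[item_index]
        else:
            if item is None:
                raise ValueError("update requires an item")
            items[item_index] = item
    else:
        raise ValueError(f"unknown edit action {action!r}")
    meals = list(day.meals)
    meals[meal_index] = replace(meal, items=tuple(items))
    return replace(day, meals=tuple(meals))


# ---------------------------------------------------------------------------
# CSV IO (long format)

_RECORD_COLUMNS = (
    "participant_id",
    "date",
    "time",
    "meal_type",
    "food_id",
    "unit_name",
    "amount",
)


def save_diet_days(days: Sequence[DietDay], path: str | Path) -> None:
    """Write diet days as the long-format record CSV."""
    rows = []
    for day in days:
        for meal in day.meals:
            for it in meal.items:
                rows.append(
                    {
                        "participant_id": day.participant_id,
                        "date": day.date.isoformat(),
                        "time": meal.time.strftime("%H:%M"),
                        "meal_type": meal.meal_type,
                        "food_id": it.food_id,
                        "unit_name": it.unit_name,
                        "amount": it.amount,
                    }
                )
    pd.DataFrame(rows, columns=list(_RECORD_COLUMNS)).to_csv(
        path, index=False, encoding="utf-8"
    )


def load_diet_days(path: str | Path) -> list[DietDay]:
    """Read the long-format record CSV back into :class:`DietDay` objects.

    Rows sharing participant, date, time and meal type form one meal.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "food_id": str})
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"diet-record CSV missing column(s): {', '.join(missing)}")
    days: list[DietDay] = []
    for (pid, date_s), day_df in df.groupby(["participant_id", "date"], sort=True):
        date = dt.date.fromisoformat(str(date_s))
        meals = []
        for (time_s, mtype), meal_df in day_df.groupby(["time", "meal_type"], sort=True):
            items = tuple(
                MealItem(str(r.food_id), str(r.unit_name), float(r.amount))
                for r in meal_df.itertuples()
            )
            meals.append(
                MealRecord(
                    date=date,
                    time=dt.time.fromisoformat(str(time_s)),
                    meal_type=str(mtype),
                    items=items,
                )
            )
        days.append(DietDay(participant_id=str(pid), date=date, meals=tuple(meals)))
    return days
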