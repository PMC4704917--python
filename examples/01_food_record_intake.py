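"""Record a day of meals and compute its energy and nutrient intake.

Builds a three-item food database, records breakfast and lunch for one
participant-day, and prints the daily totals plus feedback relative to
recommended intakes.
"""

import datetime as dt

from dietval import (
    DietDay,
    FoodDatabase,
    FoodItem,
    MealItem,
    MealRecord,
    PortionUnit,
    compute_day_intake,
    feedback_report,
    search_foods,
)

db = FoodDatabase.from_items(
    [
        FoodItem("oat", "Oatmeal porridge", "Bread and cereals", 460.0,
                 {"protein_g": 1.7, "fibre_g": 1.5, "iron_mg": 0.6},
                 units=(PortionUnit("deciliter", 101.0),)),
        FoodItem("milk", "Milk 1.5%", "Dairy", 195.0,
                 {"protein_g": 3.5, "calcium_mg": 120.0},
                 units=(PortionUnit("deciliter", 103.0),)),
        FoodItem("bread", "Rye bread", "Bread and cereals", 1010.0,
                 {"protein_g": 8.0, "fibre_g": 7.2, "iron_mg": 2.4},
                 units=(PortionUnit("piece", 40.0),)),
    ]
)

print("free-text search for 'bread':",
      [f.name for f in search_foods("bread", db)])

date = dt.date(2013, 5, 15)
day = DietDay(
    participant_id="P001",
    date=date,
    meals=(
        MealRecord(date, dt.time(7, 30), "breakfast",
                   items=(MealItem("oat", "deciliter", 3.0),
                          MealItem("milk", "deciliter", 2.0))),
        MealRecord(date, dt.time(12, 0), "lunch",
                   items=(MealItem("bread", "piece", 2.0),
                          MealItem("milk", "deciliter", 2.5))),
    ),
)

summary = compute_day_intake(day, db)
print(f"daily energy: {summary.energy_kj:.0f} kJ")
for meal, kj in summary.per_meal_energy_kj.items():
    print(f"  {meal[1]:<10} {kj:7.0f} kJ")
print("food-group grams:", {k: round(v) for k, v in summary.food_group_grams.items()})

report = feedback_report(summary, {"energy_kj": 9700.0, "calcium_mg": 900.0,
                                   "iron_mg": 11.0, "fibre_g": 28.0})
print("intake vs recommendation (1.0 = meets it):",
      {k: round(v, 2) for k, v in report["ratios"].items()})
# The ratios show how far this (incomplete) day is from the recommended
# daily amounts; per-meal percentages relate each meal to the daily
# recommended energy.
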