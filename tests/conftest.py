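import datetime as dt

import pytest

from dietval.food_db import FoodDatabase, FoodItem, PortionUnit
from dietval.physiology import load_lms_table
from dietval.synthetic_data import SimConfig, generate_study


@pytest.fixture(scope="session")
def lms():
    return load_lms_table()


@pytest.fixture()
def small_db():
    """Hand-built database with easy round numbers."""
    items = [
        FoodItem(
            food_id="milk",
            name="Milk",
            food_group="Dairy",
            energy_kj_per_100g=200.0,
            nutrients_per_100g={"protein_g": 3.5, "calcium_mg": 120.0},
            units=(PortionUnit("gram", 1.0), PortionUnit("deciliter", 100.0)),
        ),
        FoodItem(
            food_id="shake",
            name="Milkshake",
            food_group="Dairy",
            energy_kj_per_100g=350.0,
            nutrients_per_100g={"protein_g": 3.0, "calcium_mg": 110.0},
            units=(PortionUnit("gram", 1.0), PortionUnit("deciliter", 104.0)),
        ),
        FoodItem(
            food_id="oatmilk",
            name="Oat milk",
            food_group="Beverages",
            energy_kj_per_100g=180.0,
            nutrients_per_100g={"protein_g": 1.0, "calcium_mg": 100.0},
            units=(PortionUnit("gram", 1.0),),
        ),
        FoodItem(
            food_id="bread",
            name="Rye bread",
            food_group="Bread and cereals",
            energy_kj_per_100g=1000.0,
            nutrients_per_100g={"protein_g": 8.0, "fibre_g": 7.0},
            units=(PortionUnit("gram", 1.0), PortionUnit("piece", 40.0)),
        ),
        FoodItem(
            food_id="butter",
            name="Butter",
            food_group="Fats and oils",
            energy_kj_per_100g=3000.0,
            nutrients_per_100g={"fat_g": 81.0},
            units=(PortionUnit("gram", 1.0), PortionUnit("tablespoon", 15.0)),
        ),
    ]
    return FoodDatabase.from_items(items, version="test-1")


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused across module tests."""
    return generate_study(SimConfig(seed=11, n_participants=20))


@pytest.fixture()
def a_date():
    return dt.date(2013, 5, 15)
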