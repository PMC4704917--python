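"""Food-composition database: model, serialization, search, portion conversion.

A :class:`FoodDatabase` is a keyed collection of :class:`FoodItem` records,
each carrying energy (kJ per 100 g), a named nutrient vector per 100 g and a
list of portion units with gram weights (a ``gram`` unit with weight 1 is
always present).  The on-disk dialects are

* CSV — columns ``food_id, name, food_group, energy_kj_per_100g``, one
  column per nutrient, and one column ``unit:<name>`` per portion unit
  holding the gram weight (empty when the unit is not offered for a food);
* JSON — a ``{"version": ..., "items": [...]}`` document with nested
  records mirroring :class:`FoodItem`; load/save round-trips bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DuplicateKeyError, SchemaError, UnknownFoodError, UnknownUnitError

__all__ = [
    "PortionUnit",
    "FoodItem",
    "FoodDatabase",
    "load_food_db",
    "load_packaged_food_db",
    "save_food_db",
    "search_foods",
    "to_grams",
]

#: Columns every food-db CSV must provide, in this order.
REQUIRED_COLUMNS = ("food_id", "name", "food_group", "energy_kj_per_100g")

_UNIT_PREFIX = "unit:"


@dataclass(frozen=True)
class PortionUnit:
    """A household portion unit for one food: ``gram_weight`` g per 1 unit."""

    name: str
    gram_weight: float

    def __post_init__(self) -> None:
        if self.gram_weight <= 0:
            raise ValueError(f"gram_weight must be positive, got {self.gram_weight!r}")


@dataclass(frozen=True)
class FoodItem:
    """One food or pre-resolved dish with per-100 g composition."""

    food_id: str
    name: str
    food_group: str
    energy_kj_per_100g: float
    nutrients_per_100g: Mapping[str, float] = field(default_factory=dict)
    units: tuple[PortionUnit, ...] = ()

    def __post_init__(self) -> None:
        if self.energy_kj_per_100g < 0:
            raise ValueError("energy_kj_per_100g must be >= 0")
        for k, v in self.nutrients_per_100g.items():
            if v < 0:
                raise ValueError(f"nutrient {k!r} must be >= 0, got {v!r}")
        names = [u.name for u in self.units]
        if "gram" not in names:
            object.__setattr__(
                self, "units", tuple(self.units) + (PortionUnit("gram", 1.0),)
            )

    def unit(self, unit_name: str) -> PortionUnit:
        for u in self.units:
            if u.name == unit_name:
                return u
        available = ", ".join(sorted(u.name for u in self.units))
        raise UnknownUnitError(
            f"food {self.food_id!r} has no unit {unit_name!r}; available: {available}"
        )


@dataclass
class FoodDatabase:
    """Collection of :class:`FoodItem` indexed by ``food_id``."""

    items: dict[str, FoodItem]
    version: str = ""

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, food_id: str) -> bool:
        return food_id in self.items

    def get(self, food_id: str) -> FoodItem:
        try:
            return self.items[food_id]
        except KeyError:
            raise UnknownFoodError(f"unknown food_id {food_id!r}") from None

    @classmethod
    def from_items(cls, items: Iterable[FoodItem], version: str = "") -> "FoodDatabase":
        out: dict[str, FoodItem] = {}
        for it in items:
            if it.food_id in out:
                raise DuplicateKeyError(f"duplicate food_id {it.food_id!r}")
            out[it.food_id] = it
        return cls(items=out, version=version)

    #: Names of all nutrient columns occurring in any item, sorted.
    @property
    def nutrient_names(self) -> list[str]:
        names: set[str] = set()
        for it in self.items.values():
            names.update(it.nutrients_per_100g)
        return sorted(names)


def to_grams(food: FoodItem, unit_name: str, amount: float) -> float:
    """Convert ``amount`` of ``unit_name`` of ``food`` to grams.

    Linear in ``amount``; the ``gram`` unit is the identity.
    """
    if amount < 0:
        raise ValueError("amount must be >= 0")
    return amount * food.unit(unit_name).gram_weight


def search_foods(query: str, db: FoodDatabase, limit: int = 10) -> list[FoodItem]:
    """Case-insensitive substring search over item names.

    Results are ordered by the position of the match within the name
    (earlier first), then by name; at most ``limit`` items are returned.
    """
    q = query.strip().lower()
    if not q:
        raise ValueError("query must be non-empty")
    hits: list[tuple[int, str, FoodItem]] = []
    for it in db.items.values():
        pos = it.name.lower().find(q)
        if pos >= 0:
            hits.append((pos, it.name, it))
    hits.sort(key=lambda t: (t[0], t[1]))
    return [it for _, _, it in hits[: max(limit, 0)]]


# ---------------------------------------------------------------------------
# serialization


def _item_to_record(it: FoodItem) -> dict:
    return {
        "food_id": it.food_id,
        "name": it.name,
        "food_group": it.food_group,
        "energy_kj_per_100g": it.energy_kj_per_100g,
        "nutrients_per_100g": dict(it.nutrients_per_100g),
        "units": [{"name": u.name, "gram_weight": u.gram_weight} for u in it.units],
    }


def _item_from_record(rec: dict) -> FoodItem:
    for key in ("food_id", "name", "food_group", "energy_kj_per_100g"):
        if key not in rec:
            raise SchemaError(f"food record missing required field {key!r}")
    return FoodItem(
        food_id=str(rec["food_id"]),
        name=str(rec["name"]),
        food_group=str(rec["food_group"]),
        energy_kj_per_100g=float(rec["energy_kj_per_100g"]),
        nutrients_per_100g={k: float(v) for k, v in rec.get("nutrients_per_100g", {}).items()},
        units=tuple(
            PortionUnit(u["name"], float(u["gram_weight"])) for u in rec.get("units", [])
        ),
    )


def load_packaged_food_db() -> FoodDatabase:
    """The synthetic >=50-item food-composition fixture shipped with the
    package (49 nutrient columns, 12 food groups, household units)."""
    from importlib import resources

    ref = resources.files("dietval.data") / "foods_synthetic.csv"
    with resources.as_file(ref) as p:
        return load_food_db(p, format="csv")


def load_food_db(path: str | Path, format: str | None = None) -> FoodDatabase:
    """Load a food database from CSV or JSON.

    ``format`` defaults to the file suffix.  Raises :class:`SchemaError`
    when a required column/field is missing and :class:`DuplicateKeyError`
    on repeated food ids.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        if "items" not in doc:
            raise SchemaError("food-db JSON must contain an 'items' list")
        return FoodDatabase.from_items(
            (_item_from_record(r) for r in doc["items"]), version=doc.get("version", "")
        )
    if fmt == "csv":
        df = pd.read_csv(path, encoding="utf-8")
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"food-db CSV missing required column(s): {', '.join(missing)}")
        unit_cols = [c for c in df.columns if c.startswith(_UNIT_PREFIX)]
        nutrient_cols = [
            c for c in df.columns if c not in REQUIRED_COLUMNS and c not in unit_cols
        ]
        items = []
        for rec in df.to_dict("records"):
            units = []
            for c in unit_cols:
                v = rec[c]
                if pd.notna(v):
                    units.append(PortionUnit(c[len(_UNIT_PREFIX):], float(v)))
            items.append(
                FoodItem(
                    food_id=str(rec["food_id"]),
                    name=str(rec["name"]),
                    food_group=str(rec["food_group"]),
                    energy_kj_per_100g=float(rec["energy_kj_per_100g"]),
                    nutrients_per_100g={
                        c: float(rec[c]) for c in nutrient_cols if pd.notna(rec[c])
                    },
                    units=tuple(units),
                )
            )
        return FoodDatabase.from_items(items)
    raise ValueError(f"unsupported food-db format {fmt!r}")


def save_food_db(db: FoodDatabase, path: str | Path, format: str | None = None) -> None:
    """Write a database to CSV or JSON (JSON round-trips bit-identically)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        doc = {
            "version": db.version,
            "items": [_item_to_record(it) for it in db.items.values()],
        }
        path.write_text(json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8")
        return
    if fmt == "csv":
        nutrients = db.nutrient_names
        unit_names = sorted(
            {u.name for it in db.items.values() for u in it.units} - {"gram"}
        )
        rows = []
        for it in db.items.values():
            row: dict = {
                "food_id": it.food_id,
                "name": it.name,
                "food_group": it.food_group,
                "energy_kj_per_100g": it.energy_kj_per_100g,
            }
            for n in nutrients:
                row[n] = it.nutrients_per_100g.get(n, "")
            weights = {u.name: u.gram_weight for u in it.units}
            row[_UNIT_PREFIX + "gram"] = 1.0
            for n in unit_names:
                row[_UNIT_PREFIX + n] = weights.get(n, "")
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")
        return
    raise ValueError(f"unsupported food-db format {fmt!r}")
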