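"""Anthropometrics and energy physiology.

Covers, for one participant:

* BMI, BMI z-score via the LMS transform, and weight status
  (thinness grades 1-2 / normal / overweight / obese) against age- and
  sex-specific cutoff curves;
* basal metabolic rate from Schofield's sex- and age-band specific linear
  weight equations (kJ/day);
* the five-level, sex-specific physical-activity-level (PAL) multipliers
  and the questionnaire-based total energy expenditure
  ``TEE_app = BMR x PAL``;
* reference total energy expenditure from a minute-level armband trace,
  with off-body minutes imputed at the basal rate
  (:func:`tee_swa`), and wear-time accounting.

The LMS/cutoff reference shipped with the package
(``data/lms_reference_synthetic.csv``) is a synthetic stand-in with the
structure of the international (IOTF-style) child references: L/M/S by sex
at half-year ages with cutoff curves back-projected from adult BMI anchors
16 / 17 / 25 / 30 through the same LMS curves.  Any conforming table can be
supplied instead.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .diet_record import ACTIVITY_LEVELS
from .errors import AgeRangeError, SchemaError

__all__ = [
    "Participant",
    "AnthroResult",
    "SWADayRecord",
    "EnergyEstimates",
    "LMSTable",
    "load_lms_table",
    "age_years",
    "bmi",
    "bmi_zscore",
    "weight_status",
    "anthro_result",
    "save_participants",
    "load_participants",
    "schofield_bmr",
    "pal_value",
    "tee_app",
    "wear_hours",
    "tee_swa",
    "load_swa_records",
    "save_swa_records",
    "SCHOFIELD_KJ",
    "PAL_TABLE",
    "WEIGHT_STATUS_CATEGORIES",
]

MINUTES_PER_DAY = 1440

WEIGHT_STATUS_CATEGORIES = (
    "thinness_grade_2",
    "thinness_grade_1",
    "normal",
    "overweight",
    "obese",
)

# ---------------------------------------------------------------------------
# Schofield BMR (weight-only equations, kJ/day)
#
# BMR = a * weight_kg + b for the participant's sex and age band.  These are
# the classical weight-only coefficients expressed in kJ/day (the source
# tables are in MJ/day; 1 MJ = 1000 kJ).  Age bands are half-open
# [lower, upper): a participant aged exactly 18.0 falls in the 18-30 band.
SCHOFIELD_KJ: dict[str, tuple[tuple[float, float, float, float], ...]] = {
    # (age_lower, age_upper, a, b)
    "male": (
        (0.0, 3.0, 249.0, -127.0),
        (3.0, 10.0, 95.0, 2110.0),
        (10.0, 18.0, 74.0, 2754.0),
        (18.0, 30.0, 63.0, 2896.0),
        (30.0, 60.0, 48.0, 3653.0),
        (60.0, 150.0, 49.0, 2459.0),
    ),
    "female": (
        (0.0, 3.0, 244.0, -130.0),
        (3.0, 10.0, 85.0, 2033.0),
        (10.0, 18.0, 56.0, 2898.0),
        (18.0, 30.0, 62.0, 2036.0),
        (30.0, 60.0, 34.0, 3538.0),
        (60.0, 150.0, 38.0, 2755.0),
    ),
}

# Five-level PAL multipliers (girl value, boy value); boys sit exactly
# 0.1 above girls at every level.
PAL_TABLE: dict[str, dict[str, float]] = {
    "female": {
        "very_light": 1.3,
        "light": 1.5,
        "moderate": 1.7,
        "heavy": 1.9,
        "very_heavy": 2.1,
    },
    "male": {
        "very_light": 1.4,
        "light": 1.6,
        "moderate": 1.8,
        "heavy": 2.0,
        "very_heavy": 2.2,
    },
}

#: Plain-language descriptions of the five activity levels.
ACTIVITY_LEVEL_DESCRIPTIONS: dict[str, str] = {
    "very_light": "sedentary most of the day",
    "light": "sedentary, standing, or walking short distances",
    "moderate": (
        "standing or walking most of the day, or sedentary but with 30-60 "
        "minutes of walking or bicycling at moderate speed"
    ),
    "heavy": (
        "sedentary, standing, and walking short distances, and 60 minutes "
        "of strenuous physical activity/sport"
    ),
    "very_heavy": (
        "standing and walking most of the day, and 60 minutes of strenuous "
        "physical activity/sport"
    ),
}


@dataclass(frozen=True)
class Participant:
    """Profile data entered at registration plus measured anthropometrics."""

    participant_id: str
    gender: Literal["female", "male"]
    birth_date: dt.date
    weight_kg: float
    height_cm: float
    parental_education: str | None = None  # low / medium / high
    born_outside_sweden: str | None = None
    special_diet: str | None = None
    school: str | None = None

    def __post_init__(self) -> None:
        if self.gender not in ("female", "male"):
            raise ValueError("gender must be 'female' or 'male'")
        if self.weight_kg <= 0 or self.height_cm <= 0:
            raise ValueError("weight_kg and height_cm must be positive")

    def age_years(self, reference_date: dt.date) -> float:
        return age_years(self.birth_date, reference_date)


@dataclass(frozen=True)
class AnthroResult:
    bmi: float
    bmi_zscore: float
    weight_status: str


@dataclass(frozen=True)
class SWADayRecord:
    """One participant-day armband trace: 1440 minute slots.

    ``ee_kj`` holds the device's energy-expenditure estimate per minute;
    ``on_body`` flags whether the device was worn that minute.
    """

    participant_id: str
    date: dt.date
    ee_kj: np.ndarray  # shape (1440,)
    on_body: np.ndarray  # shape (1440,), bool

    def __post_init__(self) -> None:
        ee = np.asarray(self.ee_kj, dtype=float)
        ob = np.asarray(self.on_body, dtype=bool)
        if ee.shape != (MINUTES_PER_DAY,) or ob.shape != (MINUTES_PER_DAY,):
            raise ValueError("ee_kj and on_body must have exactly 1440 minute slots")
        if (ee < 0).any():
            raise ValueError("minute EE must be >= 0")
        object.__setattr__(self, "ee_kj", ee)
        object.__setattr__(self, "on_body", ob)


@dataclass(frozen=True)
class EnergyEstimates:
    """Per-participant energy bookkeeping (all kJ/day)."""

    bmr_kj: float
    pal: float
    tee_app_kj: float
    tee_swa_kj: float
    wear_hours: float

    @property
    def pal_swa(self) -> float:
        return self.tee_swa_kj / self.bmr_kj


def age_years(birth_date: dt.date, reference_date: dt.date) -> float:
    """Exact decimal age in years (mean Gregorian year of 365.2425 days)."""
    return (reference_date - birth_date).days / 365.2425


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m^2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    h = height_cm / 100.0
    return weight_kg / (h * h)


# ---------------------------------------------------------------------------
# LMS reference


_LMS_COLUMNS = (
    "sex",
    "age_years",
    "L",
    "M",
    "S",
    "cutoff_thin2",
    "cutoff_thin1",
    "cutoff_overweight",
    "cutoff_obese",
)


class LMSTable:
    """Sex-specific LMS curves plus weight-status cutoff curves.

    Rows give L, M, S and the four BMI cutoffs at tabulated ages; lookups
    interpolate linearly in age within the covered range and raise
    :class:`AgeRangeError` outside it.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _LMS_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"LMS table missing column(s): {', '.join(missing)}")
        self._by_sex = {
            sex: g.sort_values("age_years").reset_index(drop=True)
            for sex, g in df.groupby("sex")
        }

    def _interp(self, sex: str, age: float) -> pd.Series:
        if sex not in self._by_sex:
            raise SchemaError(f"LMS table has no rows for sex {sex!r}")
        g = self._by_sex[sex]
        ages = g["age_years"].to_numpy()
        if age < ages[0] or age > ages[-1]:
            raise AgeRangeError(
                f"age {age:.2f} outside LMS table coverage [{ages[0]}, {ages[-1]}]"
            )
        out = {}
        for col in _LMS_COLUMNS[2:]:
            out[col] = float(np.interp(age, ages, g[col].to_numpy()))
        return pd.Series(out)

    def lms(self, sex: str, age: float) -> tuple[float, float, float]:
        row = self._interp(sex, age)
        return row["L"], row["M"], row["S"]

    def cutoffs(self, sex: str, age: float) -> dict[str, float]:
        row = self._interp(sex, age)
        return {
            "thin2": row["cutoff_thin2"],
            "thin1": row["cutoff_thin1"],
            "overweight": row["cutoff_overweight"],
            "obese": row["cutoff_obese"],
        }

    def bmi_from_z(self, sex: str, age: float, z: float) -> float:
        """Invert the LMS transform (used by the cohort simulator)."""
        L, M, S = self.lms(sex, age)
        if abs(L) < 1e-12:
            return M * float(np.exp(S * z))
        return M * (1.0 + L * S * z) ** (1.0 / L)


def load_lms_table(path: str | Path | None = None) -> LMSTable:
    """Load an LMS/cutoff CSV; default is the packaged synthetic reference."""
    if path is None:
        ref = resources.files("dietval.data") / "lms_reference_synthetic.csv"
        with resources.as_file(ref) as p:
            return LMSTable(pd.read_csv(p))
    return LMSTable(pd.read_csv(path))


def bmi_zscore(bmi_value: float, age: float, sex: str, lms_table: LMSTable) -> float:
    """BMI standard-deviation score via the LMS transform.

    z = ((BMI/M)^L - 1) / (L*S), with L, M, S linearly interpolated in age.
    """
    L, M, S = lms_table.lms(sex, age)
    if abs(L) < 1e-12:
        return float(np.log(bmi_value / M) / S)
    return float(((bmi_value / M) ** L - 1.0) / (L * S))


def weight_status(bmi_value: float, age: float, sex: str, lms_table: LMSTable) -> str:
    """Weight-status category from the age/sex cutoff curves.

    Boundaries are inclusive toward the more extreme category: a BMI equal
    to the overweight cutoff is overweight, equal to a thinness cutoff is
    that thinness grade.
    """
    c = lms_table.cutoffs(sex, age)
    if bmi_value <= c["thin2"]:
        return "thinness_grade_2"
    if bmi_value <= c["thin1"]:
        return "thinness_grade_1"
    if bmi_value >= c["obese"]:
        return "obese"
    if bmi_value >= c["overweight"]:
        return "overweight"
    return "normal"


def anthro_result(
    participant: Participant, reference_date: dt.date, lms_table: LMSTable
) -> AnthroResult:
    """BMI, z-score and weight status for one participant at a date."""
    b = bmi(participant.weight_kg, participant.height_cm)
    age = participant.age_years(reference_date)
    z = bmi_zscore(b, age, participant.gender, lms_table)
    return AnthroResult(bmi=b, bmi_zscore=z, weight_status=weight_status(b, age, participant.gender, lms_table))


def schofield_bmr(gender: str, age: float, weight_kg: float) -> float:
    """Basal metabolic rate (kJ/day) from the weight-only linear equations.

    Strictly increasing in weight within a band.  Raises
    :class:`AgeRangeError` for ages outside the tabulated bands.
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    if gender not in SCHOFIELD_KJ:
        raise ValueError("gender must be 'female' or 'male'")
    for lo, hi, a, b in SCHOFIELD_KJ[gender]:
        if lo <= age < hi:
            return a * weight_kg + b
    raise AgeRangeError(f"no BMR coefficients for age {age:.2f}")


def pal_value(gender: str, level: str) -> float:
    """PAL multiplier for a sex and self-reported activity level."""
    if gender not in PAL_TABLE:
        raise ValueError("gender must be 'female' or 'male'")
    if level not in ACTIVITY_LEVELS:
        raise ValueError(f"level must be one of {ACTIVITY_LEVELS}")
    return PAL_TABLE[gender][level]


def tee_app(
    participant: Participant, level: str, reference_date: dt.date
) -> float:
    """Questionnaire-based TEE (kJ/day): Schofield BMR x PAL multiplier."""
    bmr = schofield_bmr(
        participant.gender, participant.age_years(reference_date), participant.weight_kg
    )
    return bmr * pal_value(participant.gender, level)


def wear_hours(rec: SWADayRecord) -> float:
    """Hours the armband was on the body during the day."""
    return float(rec.on_body.sum()) / 60.0


def tee_swa(rec: SWADayRecord, bmr_kj: float) -> float:
    """Daily reference TEE (kJ) from an armband trace.

    On-body minutes contribute their recorded EE; each off-body minute is
    imputed at the basal rate ``bmr_kj / 1440`` (the device reports basal
    expenditure when removed).  Consequently ``tee_swa >= sum of on-body
    EE`` with equality iff the device was worn the whole day.
    """
    on = rec.on_body
    on_sum = float(rec.ee_kj[on].sum())
    n_off = int(MINUTES_PER_DAY - on.sum())
    return on_sum + n_off * bmr_kj / MINUTES_PER_DAY


# ---------------------------------------------------------------------------
# participant CSV IO

_PARTICIPANT_COLUMNS = (
    "participant_id",
    "gender",
    "birth_date",
    "weight_kg",
    "height_cm",
    "parental_education",
    "born_outside_sweden",
    "special_diet",
    "school",
)


def save_participants(participants: Sequence[Participant], path: str | Path) -> None:
    rows = []
    for p in participants:
        rows.append(
            {
                "participant_id": p.participant_id,
                "gender": p.gender,
                "birth_date": p.birth_date.isoformat(),
                "weight_kg": p.weight_kg,
                "height_cm": p.height_cm,
                "parental_education": p.parental_education,
                "born_outside_sweden": p.born_outside_sweden,
                "special_diet": p.special_diet,
                "school": p.school,
            }
        )
    pd.DataFrame(rows, columns=list(_PARTICIPANT_COLUMNS)).to_csv(
        path, index=False, encoding="utf-8"
    )


def load_participants(path: str | Path) -> list["Participant"]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = ("participant_id", "gender", "birth_date", "weight_kg", "height_cm")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"participant CSV missing column(s): {', '.join(missing)}")

    def opt(v):
        return None if pd.isna(v) else str(v)

    return [
        Participant(
            participant_id=str(r["participant_id"]),
            gender=str(r["gender"]),
            birth_date=dt.date.fromisoformat(str(r["birth_date"])),
            weight_kg=float(r["weight_kg"]),
            height_cm=float(r["height_cm"]),
            parental_education=opt(r.get("parental_education")),
            born_outside_sweden=opt(r.get("born_outside_sweden")),
            special_diet=opt(r.get("special_diet")),
            school=opt(r.get("school")),
        )
        for r in df.to_dict("records")
    ]


# ---------------------------------------------------------------------------
# armband CSV IO


def save_swa_records(records: Sequence[SWADayRecord], path: str | Path) -> None:
    """Write minute-level traces as CSV (participant_id, date, minute, ee_kj, on_body)."""
    frames = []
    for rec in records:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": rec.participant_id,
                    "date": rec.date.isoformat(),
                    "minute": np.arange(MINUTES_PER_DAY),
                    "ee_kj": np.round(rec.ee_kj, 5),
                    "on_body": rec.on_body.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, encoding="utf-8")


def load_swa_records(path: str | Path) -> list[SWADayRecord]:
    """Read the minute-level armband CSV back into day records."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = ("participant_id", "date", "minute", "ee_kj", "on_body")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"armband CSV missing column(s): {', '.join(missing)}")
    out = []
    for (pid, date_s), g in df.groupby(["participant_id", "date"], sort=True):
        g = g.sort_values("minute")
        if len(g) != MINUTES_PER_DAY:
            raise SchemaError(
                f"trace for {pid} {date_s} has {len(g)} minutes, expected 1440"
            )
        out.append(
            SWADayRecord(
                participant_id=str(pid),
                date=dt.date.fromisoformat(str(date_s)),
                ee_kj=g["ee_kj"].to_numpy(float),
                on_body=g["on_body"].to_numpy(bool),
            )
        )
    return out
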