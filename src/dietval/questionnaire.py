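"""Questionnaire scoring: 0-100 indices, eating-behaviour subscales,
body-size discrepancy, dichotomizations and the imputation rules.

The battery holds 53 items across five borrowed instruments plus a few
single questions: a 15-item conscientiousness scale, 5 fear-of-negative-
evaluation items, 7 social-desirability items, the 18-item three-factor
eating questionnaire (TFEQ-R18: cognitive restraint, uncontrolled eating,
emotional eating), a 9-figure body-silhouette rating (current and ideal),
breakfast and school-lunch frequency, and four yes/somewhat/no attitude
questions.

Every multi-item scale is expressed as a 0-100 index by the linear
min-max transform

    index = 100 * sum(item - item_min) / (n_items * (item_max - item_min))

after flipping reverse-keyed items.  Item counts, scale bounds, reverse
keys and the TFEQ-R18 subscale map are declared in a JSON instrument
config (``data/instruments.json`` by default); any conforming config may
be supplied.

Imputation rules (applied before scoring):

* missing figure-rating answer -> *no discrepancy*;
* missing breakfast frequency -> 7 days/week; missing school lunch -> 5;
* missing conscientiousness items -> the scale midpoint (the middle
  response alternative);
* other missing scale items -> the per-item median over the remaining
  respondents (the printed rule for social desirability, uncontrolled
  eating and cognitive restraint, applied uniformly to item scales);
* missing yes/somewhat/no answers -> the modal response of the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ImputationError,
    MissingDataError,
    SchemaError,
    UndefinedStatisticError,
)

__all__ = [
    "QuestionnaireResponse",
    "QuestionnaireScores",
    "load_instrument_config",
    "score_index",
    "tfeq_r18_scores",
    "frs_discrepancy",
    "impute_missing",
    "dichotomize",
    "cronbach_alpha",
    "score_response",
    "load_responses",
    "save_responses",
]

YES_SOMEWHAT_NO = ("yes", "somewhat", "no")

FRS_CATEGORIES = ("no_discrepancy", "prefer_smaller", "prefer_larger")

#: (attribute name, instrument key) pairs for the item-vector fields.
_ITEM_FIELDS = (
    ("conscientiousness_items", "conscientiousness"),
    ("fne_items", "fear_of_negative_evaluation"),
    ("sds_items", "social_desirability"),
    ("tfeq_items", "tfeq_r18"),
)

_ATTITUDE_FIELDS = ("eat_important", "comprehensible", "manageable", "meaningful")


def load_instrument_config(path: str | Path | None = None) -> dict:
    """Load an instrument config; default is the packaged fixture."""
    if path is None:
        ref = resources.files("dietval.data") / "instruments.json"
        cfg = json.loads(ref.read_text(encoding="utf-8"))
    else:
        cfg = json.loads(Path(path).read_text(encoding="utf-8"))
    required = [key for _, key in _ITEM_FIELDS] + ["figure_rating_scale"]
    missing = [k for k in required if k not in cfg]
    if missing:
        raise SchemaError(f"instrument config missing: {', '.join(missing)}")
    return cfg


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One respondent's item-level answers; ``None`` marks a missing answer."""

    participant_id: str
    conscientiousness_items: tuple[float | None, ...] = (None,) * 15
    fne_items: tuple[float | None, ...] = (None,) * 5
    sds_items: tuple[float | None, ...] = (None,) * 7
    tfeq_items: tuple[float | None, ...] = (None,) * 18
    frs_current: float | None = None
    frs_ideal: float | None = None
    breakfast_days_per_week: float | None = None
    school_lunch_days_per_week: float | None = None
    eat_important: str | None = None
    comprehensible: str | None = None
    manageable: str | None = None
    meaningful: str | None = None

    def __post_init__(self) -> None:
        for f in _ATTITUDE_FIELDS:
            v = getattr(self, f)
            if v is not None and v not in YES_SOMEWHAT_NO:
                raise ValueError(f"{f} must be one of {YES_SOMEWHAT_NO}, got {v!r}")


@dataclass(frozen=True)
class QuestionnaireScores:
    """Scored indices (each 0-100), categories and dichotomies."""

    participant_id: str
    conscientiousness: float
    fear_of_negative_evaluation: float
    social_desirability: float
    cognitive_restraint: float
    uncontrolled_eating: float
    emotional_eating: float
    frs_discrepancy: str
    breakfast_7: bool
    lunch_5: bool
    eat_important_yes: bool
    comprehensible_yes: bool
    manageable_yes: bool
    meaningful_yes: bool


def score_index(
    items: Sequence[float | None],
    item_min: float,
    item_max: float,
    reversed_ids: Sequence[int] = (),
) -> float:
    """Linear 0-100 index of an ordinal item vector.

    ``reversed_ids`` are 1-based positions flipped as
    ``item_min + item_max - value`` before summation.  Raises
    :class:`MissingDataError` on any missing item (impute first).
    """
    if item_max <= item_min:
        raise ValueError("item_max must exceed item_min")
    vals = []
    rev = set(reversed_ids)
    for i, v in enumerate(items, start=1):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise MissingDataError(
                f"item {i} is missing; run impute_missing before scoring"
            )
        vals.append(item_min + item_max - v if i in rev else v)
    n = len(vals)
    return 100.0 * sum(v - item_min for v in vals) / (n * (item_max - item_min))


def tfeq_r18_scores(
    tfeq_items: Sequence[float | None], config: Mapping
) -> dict[str, float]:
    """The three eating-behaviour subscale indices.

    Each subscale is scored by :func:`score_index` over its own items from
    the config's subscale partition, so subscales are independent.
    """
    inst = config["tfeq_r18"]
    rev = set(inst.get("reversed", ()))
    out = {}
    for name, ids in inst["subscales"].items():
        sub = [tfeq_items[i - 1] for i in ids]
        sub_rev = [k + 1 for k, i in enumerate(ids) if i in rev]
        out[name] = score_index(sub, inst["item_min"], inst["item_max"], sub_rev)
    return out


def frs_discrepancy(current: float | None, ideal: float | None) -> str:
    """Body-size preference from current vs ideal silhouette indices."""
    if current is None or ideal is None:
        raise MissingDataError("figure-rating answers missing; impute first")
    if current == ideal:
        return "no_discrepancy"
    return "prefer_smaller" if current > ideal else "prefer_larger"


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha of a respondents x items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of totals),
    with sample (n-1) variances.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 respondents and 2 items")
    k = x.shape[1]
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var == 0:
        raise UndefinedStatisticError("zero variance of totals; alpha undefined")
    return float(k / (k - 1) * (1.0 - x.var(axis=0, ddof=1).sum() / total_var))


# ---------------------------------------------------------------------------
# imputation


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def impute_missing(
    responses: Sequence[QuestionnaireResponse], config: Mapping | None = None
) -> tuple[list[QuestionnaireResponse], list[dict]]:
    """Apply the imputation rules across a respondent collection.

    Returns the completed responses plus a log with one entry per imputed
    cell (participant, field, rule, value).  A complete collection passes
    through unchanged with an empty log.
    """
    config = config or load_instrument_config()
    log: list[dict] = []
    out: list[QuestionnaireResponse] = []

    def medians_for(attr: str, n_items: int) -> list[float | None]:
        med: list[float | None] = []
        for i in range(n_items):
            donors = [
                getattr(r, attr)[i]
                for r in responses
                if not _is_missing(getattr(r, attr)[i])
            ]
            med.append(float(np.median(donors)) if donors else None)
        return med

    item_medians = {
        attr: medians_for(attr, config[key]["n_items"]) for attr, key in _ITEM_FIELDS
    }
    attitude_modes: dict[str, str | None] = {}
    for f in _ATTITUDE_FIELDS:
        donors = [getattr(r, f) for r in responses if getattr(r, f) is not None]
        attitude_modes[f] = max(set(donors), key=donors.count) if donors else None

    for r in responses:
        changes: dict = {}
        # figure rating: any missing answer becomes "no discrepancy"
        if _is_missing(r.frs_current) or _is_missing(r.frs_ideal):
            anchor = r.frs_current if not _is_missing(r.frs_current) else r.frs_ideal
            if _is_missing(anchor):
                anchor = (config["figure_rating_scale"]["min"] + config["figure_rating_scale"]["max"]) / 2
            changes["frs_current"] = float(anchor)
            changes["frs_ideal"] = float(anchor)
            log.append(
                {"participant_id": r.participant_id, "field": "figure_rating_scale",
                 "rule": "no_discrepancy", "value": float(anchor)}
            )
        if _is_missing(r.breakfast_days_per_week):
            changes["breakfast_days_per_week"] = 7.0
            log.append({"participant_id": r.participant_id, "field": "breakfast_days_per_week",
                        "rule": "7_days_per_week", "value": 7.0})
        if _is_missing(r.school_lunch_days_per_week):
            changes["school_lunch_days_per_week"] = 5.0
            log.append({"participant_id": r.participant_id, "field": "school_lunch_days_per_week",
                        "rule": "5_days_per_week", "value": 5.0})
        for attr, key in _ITEM_FIELDS:
            inst = config[key]
            items = list(getattr(r, attr))
            changed = False
            for i, v in enumerate(items):
                if not _is_missing(v):
                    continue
                if attr == "conscientiousness_items":
                    val = (inst["item_min"] + inst["item_max"]) / 2.0
                    rule = "scale_midpoint"
                else:
                    val = item_medians[attr][i]
                    rule = "item_median_of_others"
                    if val is None:
                        raise ImputationError(
                            f"no non-missing respondents for {attr} item {i + 1}"
                        )
                items[i] = val
                changed = True
                log.append({"participant_id": r.participant_id, "field": f"{attr}[{i + 1}]",
                            "rule": rule, "value": val})
            if changed:
                changes[attr] = tuple(items)
        for f in _ATTITUDE_FIELDS:
            if getattr(r, f) is None:
                mode = attitude_modes[f]
                if mode is None:
                    raise ImputationError(f"no non-missing respondents for {f}")
                changes[f] = mode
                log.append({"participant_id": r.participant_id, "field": f,
                            "rule": "mode_of_others", "value": mode})
        out.append(replace(r, **changes) if changes else r)
    return out, log


def dichotomize(response: QuestionnaireResponse) -> dict[str, bool]:
    """The analysis dichotomies on a complete response.

    Breakfast every day (7 vs <7), school lunch every school day (5 vs <5),
    and each attitude question as yes vs somewhat/no.
    """
    for f in ("breakfast_days_per_week", "school_lunch_days_per_week", *_ATTITUDE_FIELDS):
        if _is_missing(getattr(response, f)) or getattr(response, f) is None:
            raise MissingDataError(f"{f} missing; impute first")
    return {
        "breakfast_7": response.breakfast_days_per_week >= 7,
        "lunch_5": response.school_lunch_days_per_week >= 5,
        "eat_important_yes": response.eat_important == "yes",
        "comprehensible_yes": response.comprehensible == "yes",
        "manageable_yes": response.manageable == "yes",
        "meaningful_yes": response.meaningful == "yes",
    }


def score_response(
    response: QuestionnaireResponse, config: Mapping | None = None
) -> QuestionnaireScores:
    """Score one complete response into :class:`QuestionnaireScores`."""
    config = config or load_instrument_config()
    c = config["conscientiousness"]
    f = config["fear_of_negative_evaluation"]
    s = config["social_desirability"]
    tfeq = tfeq_r18_scores(response.tfeq_items, config)
    d = dichotomize(response)
    return QuestionnaireScores(
        participant_id=response.participant_id,
        conscientiousness=score_index(
            response.conscientiousness_items, c["item_min"], c["item_max"], c.get("reversed", ())
        ),
        fear_of_negative_evaluation=score_index(
            response.fne_items, f["item_min"], f["item_max"], f.get("reversed", ())
        ),
        social_desirability=score_index(
            response.sds_items, s["item_min"], s["item_max"], s.get("reversed", ())
        ),
        cognitive_restraint=tfeq["cognitive_restraint"],
        uncontrolled_eating=tfeq["uncontrolled_eating"],
        emotional_eating=tfeq["emotional_eating"],
        frs_discrepancy=frs_discrepancy(response.frs_current, response.frs_ideal),
        **d,
    )


# ---------------------------------------------------------------------------
# CSV IO — one row per respondent, one column per item

_ITEM_PREFIXES = {
    "conscientiousness_items": "consc",
    "fne_items": "fne",
    "sds_items": "sds",
    "tfeq_items": "tfeq",
}
_SCALAR_COLUMNS = (
    "frs_current",
    "frs_ideal",
    "breakfast_days_per_week",
    "school_lunch_days_per_week",
    "eat_important",
    "comprehensible",
    "manageable",
    "meaningful",
)


def save_responses(responses: Sequence[QuestionnaireResponse], path: str | Path) -> None:
    rows = []
    for r in responses:
        row: dict = {"participant_id": r.participant_id}
        for attr, prefix in _ITEM_PREFIXES.items():
            for i, v in enumerate(getattr(r, attr), start=1):
                row[f"{prefix}_{i}"] = v
        for c in _SCALAR_COLUMNS:
            row[c] = getattr(r, c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def load_responses(
    path: str | Path, config: Mapping | None = None
) -> list[QuestionnaireResponse]:
    config = config or load_instrument_config()
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise SchemaError("questionnaire CSV missing column participant_id")
    out = []
    for rec in df.to_dict("records"):
        kwargs: dict = {"participant_id": str(rec["participant_id"])}
        for (attr, key), prefix in zip(_ITEM_FIELDS, _ITEM_PREFIXES.values()):
            n = config[key]["n_items"]
            vals = []
            for i in range(1, n + 1):
                v = rec.get(f"{prefix}_{i}")
                vals.append(None if _is_missing(v) else float(v))
            kwargs[attr] = tuple(vals)
        for c in _SCALAR_COLUMNS:
            v = rec.get(c)
            if _is_missing(v):
                kwargs[c] = None
            elif c in _ATTITUDE_FIELDS:
                kwargs[c] = str(v)
            else:
                kwargs[c] = float(v)
        out.append(QuestionnaireResponse(**kwargs))
    return out
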