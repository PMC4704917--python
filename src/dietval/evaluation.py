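"""Energy-intake validation pipeline.

Given per-day reported energy intake (EI), minute-level armband reference
expenditure (TEE_SWA) and questionnaire-based expenditure
(TEE_app = Schofield BMR x PAL), this module implements the full
evaluation chain:

1. inclusion filters — drop recording days with EI below 2092 kJ
   (500 kcal) and armband days worn less than 19 h (80% of the day);
2. per-participant accuracy metrics — means of the included daily values
   (EI and TEE day sets may differ; the reference was worn on the same or
   proximate days), differences and ratios against TEE_SWA and BMR;
3. misreporting classification — EI within +/-5% of TEE_SWA is plausible,
   below is under-reporting, above is over-reporting (boundaries
   inclusive);
4. agreement and association — Bland-Altman limits of agreement
   (mean difference +/- 1.96 sample SD), Spearman correlations,
   Mann-Whitney / Wilcoxon / paired-t contracts;
5. reporting-accuracy regression — univariable OLS per candidate factor
   followed by forward stepwise selection (entry p < .05, removal
   p > .10), for the absolute (EI-TEE, kJ/day) and relative
   ((EI-TEE)/TEE) outcomes;
6. the design-stage sample-size formula n = 2*(2.8*SD/difference)^2 and a
   paired two-method comparison of intake variables.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    InsufficientDataError,
    PairingError,
    SingularityError,
    UndefinedStatisticError,
)
from .physiology import (
    LMSTable,
    Participant,
    SWADayRecord,
    anthro_result,
    pal_value,
    schofield_bmr,
    tee_swa,
    wear_hours,
)

__all__ = [
    "EIDay",
    "ParticipantEvaluation",
    "BlandAltmanResult",
    "AccuracyRegressionResult",
    "EI_EXCLUSION_KJ",
    "MIN_WEAR_HOURS",
    "PLAUSIBLE_BAND",
    "filter_ei_days",
    "filter_swa_days",
    "classify_reporting",
    "evaluate_participant",
    "bland_altman",
    "bland_altman_plot",
    "correlations",
    "group_compare",
    "paired_compare",
    "accuracy_regression",
    "sample_size",
    "method_comparison",
    "evaluate_study",
    "cohort_summary",
    "mixed_model_check",
]

#: Default inclusion thresholds and plausibility band.
EI_EXCLUSION_KJ = 2092.0  # 500 kcal
MIN_WEAR_HOURS = 19.0  # 80% of the day
PLAUSIBLE_BAND = 0.05
LOA_MULTIPLIER = 1.96


class EIDay(NamedTuple):
    """One participant-day of reported energy intake."""

    participant_id: str
    date: dt.date
    energy_kj: float


# ---------------------------------------------------------------------------
# filters


def filter_ei_days(
    days: Sequence[EIDay], threshold_kj: float = EI_EXCLUSION_KJ
) -> tuple[list[EIDay], list[dict]]:
    """Drop days with reported EI strictly below the threshold.

    A day at exactly the threshold is kept.  Returns (included days,
    exclusion log); idempotent on its own output.
    """
    included, log = [], []
    for d in days:
        if d.energy_kj < threshold_kj:
            log.append(
                {"participant_id": d.participant_id, "date": d.date,
                 "energy_kj": d.energy_kj, "reason": f"EI below {threshold_kj:g} kJ"}
            )
        else:
            included.append(d)
    return included, log


def filter_swa_days(
    records: Sequence[SWADayRecord], min_hours: float = MIN_WEAR_HOURS
) -> tuple[list[SWADayRecord], list[dict]]:
    """Keep armband days worn at least ``min_hours`` (inclusive)."""
    included, log = [], []
    for r in records:
        h = wear_hours(r)
        if h >= min_hours:
            included.append(r)
        else:
            log.append(
                {"participant_id": r.participant_id, "date": r.date,
                 "wear_hours": h, "reason": f"worn less than {min_hours:g} h"}
            )
    return included, log


def classify_reporting(
    ei_kj: float, tee_kj: float, band: float = PLAUSIBLE_BAND
) -> str:
    """Under/plausible/over-reporting of EI against a reference TEE.

    Plausible means EI/TEE within [1-band, 1+band], boundaries inclusive.
    """
    if tee_kj <= 0:
        raise ValueError("tee must be positive")
    ratio = ei_kj / tee_kj
    if ratio < 1.0 - band:
        return "under"
    if ratio > 1.0 + band:
        return "over"
    return "plausible"


# ---------------------------------------------------------------------------
# per-participant evaluation


@dataclass(frozen=True)
class ParticipantEvaluation:
    """Accuracy metrics for one participant (all energies kJ/day)."""

    participant_id: str
    n_ei_days: int
    n_swa_days: int
    has_weekend_ei_day: bool
    ei_kj: float
    tee_swa_kj: float
    tee_app_kj: float  # NaN when no daily activity answers exist
    bmr_kj: float
    reporting_class: str

    @property
    def ei_minus_tee(self) -> float:
        return self.ei_kj - self.tee_swa_kj

    @property
    def ei_over_tee(self) -> float:
        return self.ei_kj / self.tee_swa_kj

    @property
    def rel_accuracy(self) -> float:
        return (self.ei_kj - self.tee_swa_kj) / self.tee_swa_kj

    @property
    def ei_over_bmr(self) -> float:
        return self.ei_kj / self.bmr_kj

    @property
    def tee_over_bmr(self) -> float:
        return self.tee_swa_kj / self.bmr_kj

    @property
    def teeapp_minus_teeswa(self) -> float:
        return self.tee_app_kj - self.tee_swa_kj

    @property
    def teeapp_over_teeswa(self) -> float:
        return self.tee_app_kj / self.tee_swa_kj

    def as_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id,
            "n_ei_days": self.n_ei_days,
            "n_swa_days": self.n_swa_days,
            "has_weekend_ei_day": self.has_weekend_ei_day,
            "ei_kj": self.ei_kj,
            "tee_swa_kj": self.tee_swa_kj,
            "tee_app_kj": self.tee_app_kj,
            "bmr_kj": self.bmr_kj,
            "reporting_class": self.reporting_class,
        }
        for name in (
            "ei_minus_tee", "ei_over_tee", "rel_accuracy", "ei_over_bmr",
            "tee_over_bmr", "teeapp_minus_teeswa", "teeapp_over_teeswa",
        ):
            d[name] = getattr(self, name)
        return d


def evaluate_participant(
    ei_days: Sequence[EIDay],
    swa_days: Sequence[SWADayRecord],
    participant: Participant,
    reference_date: dt.date,
    app_tee_days: Sequence[tuple[dt.date, float]] | None = None,
    band: float = PLAUSIBLE_BAND,
) -> ParticipantEvaluation:
    """Aggregate included days into per-participant accuracy metrics.

    ``ei_days`` and ``swa_days`` are the already-filtered day sets; they
    need not cover the same dates.  ``app_tee_days`` carries per-day
    questionnaire-based TEE when the evening activity question was
    answered.  At least one day on each side is required.
    """
    if not ei_days or not swa_days:
        raise InsufficientDataError(
            f"participant {participant.participant_id}: need >=1 included EI day "
            f"and >=1 included armband day"
        )
    bmr = schofield_bmr(
        participant.gender, participant.age_years(reference_date), participant.weight_kg
    )
    ei = float(np.mean([d.energy_kj for d in ei_days]))
    tee = float(np.mean([tee_swa(r, bmr) for r in swa_days]))
    tee_app = (
        float(np.mean([v for _, v in app_tee_days])) if app_tee_days else float("nan")
    )
    return ParticipantEvaluation(
        participant_id=participant.participant_id,
        n_ei_days=len(ei_days),
        n_swa_days=len(swa_days),
        has_weekend_ei_day=any(d.date.weekday() >= 5 for d in ei_days),
        ei_kj=ei,
        tee_swa_kj=tee,
        tee_app_kj=tee_app,
        bmr_kj=bmr,
        reporting_class=classify_reporting(ei, tee, band),
    )


# ---------------------------------------------------------------------------
# agreement


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray
    ids: tuple
    outside_loa_ids: tuple

    @property
    def n(self) -> int:
        return len(self.diffs)


def bland_altman(
    x: Sequence[float],
    y: Sequence[float],
    ids: Sequence | None = None,
    k: float = LOA_MULTIPLIER,
) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements x vs y.

    Differences are x - y; limits of agreement are mean +/- k * sample SD
    (n-1 denominator, k = 1.96 by default).  Pairs with a difference
    strictly outside [loa_low, loa_high] are flagged.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 pairs")
    ids = tuple(ids) if ids is not None else tuple(range(len(x)))
    diffs = x - y
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    lo, hi = mean_diff - k * sd_diff, mean_diff + k * sd_diff
    outside = tuple(i for i, d in zip(ids, diffs) if d < lo or d > hi)
    return BlandAltmanResult(
        mean_diff=mean_diff, sd_diff=sd_diff, loa_low=lo, loa_high=hi,
        means=(x + y) / 2.0, diffs=diffs, ids=ids, outside_loa_ids=outside,
    )


def bland_altman_plot(result: BlandAltmanResult, path, xlabel="mean", ylabel="difference"):
    """Write the agreement plot (scatter + mean and LoA lines) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.means, result.diffs, s=18, alpha=0.8)
    for yv, style in ((result.mean_diff, "-"), (result.loa_low, "--"), (result.loa_high, "--")):
        ax.axhline(yv, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# correlation and comparison contracts (delegated to scipy.stats)


def correlations(
    df: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> dict[tuple[str, str], tuple[float, float]]:
    """Spearman rho and two-sided p for each named column pair.

    Ties get average ranks (scipy's convention).  Constant columns make
    the coefficient undefined.
    """
    out = {}
    for cx, cy in pairs:
        sub = df[[cx, cy]].dropna()
        if len(sub) < 3:
            raise InsufficientDataError(f"need >=3 complete pairs for ({cx}, {cy})")
        x, y = sub[cx].to_numpy(float), sub[cy].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise UndefinedStatisticError(f"constant vector in pair ({cx}, {cy})")
        rho, p = stats.spearmanr(x, y)
        out[(cx, cy)] = (float(rho), float(p))
    return out


def group_compare(values: Sequence[float], groups: Sequence) -> float:
    """Two-sided Mann-Whitney U p-value comparing exactly two groups."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 observations")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def paired_compare(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """(Wilcoxon signed-rank p, paired-t p), both two-sided.

    Identical pairs (all differences zero) return p = 1.0 for both tests
    by convention.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    d = a - b
    if np.all(d == 0):
        return 1.0, 1.0
    w_p = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
    t_p = float(stats.ttest_rel(a, b).pvalue)
    if math.isnan(t_p):  # zero-variance nonzero differences
        t_p = 0.0
    return w_p, t_p


# ---------------------------------------------------------------------------
# reporting-accuracy regression


#: Candidate factors, their type, and reference levels for the dummies.
_CANDIDATE_SPEC: tuple[tuple[str, str], ...] = (
    ("gender", "binary:male"),          # vs female
    ("bmi_zscore", "numeric"),
    ("tee_swa_kj", "numeric"),          # absolute outcome only
    ("parental_education", "cat:medium"),
    ("born_outside_sweden", "binary_any"),  # any vs none
    ("has_weekend_ei_day", "bool"),
    ("school", "cat:first"),
    ("fear_of_negative_evaluation", "numeric"),
    ("conscientiousness", "numeric"),
    ("social_desirability", "numeric"),
    ("cognitive_restraint", "numeric"),
    ("uncontrolled_eating", "numeric"),
    ("emotional_eating", "numeric"),
    ("frs_discrepancy", "cat:no_discrepancy"),
    ("breakfast_7", "bool"),
    ("lunch_5", "bool"),
    ("eat_important_yes", "bool"),
    ("comprehensible_yes", "bool"),
    ("manageable_yes", "bool"),
    ("meaningful_yes", "bool"),
)


@dataclass
class AccuracyRegressionResult:
    outcome: str
    n: int
    univariable: dict[str, dict]  # term -> {"term_p": float, "coefficients": [...]}
    selected: list[str]
    stepwise_coefficients: list[dict]


def _term_columns(df: pd.DataFrame, term: str, kind: str) -> pd.DataFrame | None:
    """Design-matrix block for one candidate term, or None if absent."""
    if term not in df.columns:
        return None
    s = df[term]
    if kind == "numeric":
        return pd.DataFrame({term: s.astype(float)})
    if kind == "bool":
        return pd.DataFrame({f"{term}[yes]": s.astype(bool).astype(float)})
    if kind.startswith("binary:"):
        level = kind.split(":", 1)[1]
        return pd.DataFrame({f"{term}[{level}]": (s == level).astype(float)})
    if kind == "binary_any":
        return pd.DataFrame({f"{term}[any]": (s.astype(str) != "none").astype(float)})
    if kind.startswith("cat:"):
        ref = kind.split(":", 1)[1]
        levels = sorted(s.astype(str).unique())
        if ref == "first":
            ref = levels[0]
        cols = {
            f"{term}[{lv}]": (s.astype(str) == lv).astype(float)
            for lv in levels
            if lv != ref
        }
        if not cols:
            return None
        return pd.DataFrame(cols)
    raise ValueError(f"unknown term kind {kind!r}")


def _fit(y: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # find columns that do not raise the rank
        bad, cols, base = [], [], None
        for c in Xc.columns:
            trial = Xc[cols + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(cols) + 1:
                cols.append(c)
            else:
                bad.append(c)
        raise SingularityError(
            f"design matrix is rank deficient; collinear column(s): {', '.join(bad)}",
            columns=bad,
        )
    return sm.OLS(y, Xc).fit()


def _term_pvalue(y: np.ndarray, base: pd.DataFrame | None, block: pd.DataFrame) -> float:
    """p-value of adding ``block`` to ``base`` (F-test; t-test equivalent
    for a single added column)."""
    X_full = pd.concat([base, block], axis=1) if base is not None else block
    full = _fit(y, X_full)
    if base is None or base.shape[1] == 0:
        restricted = sm.OLS(y, np.ones((len(y), 1))).fit()
    else:
        restricted = _fit(y, base)
    return float(full.compare_f_test(restricted)[1])


def accuracy_regression(
    data: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str] | None = None,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> AccuracyRegressionResult:
    """Univariable OLS per candidate factor, then forward stepwise selection.

    ``outcome`` is ``"ei_minus_tee"`` (kJ/day) or ``"rel_accuracy"``
    ((EI-TEE)/TEE); measured TEE is a candidate only for the absolute
    outcome (it is built into the relative one).  Rows with a missing
    outcome or candidate value are dropped.  Stepwise selection adds the
    smallest-p candidate while p < ``entry_p`` and removes included terms
    whose p rises above ``removal_p``.
    """
    if outcome not in ("ei_minus_tee", "rel_accuracy"):
        raise ValueError("outcome must be 'ei_minus_tee' or 'rel_accuracy'")
    spec = [
        (t, k)
        for t, k in _CANDIDATE_SPEC
        if (candidates is None or t in candidates)
        and not (outcome == "rel_accuracy" and t == "tee_swa_kj")
        and t in data.columns
    ]
    used_cols = [outcome] + [t for t, _ in spec]
    df = data[used_cols].dropna().reset_index(drop=True)
    if len(df) < 10:
        raise InsufficientDataError(f"need >=10 complete observations, got {len(df)}")
    y = df[outcome].to_numpy(float)

    blocks = {t: _term_columns(df, t, k) for t, k in spec}
    blocks = {t: b for t, b in blocks.items() if b is not None}

    univariable: dict[str, dict] = {}
    for term, block in blocks.items():
        res = _fit(y, block)
        ci = res.conf_int(alpha=0.05)
        coefs = [
            {
                "name": c,
                "coef": float(res.params[c]),
                "ci_low": float(ci.loc[c, 0]),
                "ci_high": float(ci.loc[c, 1]),
                "p": float(res.pvalues[c]),
            }
            for c in block.columns
        ]
        univariable[term] = {
            "term_p": _term_pvalue(y, None, block),
            "coefficients": coefs,
        }

    # forward stepwise with backward pruning
    selected: list[str] = []
    while True:
        changed = False
        remaining = [t for t in blocks if t not in selected]
        base = (
            pd.concat([blocks[t] for t in selected], axis=1) if selected else None
        )
        if remaining:
            pvals = {t: _term_pvalue(y, base, blocks[t]) for t in remaining}
            best = min(pvals, key=pvals.get)
            if pvals[best] < entry_p:
                selected.append(best)
                changed = True
        if selected:
            drop_p = {}
            for t in selected:
                others = [blocks[u] for u in selected if u != t]
                base_wo = pd.concat(others, axis=1) if others else None
                drop_p[t] = _term_pvalue(y, base_wo, blocks[t])
            worst = max(drop_p, key=drop_p.get)
            if drop_p[worst] > removal_p:
                selected.remove(worst)
                changed = True
        if not changed:
            break

    step_coefs: list[dict] = []
    if selected:
        res = _fit(y, pd.concat([blocks[t] for t in selected], axis=1))
        ci = res.conf_int(alpha=0.05)
        for c in res.params.index:
            if c == "const":
                continue
            step_coefs.append(
                {
                    "name": c,
                    "coef": float(res.params[c]),
                    "ci_low": float(ci.loc[c, 0]),
                    "ci_high": float(ci.loc[c, 1]),
                    "p": float(res.pvalues[c]),
                }
            )
    return AccuracyRegressionResult(
        outcome=outcome,
        n=len(df),
        univariable=univariable,
        selected=selected,
        stepwise_coefficients=step_coefs,
    )


def mixed_model_check(
    data: pd.DataFrame, outcome: str, fixed_terms: Sequence[str], group: str = "school"
):
    """Refit selected fixed effects with a random intercept per group.

    Sanity check that stepwise-selected effects are not artifacts of the
    clustering (here: school); returns the fitted MixedLM results object.
    """
    spec = dict(_CANDIDATE_SPEC)
    blocks = [
        _term_columns(data, t, spec.get(t, "numeric")) for t in fixed_terms
    ]
    X = sm.add_constant(pd.concat(blocks, axis=1), has_constant="add")
    model = sm.MixedLM(
        data[outcome].to_numpy(float), X, groups=data[group].astype(str)
    )
    return model.fit(reml=True)


# ---------------------------------------------------------------------------
# design-stage sample size and two-method comparison


def sample_size(sd: float, difference: float) -> int:
    """Participants needed per comparison: ceil(2 * (2.8 * sd/difference)^2).

    The 2.8 factor corresponds to alpha = .05 with 80% power for a paired
    difference.
    """
    if sd <= 0 or difference <= 0:
        raise ValueError("sd and difference must be positive")
    return math.ceil(2.0 * (2.8 * sd / difference) ** 2)


def method_comparison(
    intakes_a: pd.DataFrame,
    intakes_b: pd.DataFrame,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Paired comparison of two assessment methods, variable by variable.

    Inputs are participant-indexed tables of intake variables (energy,
    nutrients, food-group grams).  Returns one row per variable with the
    Wilcoxon signed-rank p, Spearman rho and the rho p-value.
    """
    if set(intakes_a.index) != set(intakes_b.index):
        raise PairingError("participant sets differ between the two methods")
    if variables is None:
        variables = list(intakes_a.columns)
    rows = []
    b = intakes_b.loc[intakes_a.index]
    for var in variables:
        if var not in intakes_a.columns or var not in intakes_b.columns:
            raise PairingError(f"variable {var!r} absent in one method")
        x = intakes_a[var].to_numpy(float)
        y = b[var].to_numpy(float)
        if len(x) < 3:
            raise InsufficientDataError(f"need >=3 pairs for {var!r}")
        w_p, _ = paired_compare(x, y)
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            rho, rho_p = 1.0, 1.0  # identical constant vectors
        else:
            rho, rho_p = stats.spearmanr(x, y)
        rows.append(
            {"variable": var, "wilcoxon_p": float(w_p),
             "spearman_rho": float(rho), "spearman_p": float(rho_p)}
        )
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# cohort driver


def evaluate_study(
    participants: Sequence[Participant],
    ei_days: Sequence[EIDay],
    swa_records: Sequence[SWADayRecord],
    lms_table: LMSTable | None = None,
    app_tee_days: Mapping[str, Sequence[tuple[dt.date, float]]] | None = None,
    reference_dates: Mapping[str, dt.date] | None = None,
    ei_threshold_kj: float = EI_EXCLUSION_KJ,
    min_wear_hours: float = MIN_WEAR_HOURS,
    band: float = PLAUSIBLE_BAND,
) -> pd.DataFrame:
    """Run filters + per-participant evaluation over a whole cohort.

    Returns one row per participant with at least one included EI day and
    one included armband day, carrying all accuracy metrics plus BMI,
    BMI z-score and weight status (when an LMS table is given).  The
    reference date for age defaults to the participant's first EI day.
    """
    inc_ei, _ = filter_ei_days(ei_days, ei_threshold_kj)
    inc_swa, _ = filter_swa_days(swa_records, min_wear_hours)
    ei_by_pid: dict[str, list[EIDay]] = {}
    for d in inc_ei:
        ei_by_pid.setdefault(d.participant_id, []).append(d)
    swa_by_pid: dict[str, list[SWADayRecord]] = {}
    for r in inc_swa:
        swa_by_pid.setdefault(r.participant_id, []).append(r)

    rows = []
    for p in participants:
        pid = p.participant_id
        if pid not in ei_by_pid or pid not in swa_by_pid:
            continue
        if reference_dates and pid in reference_dates:
            ref = reference_dates[pid]
        else:
            ref = min(d.date for d in ei_by_pid[pid])
        ev = evaluate_participant(
            ei_by_pid[pid],
            swa_by_pid[pid],
            p,
            ref,
            app_tee_days.get(pid) if app_tee_days else None,
            band=band,
        )
        row = ev.as_dict()
        row.update(
            gender=p.gender,
            school=p.school,
            parental_education=p.parental_education,
            born_outside_sweden=p.born_outside_sweden,
        )
        if lms_table is not None:
            an = anthro_result(p, ref, lms_table)
            row.update(bmi=an.bmi, bmi_zscore=an.bmi_zscore, weight_status=an.weight_status)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_summary(evaluation: pd.DataFrame) -> dict:
    """Cohort-level summaries: median (IQR) and mean (SD) per metric,
    reporting-class counts, and Bland-Altman agreement of EI vs TEE."""
    metrics = [
        "bmr_kj", "ei_kj", "tee_swa_kj", "tee_app_kj", "ei_over_bmr",
        "tee_over_bmr", "ei_minus_tee", "ei_over_tee",
        "teeapp_minus_teeswa", "teeapp_over_teeswa",
    ]
    out: dict = {"n": int(len(evaluation)), "metrics": {}}
    for m in metrics:
        if m not in evaluation.columns:
            continue
        s = evaluation[m].dropna()
        if s.empty:
            continue
        q1, q3 = s.quantile([0.25, 0.75])
        out["metrics"][m] = {
            "median": float(s.median()),
            "iqr": float(q3 - q1),
            "mean": float(s.mean()),
            "sd": float(s.std(ddof=1)),
            "n": int(len(s)),
        }
    counts = evaluation["reporting_class"].value_counts().to_dict()
    out["reporting_class"] = {k: int(v) for k, v in counts.items()}
    if len(evaluation) >= 3:
        ba = bland_altman(
            evaluation["ei_kj"], evaluation["tee_swa_kj"],
            ids=evaluation["participant_id"],
        )
        out["bland_altman_ei_vs_tee"] = {
            "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
            "loa_low": ba.loa_low, "loa_high": ba.loa_high,
            "outside_loa_ids": list(ba.outside_loa_ids),
        }
    return out
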