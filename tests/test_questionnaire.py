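import numpy as np
import pytest

from dietval.errors import ImputationError, MissingDataError, UndefinedStatisticError
from dietval.questionnaire import (
    QuestionnaireResponse,
    cronbach_alpha,
    dichotomize,
    frs_discrepancy,
    impute_missing,
    load_instrument_config,
    load_responses,
    save_responses,
    score_index,
    score_response,
    tfeq_r18_scores,
)


@pytest.fixture(scope="module")
def config():
    return load_instrument_config()


def complete_response(pid="p1", **overrides):
    kwargs = dict(
        participant_id=pid,
        conscientiousness_items=(4,) * 15,
        fne_items=(2,) * 5,
        sds_items=(1,) * 7,
        tfeq_items=(2,) * 18,
        frs_current=5.0,
        frs_ideal=4.0,
        breakfast_days_per_week=7.0,
        school_lunch_days_per_week=5.0,
        eat_important="yes",
        comprehensible="yes",
        manageable="somewhat",
        meaningful="no",
    )
    kwargs.update(overrides)
    return QuestionnaireResponse(**kwargs)


class TestScoreIndex:
    def test_anchors_and_midpoint(self):
        assert score_index([1] * 5, 1, 5) == 0.0
        assert score_index([5] * 5, 1, 5) == 100.0
        assert score_index([3] * 5, 1, 5) == 50.0

    def test_reverse_keyed_items_flip(self):
        # item 2 reversed: (5, 1) scores like (5, 5)
        assert score_index([5, 1], 1, 5, reversed_ids=[2]) == 100.0

    def test_missing_item_raises(self):
        with pytest.raises(MissingDataError):
            score_index([3, None, 3], 1, 5)

    def test_bounded_for_any_valid_input(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            items = rng.integers(1, 6, size=8).tolist()
            assert 0.0 <= score_index(items, 1, 5, reversed_ids=[1, 3]) <= 100.0


class TestTfeq:
    def test_all_max_scores_100_everywhere(self, config):
        scores = tfeq_r18_scores((4,) * 18, config)
        assert scores == pytest.approx(
            {"cognitive_restraint": 100.0, "uncontrolled_eating": 100.0,
             "emotional_eating": 100.0}
        )

    def test_subscale_independence(self, config):
        base = [2] * 18
        bumped = list(base)
        bumped[0] = 4  # item 1 belongs to uncontrolled eating
        s0 = tfeq_r18_scores(base, config)
        s1 = tfeq_r18_scores(bumped, config)
        assert s1["cognitive_restraint"] == s0["cognitive_restraint"]
        assert s1["emotional_eating"] == s0["emotional_eating"]
        assert s1["uncontrolled_eating"] > s0["uncontrolled_eating"]

    def test_hand_scored_vector(self, config):
        # CR items {2,11,12,15,16,18} set to 3, EE items {3,6,10} to 4, rest 1
        items = [1] * 18
        for i in (2, 11, 12, 15, 16, 18):
            items[i - 1] = 3
        for i in (3, 6, 10):
            items[i - 1] = 4
        s = tfeq_r18_scores(items, config)
        # hand computation: CR 6 items at 3 -> 100*6*2/(6*3); EE 3 at 4; UE 9 at 1
        assert s["cognitive_restraint"] == pytest.approx(100 * 12 / 18)
        assert s["emotional_eating"] == pytest.approx(100.0)
        assert s["uncontrolled_eating"] == pytest.approx(0.0)


class TestFrs:
    def test_categories(self):
        assert frs_discrepancy(5, 5) == "no_discrepancy"
        assert frs_discrepancy(6, 4) == "prefer_smaller"
        assert frs_discrepancy(3, 5) == "prefer_larger"

    def test_missing_raises(self):
        with pytest.raises(MissingDataError):
            frs_discrepancy(None, 4)


class TestImputation:
    def test_complete_collection_is_identity_with_empty_log(self):
        responses = [complete_response("p1"), complete_response("p2")]
        completed, log = impute_missing(responses)
        assert completed == responses
        assert log == []

    def test_missing_breakfast_and_lunch_rules(self):
        responses = [
            complete_response("p1", breakfast_days_per_week=None,
                              school_lunch_days_per_week=None),
            complete_response("p2"),
        ]
        completed, log = impute_missing(responses)
        assert completed[0].breakfast_days_per_week == 7.0
        assert completed[0].school_lunch_days_per_week == 5.0
        assert {e["rule"] for e in log} == {"7_days_per_week", "5_days_per_week"}

    def test_missing_frs_becomes_no_discrepancy(self):
        responses = [complete_response("p1", frs_ideal=None), complete_response("p2")]
        completed, _ = impute_missing(responses)
        assert frs_discrepancy(completed[0].frs_current, completed[0].frs_ideal) == (
            "no_discrepancy"
        )

    def test_missing_conscientiousness_item_gets_midpoint(self):
        items = list((4,) * 15)
        items[4] = None
        responses = [
            complete_response("p1", conscientiousness_items=tuple(items)),
            complete_response("p2"),
        ]
        completed, log = impute_missing(responses)
        assert completed[0].conscientiousness_items[4] == 3.0  # middle alternative
        assert log[0]["rule"] == "scale_midpoint"

    def test_missing_sds_item_gets_median_of_others(self):
        donors = [
            complete_response(f"d{i}", sds_items=(v, 1, 1, 1, 1, 1, 1))
            for i, v in enumerate([1, 2, 2, 3])
        ]
        target = complete_response("p0", sds_items=(None, 1, 1, 1, 1, 1, 1))
        completed, _ = impute_missing([target] + donors)
        assert completed[0].sds_items[0] == 2.0

    def test_median_rule_without_donors_fails(self):
        responses = [
            complete_response("p1", sds_items=(None, 1, 1, 1, 1, 1, 1)),
            complete_response("p2", sds_items=(None, 0, 0, 0, 0, 0, 0)),
        ]
        with pytest.raises(ImputationError):
            impute_missing(responses)

    def test_scoring_after_imputation_is_total(self):
        responses = [
            complete_response("p1", frs_current=None, breakfast_days_per_week=None,
                              tfeq_items=(None,) + (2,) * 17),
            complete_response("p2"),
            complete_response("p3"),
        ]
        completed, _ = impute_missing(responses)
        for r in completed:
            s = score_response(r)
            for idx in ("conscientiousness", "social_desirability", "uncontrolled_eating"):
                assert 0.0 <= getattr(s, idx) <= 100.0


class TestDichotomize:
    def test_breakfast_and_lunch_thresholds(self):
        assert dichotomize(complete_response(breakfast_days_per_week=7))["breakfast_7"]
        assert not dichotomize(complete_response(breakfast_days_per_week=6))["breakfast_7"]
        assert dichotomize(complete_response(school_lunch_days_per_week=5))["lunch_5"]
        assert not dichotomize(complete_response(school_lunch_days_per_week=4))["lunch_5"]

    def test_somewhat_counts_as_no(self):
        d = dichotomize(complete_response(eat_important="somewhat"))
        assert d["eat_important_yes"] is False
        assert dichotomize(complete_response(eat_important="yes"))["eat_important_yes"]


class TestCronbach:
    def test_hand_sized_matrix(self):
        x = np.array([[1.0, 2, 1, 3], [2, 3, 2, 4], [3, 4, 2, 5]])
        # hand: k=4, item vars (1,1,1/3,1), var of totals 37/3
        assert cronbach_alpha(x) == pytest.approx(0.972973, abs=1e-6)

    def test_parallel_items_approach_one(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(size=(200, 1))
        x = latent + rng.normal(scale=0.01, size=(200, 6))
        assert cronbach_alpha(x) > 0.99

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4000, 5))
        assert abs(cronbach_alpha(x)) < 0.1

    def test_zero_total_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cronbach_alpha(np.array([[1.0, 2.0], [1.0, 2.0]]))


def test_csv_round_trip_preserves_missingness(tmp_path):
    responses = [
        complete_response("p1", frs_ideal=None, eat_important="somewhat"),
        complete_response("p2", sds_items=(None, 1, 0, 1, 1, 0, 1)),
    ]
    p = tmp_path / "q.csv"
    save_responses(responses, p)
    again = load_responses(p)
    assert again[0].frs_ideal is None
    assert again[0].eat_important == "somewhat"
    assert again[1].sds_items[0] is None
    assert again[1].sds_items[1] == 1.0
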