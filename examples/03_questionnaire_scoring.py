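"""Impute and score questionnaire responses.

Two respondents, one with missing answers; the imputation rules fill the
gaps (figure rating -> no discrepancy, breakfast -> 7 days/week, item
scales -> midpoint or donor median) and every scale becomes a 0-100 index.
"""

from dietval import QuestionnaireResponse, impute_missing, score_response

complete = QuestionnaireResponse(
    participant_id="P002",
    conscientiousness_items=(4,) * 15,
    fne_items=(2, 3, 2, 1, 2),
    sds_items=(1, 0, 1, 1, 0, 1, 1),
    tfeq_items=(2, 3, 1, 2, 2, 1, 3, 2, 2, 1, 3, 3, 2, 2, 3, 2, 2, 3),
    frs_current=5, frs_ideal=4,
    breakfast_days_per_week=7, school_lunch_days_per_week=5,
    eat_important="yes", comprehensible="yes", manageable="yes", meaningful="somewhat",
)
incomplete = QuestionnaireResponse(
    participant_id="P001",
    conscientiousness_items=(3, None, 4, 4, 3, 4, 2, 4, 4, 3, 4, 4, 3, 4, 4),
    fne_items=(2, 2, 3, 2, 2),
    sds_items=(None, 0, 1, 1, 0, 1, 1),
    tfeq_items=(2,) * 18,
    frs_current=6, frs_ideal=None,          # -> imputed as no discrepancy
    breakfast_days_per_week=None,           # -> imputed as 7 days/week
    school_lunch_days_per_week=4,
    eat_important="somewhat", comprehensible="yes", manageable="yes", meaningful="yes",
)

completed, log = impute_missing([incomplete, complete])
print(f"imputed {len(log)} cells:")
for entry in log:
    print(f"  {entry['participant_id']} {entry['field']:<28} rule={entry['rule']}")

for r in completed:
    s = score_response(r)
    print(f"\n{s.participant_id}: conscientiousness {s.conscientiousness:.0f}, "
          f"uncontrolled eating {s.uncontrolled_eating:.0f}, "
          f"body-size preference {s.frs_discrepancy}, "
          f"breakfast every day: {s.breakfast_7}")
# Indices are linear 0-100 transforms of the item sums; the dichotomies
# ("breakfast every day", "eats lunch all 5 school days", attitude = yes)
# feed the reporting-accuracy regression downstream.
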