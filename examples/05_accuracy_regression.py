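"""Which participant factors predict reporting accuracy?

Runs univariable OLS for each candidate factor and a forward stepwise
model (entry p < .05, removal p > .10) on a synthetic cohort in which
accuracy truly improves with a weekend day in the record and worsens
with BMI z-score.
"""

from dietval import SimConfig, accuracy_regression, evaluation_frame, generate_study

frame = evaluation_frame(generate_study(SimConfig(seed=3)))

for outcome, unit in (("ei_minus_tee", "kJ/day"), ("rel_accuracy", "ratio")):
    res = accuracy_regression(frame, outcome)
    print(f"\noutcome {outcome} ({unit}), n = {res.n}")
    for term in ("has_weekend_ei_day", "bmi_zscore", "tee_swa_kj"):
        if term not in res.univariable:
            continue
        c = res.univariable[term]["coefficients"][0]
        print(f"  univariable {term:<20} b = {c['coef']:9.3f} "
              f"(95% CI {c['ci_low']:9.3f} to {c['ci_high']:9.3f}), p = {c['p']:.4f}")
    print(f"  stepwise selected: {res.selected or 'none'}")
    for c in res.stepwise_coefficients:
        print(f"    {c['name']:<26} b = {c['coef']:9.3f}")
# The weekend coefficient on the kJ outcome recovers the generator's
# injected +1557 kJ/day shift, and the BMI-z coefficient on the relative
# outcome recovers the injected -0.13 per z-unit gradient, within their
# confidence intervals.
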