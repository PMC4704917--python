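"""Basal metabolic rate, PAL multipliers, and the two TEE estimates.

Shows the Schofield weight-only BMR, the five-level sex-specific PAL
table, questionnaire-based TEE (BMR x PAL), and the armband-based
reference TEE with off-body minutes imputed at the basal rate.
"""

import datetime as dt

import numpy as np

from dietval import Participant, SWADayRecord, schofield_bmr, tee_app, tee_swa, wear_hours
from dietval.diet_record import ACTIVITY_LEVELS
from dietval.physiology import pal_value

today = dt.date(2013, 5, 15)
girl = Participant("P001", "female", dt.date(1997, 11, 10), weight_kg=57.4, height_cm=164.9)

bmr = schofield_bmr(girl.gender, girl.age_years(today), girl.weight_kg)
print(f"Schofield BMR for a 15.5-y girl of 57.4 kg: {bmr:.0f} kJ/day")

print("\nPAL table (girl / boy) and resulting TEE for the girl:")
for level in ACTIVITY_LEVELS:
    print(f"  {level:<11} {pal_value('female', level):.1f} / {pal_value('male', level):.1f}"
          f"   TEE_app = {tee_app(girl, level, today):7.0f} kJ/day")

# an armband day: constant 6.5 kJ/min while worn, one hour off-body
on = np.ones(1440, bool)
on[480:540] = False  # removed 08:00-09:00
ee = np.where(on, 6.5, 0.0)
rec = SWADayRecord("P001", today, ee, on)
print(f"\narmband wear time: {wear_hours(rec):.1f} h")
print(f"reference TEE (off-body hour imputed at BMR rate): {tee_swa(rec, bmr):.0f} kJ")
# The imputation adds bmr/24 =~ 255 kJ for the missing hour instead of
# counting it as zero expenditure.
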