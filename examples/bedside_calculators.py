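"""NIHSS scoring and weight-based tPA dosing.

The NIHSS total is the sum of the 15 instrument items (0-42); the dose
plan follows the licensed regimen: 0.9 mg/kg capped at 90 mg, 10% bolus.
"""

from lysisgate import nihss_total, tpa_dose
from lysisgate.bedside import NIHSS_ITEMS

moderate = {item: 0 for item in NIHSS_ITEMS}
moderate.update({"1a_loc": 1, "4_facial_palsy": 2, "5a_motor_arm_left": 3,
                 "6a_motor_leg_left": 2, "9_best_language": 1})
print(f"NIHSS total for a moderate left-sided stroke: {nihss_total(moderate)}")

for weight in (62.5, 80, 100, 120):
    plan = tpa_dose(weight)
    cap = " [capped at 90 mg]" if plan.capped else ""
    print(f"{weight:6.1f} kg -> total {plan.total_dose_mg} mg "
          f"(bolus {plan.bolus_mg}, infusion {plan.infusion_mg}){cap}")
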