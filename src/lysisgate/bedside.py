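"""Bedside calculators: NIHSS total score and weight-based tPA dosing.

The NIHSS (National Institutes of Health Stroke Scale) is the standard
15-item stroke severity instrument; its total ranges 0–42.  The item set
and per-item maxima are encoded as data so the form can be validated and
summed without hard-coding the instrument into control flow.

tPA dosing follows the standard licensed regimen for intravenous
alteplase: 0.9 mg per kg body weight, capped at 90 mg, with 10 % of the
total given as a bolus and the remainder infused.  The parameters are
arguments, not constants, so local protocols can override them.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict

__all__ = ["NIHSS_ITEMS", "NIHSSForm", "DosePlan", "nihss_total", "tpa_dose"]

#: Item name -> maximum score.  1a-1c level of consciousness, 2 gaze,
#: 3 visual fields, 4 facial palsy, 5/6 motor arm/leg per side, 7 limb
#: ataxia, 8 sensory, 9 language, 10 dysarthria, 11 extinction.
NIHSS_ITEMS: dict[str, int] = {
    "1a_loc": 3,
    "1b_loc_questions": 2,
    "1c_loc_commands": 2,
    "2_best_gaze": 2,
    "3_visual_fields": 3,
    "4_facial_palsy": 3,
    "5a_motor_arm_left": 4,
    "5b_motor_arm_right": 4,
    "6a_motor_leg_left": 4,
    "6b_motor_leg_right": 4,
    "7_limb_ataxia": 2,
    "8_sensory": 2,
    "9_best_language": 3,
    "10_dysarthria": 2,
    "11_extinction_inattention": 2,
}

assert sum(NIHSS_ITEMS.values()) == 42


class NIHSSForm(BaseModel):
    """A completed form: every instrument item with an in-range score."""

    model_config = ConfigDict(frozen=True)

    scores: dict[str, int]

    def __init__(self, **data):
        # accept item scores directly as keyword arguments for convenience
        if "scores" not in data:
            data = {"scores": data}
        super().__init__(**data)

    def model_post_init(self, __context) -> None:
        missing = sorted(set(NIHSS_ITEMS) - set(self.scores))
        if missing:
            raise ValueError(f"missing NIHSS items: {missing}")
        unknown = sorted(set(self.scores) - set(NIHSS_ITEMS))
        if unknown:
            raise ValueError(f"unknown NIHSS items: {unknown}")
        for item, score in self.scores.items():
            if not 0 <= score <= NIHSS_ITEMS[item]:
                raise ValueError(
                    f"NIHSS item {item!r} score {score} out of range 0..{NIHSS_ITEMS[item]}"
                )


def nihss_total(form: NIHSSForm | dict[str, int]) -> int:
    """Total NIHSS score, the sum of the 15 item scores (0–42)."""
    if isinstance(form, dict):
        form = NIHSSForm(scores=form)
    return sum(form.scores.values())


class DosePlan(BaseModel):
    model_config = ConfigDict(frozen=True)

    weight_kg: float
    total_dose_mg: float
    bolus_mg: float
    infusion_mg: float
    capped: bool


def tpa_dose(weight_kg: float, mg_per_kg: float = 0.9, max_mg: float = 90.0,
             bolus_fraction: float = 0.10) -> DosePlan:
    """Weight-based alteplase plan: total = min(mg_per_kg x weight, max_mg),
    rounded to 0.1 mg; 10 % bolus, remainder infused over an hour.

    Raises ``ValueError`` for a missing or non-positive weight — the one
    demographic the calculator cannot do without.
    """
    if weight_kg is None or not weight_kg > 0:
        raise ValueError("patient weight (kg) must be a positive number")
    raw = mg_per_kg * weight_kg
    capped = raw >= max_mg
    total = round(min(raw, max_mg), 1)
    bolus = round(total * bolus_fraction, 1)
    infusion = round(total - bolus, 1)
    return DosePlan(weight_kg=weight_kg, total_dose_mg=total, bolus_mg=bolus,
                    infusion_mg=infusion, capped=capped)
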