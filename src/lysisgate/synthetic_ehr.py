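"""Synthetic EHR generation: the four canonical mock cases, randomized
multi-hospital cohorts, and simulated physician screening responses.

The four mock cases reproduce the published evaluation fixtures: each is
a patient with history spread over two or more hospitals of the network,
carrying between them nine extractable contraindications over six
distinct catalog items.  The source table prints only years, so event
dates are assigned deterministically: "stroke in 3 months" entries are
dated 60 days before the index (inside the 90-day window of item 3) and
every other entry July 1 of its printed year (safely outside it).

Random cohorts and the physician miss/response simulator exist so the
snapshot, consent and study-analysis machinery can be exercised at any
scale without real data; everything is reproducible under a fixed seed.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .ehr_model import (
    AdverseDrugReaction,
    DiagnosisEvent,
    LabResult,
    MedicationEvent,
    PatientRecord,
)

__all__ = [
    "TABLE_CASE_HISTORY",
    "CASE_TRUTH",
    "CohortSpec",
    "MissModel",
    "PhysicianCaseResult",
    "make_mock_cases",
    "generate_cohort",
    "simulate_responses",
]

#: The published mock-case histories: (concept, hospital, year) per case.
#: "stroke in 3 months" rows are emitted as ischemic-stroke diagnoses
#: dated index - 60 days; "* use" rows as open-ended medication orders.
TABLE_CASE_HISTORY: dict[int, tuple[tuple[str, str, int], ...]] = {
    1: (
        ("dementia", "YCH", 2007),
        ("diabetes", "YCH", 2009),
        ("ischemic stroke", "CCH", 2012),
        ("stroke in 3 months", "YCH", 2014),
    ),
    2: (
        ("atrial fibrillation", "NCH", 2010),
        ("dementia", "NCH", 2010),
        ("diabetes", "NCH", 2010),
        ("heart failure", "NCH", 2008),
        ("hemodialysis", "CCH", 2000),
        ("ischemic stroke", "NCH", 2009),
        ("liver cirrhosis", "NCH", 2009),
    ),
    3: (
        ("atrial fibrillation", "CCH", 2012),
        ("dementia", "ECH", 2012),
        ("heart failure", "ECH", 2011),
        ("intracranial hemorrhage", "CCH", 2010),
        ("ischemic stroke", "CCH", 2012),
    ),
    4: (
        ("atrial fibrillation", "YSH", 2005),
        ("dementia", "CCH", 2014),
        ("diabetes", "CCH", 2011),
        ("ischemic stroke", "CCH", 2011),
        ("rivaroxaban use", "CCH", 2014),
        ("stroke in 3 months", "CCH", 2014),
        ("warfarin use", "CCH", 2014),
    ),
}

#: Ground-truth triggered catalog items per mock case: nine findings over
#: six distinct items.
CASE_TRUTH: dict[int, frozenset[int]] = {
    1: frozenset({3, 17}),
    2: frozenset({13, 15, 17}),
    3: frozenset({1}),
    4: frozenset({3, 16, 17}),
}


def make_mock_cases(
    reference_index_date: dt.date = dt.date(2014, 9, 1),
) -> tuple[list[PatientRecord], dt.datetime]:
    """Build the four mock patient records and the code-stroke index time.

    Every table cell appears exactly once as an event; all cases carry a
    dementia history; all consent to record sharing.
    """
    index = dt.datetime.combine(reference_index_date, dt.time(8, 0, 0))
    records = []
    for case_id, rows in TABLE_CASE_HISTORY.items():
        pid = f"case-{case_id}"
        diagnoses, medications = [], []
        for concept, hospital, year in rows:
            if concept.endswith(" use"):
                drug = concept[: -len(" use")]
                medications.append(MedicationEvent(
                    patient_id=pid, hospital_id=hospital, drug_concept=drug,
                    start_date=dt.date(year, 7, 1), stop_date=None,
                    tags=frozenset({"anticoagulant"}),
                ))
            elif concept == "stroke in 3 months":
                diagnoses.append(DiagnosisEvent(
                    patient_id=pid, hospital_id=hospital, concept="ischemic stroke",
                    date=reference_index_date - dt.timedelta(days=60),
                ))
            else:
                diagnoses.append(DiagnosisEvent(
                    patient_id=pid, hospital_id=hospital, concept=concept,
                    date=dt.date(year, 7, 1),
                ))
        records.append(PatientRecord(
            patient_id=pid, sharing_consent=True,
            diagnoses=tuple(diagnoses), medications=tuple(medications),
        ))
    return records, index


class CohortSpec(BaseModel):
    """Parameters of a randomized multi-hospital cohort."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(ge=0)
    prevalence: dict[str, float] = {}
    medication_prevalence: dict[str, float] = {}
    hospitals: tuple[str, ...] = ("CCH", "ECH", "LCH", "NCH", "YCH", "YMH", "YSH")
    consent_rate: float = Field(default=0.9, ge=0.0, le=1.0)
    start_date: dt.date = dt.date(2000, 1, 1)
    end_date: dt.date = dt.date(2014, 8, 31)
    seed: int = 0

    @model_validator(mode="after")
    def _probs(self) -> "CohortSpec":
        for name, p in {**self.prevalence, **self.medication_prevalence}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {name!r} must be in [0, 1], got {p}")
        if self.start_date > self.end_date:
            raise ValueError("start_date after end_date")
        return self


def _random_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a reproducible cohort: each patient visits 1–7 hospitals, each
    condition present independently with its prevalence, event dates
    uniform over the spec's date range."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_patients):
        pid = f"P{i:05d}"
        n_hosp = int(rng.integers(1, len(spec.hospitals) + 1))
        visited = list(rng.choice(spec.hospitals, size=n_hosp, replace=False))
        diagnoses, medications = [], []
        for concept in sorted(spec.prevalence):
            if rng.random() < spec.prevalence[concept]:
                diagnoses.append(DiagnosisEvent(
                    patient_id=pid,
                    hospital_id=visited[int(rng.integers(0, n_hosp))],
                    concept=concept,
                    date=_random_date(rng, spec.start_date, spec.end_date),
                ))
        for drug in sorted(spec.medication_prevalence):
            if rng.random() < spec.medication_prevalence[drug]:
                start = _random_date(rng, spec.start_date, spec.end_date)
                open_ended = rng.random() < 0.5
                stop = None if open_ended else _random_date(rng, start, spec.end_date)
                medications.append(MedicationEvent(
                    patient_id=pid,
                    hospital_id=visited[int(rng.integers(0, n_hosp))],
                    drug_concept=drug, start_date=start, stop_date=stop,
                ))
        records.append(PatientRecord(
            patient_id=pid,
            sharing_consent=bool(rng.random() < spec.consent_rate),
            diagnoses=tuple(diagnoses),
            medications=tuple(medications),
        ))
    return records


class MissModel(BaseModel):
    """Per-arm physician behavior for the simulated crossover study.

    Each contraindication-item opportunity is missed independently with
    the arm's probability.  Review times per case are log-normal,
    parameterized by the per-case mean and SD in minutes (the published
    per-session times halve to per-case defaults; times are simulation
    realism only and never an analysis target).
    """

    model_config = ConfigDict(frozen=True)

    p_control: float = Field(ge=0.0, le=1.0)
    p_intervention: float = Field(ge=0.0, le=1.0)
    control_time_mean: float = Field(default=7.3, gt=0)
    control_time_sd: float = Field(default=5.2, ge=0)
    intervention_time_mean: float = Field(default=3.65, gt=0)
    intervention_time_sd: float = Field(default=3.7, ge=0)


class PhysicianCaseResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    physician_id: int
    arm: str  # "control" | "intervention"
    case_id: int
    missed_items: tuple[int, ...]
    time_min: float


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    sigma2 = float(np.log(1.0 + (sd / mean) ** 2))
    mu = float(np.log(mean)) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def simulate_responses(
    assignment,
    case_truth: dict[int, frozenset[int]] | None = None,
    miss_model: MissModel | None = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> list[PhysicianCaseResult]:
    """Simulate each physician screening their assigned cases in both arms.

    ``assignment`` is an ``evaluation.design.StudyAssignment``; truth sets
    default to the mock-case ground truth.  Deterministic under a fixed
    rng/seed.
    """
    from .evaluation.design import StudyAssignment  # circular-import guard

    assert isinstance(assignment, StudyAssignment)
    case_truth = CASE_TRUTH if case_truth is None else case_truth
    if miss_model is None:
        miss_model = MissModel(p_control=0.426, p_intervention=0.130)
    if rng is None:
        rng = np.random.default_rng(seed)
    results = []
    for pa in assignment.assignments:
        for arm, cases in (("control", pa.control_cases), ("intervention", pa.intervention_cases)):
            p = miss_model.p_control if arm == "control" else miss_model.p_intervention
            t_mean = miss_model.control_time_mean if arm == "control" else miss_model.intervention_time_mean
            t_sd = miss_model.control_time_sd if arm == "control" else miss_model.intervention_time_sd
            for case_id in cases:
                missed = tuple(
                    item for item in sorted(case_truth[case_id]) if rng.random() < p
                )
                results.append(PhysicianCaseResult(
                    physician_id=pa.physician_id, arm=arm, case_id=case_id,
                    missed_items=missed, time_min=round(_lognormal(rng, t_mean, t_sd), 2),
                ))
    return results
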