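"""Domain types for multi-hospital clinical events and JSON Lines I/O.

The data model mirrors what a shared electronic medical record across a
regional hospital network exposes to a screening engine: coded diagnoses,
medication orders with open or closed intervals, adverse drug reactions,
and the laboratory/imaging results generated around a code-stroke
activation.  Records carry a sharing-consent flag: without consent only
events from the treating (home) hospital are visible to a screen.

All timestamps are naive local time (single-region health system); dates
are calendar dates serialized ISO-8601.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import math
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    field_serializer,
    field_validator,
    model_validator,
)

__all__ = [
    "CodeSystem",
    "EncounterKind",
    "Sex",
    "Hospital",
    "CCHS_HOSPITALS",
    "DiagnosisEvent",
    "MedicationEvent",
    "AdverseDrugReaction",
    "LabResult",
    "ImagingResult",
    "PatientRecord",
    "RecordParseError",
    "read_records",
    "write_records",
    "restrict_to_consented",
    "export_diagnoses_csv",
]


class CodeSystem(str, Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"
    LOCAL = "LOCAL"


class EncounterKind(str, Enum):
    ADMISSION = "ADMISSION"
    OUTPATIENT = "OUTPATIENT"


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"


class Hospital(BaseModel):
    """One site of the hospital network, keyed by a short code."""

    model_config = ConfigDict(frozen=True)

    hospital_id: str = Field(min_length=1)
    name: str = Field(min_length=1)


#: The seven-site network the screener was designed around: one medical
#: center and six community hospitals sharing a single EMR.
CCHS_HOSPITALS: dict[str, Hospital] = {
    h.hospital_id: h
    for h in (
        Hospital(hospital_id="CCH", name="Changhua Christian Hospital"),
        Hospital(hospital_id="ECH", name="Erlin Christian Hospital"),
        Hospital(hospital_id="LCH", name="Lukang Christian Hospital"),
        Hospital(hospital_id="NCH", name="Nanto Christian Hospital"),
        Hospital(hospital_id="YCH", name="Yunlin Christian Hospital"),
        Hospital(hospital_id="YMH", name="Yomin Hospital"),
        Hospital(hospital_id="YSH", name="Yuanshen Hospital"),
    )
}


class _Event(BaseModel):
    """Base for clinical events.  Unknown input fields are preserved."""

    model_config = ConfigDict(extra="allow")

    patient_id: str = Field(min_length=1)
    hospital_id: str = Field(min_length=1)

    def _dedupe_key(self) -> str:
        return type(self).__name__ + self.model_dump_json()


class DiagnosisEvent(_Event):
    concept: str = Field(min_length=1, description="canonical condition label")
    code: str = ""
    code_system: CodeSystem = CodeSystem.LOCAL
    date: dt.date
    encounter_kind: EncounterKind = EncounterKind.ADMISSION


class MedicationEvent(_Event):
    drug_concept: str = Field(min_length=1)
    start_date: dt.date
    stop_date: Optional[dt.date] = None  # None = open-ended (still taking)
    tags: frozenset[str] = frozenset()

    @model_validator(mode="after")
    def _interval_ordered(self) -> "MedicationEvent":
        if self.stop_date is not None and self.start_date > self.stop_date:
            raise ValueError("medication start_date must not be after stop_date")
        return self

    @field_serializer("tags")
    def _ser_tags(self, v: frozenset[str]) -> list[str]:
        return sorted(v)


class AdverseDrugReaction(_Event):
    drug_concept: str = Field(min_length=1)
    reaction: str = Field(min_length=1)
    date: dt.date


class LabResult(_Event):
    analyte: str = Field(min_length=1)
    value: float
    units: str = ""
    collected_at: dt.datetime

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("lab value must be finite")
        return v


class ImagingResult(_Event):
    modality: str = Field(min_length=1)
    finding_summary: str = ""
    acquired_at: dt.datetime


def _sorted_events(kind: str, events: Iterable[_Event]) -> tuple:
    keys = {
        "diagnoses": lambda e: (e.date, e.hospital_id, e.concept, e.code),
        "medications": lambda e: (
            e.start_date,
            e.stop_date is None,
            e.stop_date or e.start_date,
            e.hospital_id,
            e.drug_concept,
        ),
        "adverse_reactions": lambda e: (e.date, e.hospital_id, e.drug_concept, e.reaction),
        "labs": lambda e: (e.collected_at, e.hospital_id, e.analyte, e.value),
        "imaging": lambda e: (e.acquired_at, e.hospital_id, e.modality),
    }
    return tuple(sorted(events, key=keys[kind]))


class PatientRecord(BaseModel):
    """A patient's consent flag, demographics and all clinical events.

    Event collections are stored canonically sorted, so two records built
    from the same events in any order compare equal.
    """

    patient_id: str = Field(min_length=1)
    birth_year: Optional[int] = None
    sex: Optional[Sex] = None
    weight_kg: Optional[float] = Field(default=None, gt=0)
    sharing_consent: bool = False
    diagnoses: tuple[DiagnosisEvent, ...] = ()
    medications: tuple[MedicationEvent, ...] = ()
    adverse_reactions: tuple[AdverseDrugReaction, ...] = ()
    labs: tuple[LabResult, ...] = ()
    imaging: tuple[ImagingResult, ...] = ()

    @model_validator(mode="after")
    def _canonical(self) -> "PatientRecord":
        for kind in ("diagnoses", "medications", "adverse_reactions", "labs", "imaging"):
            events = getattr(self, kind)
            for ev in events:
                if ev.patient_id != self.patient_id:
                    raise ValueError(
                        f"{kind} event patient_id {ev.patient_id!r} does not match "
                        f"record {self.patient_id!r}"
                    )
            object.__setattr__(self, kind, _sorted_events(kind, events))
        return self

    def all_events(self) -> list[_Event]:
        return [
            *self.diagnoses,
            *self.medications,
            *self.adverse_reactions,
            *self.labs,
            *self.imaging,
        ]


class RecordParseError(ValueError):
    """A malformed line or inconsistent patient structure in a JSONL file."""


_EVENT_TYPES: dict[str, type[_Event]] = {
    "diagnosis": DiagnosisEvent,
    "medication": MedicationEvent,
    "adr": AdverseDrugReaction,
    "lab": LabResult,
    "imaging": ImagingResult,
}
_KIND_FIELD: dict[str, str] = {
    "diagnosis": "diagnoses",
    "medication": "medications",
    "adr": "adverse_reactions",
    "lab": "labs",
    "imaging": "imaging",
}


def read_records(path: str | Path, format: str = "JSONL") -> list[PatientRecord]:
    """Read patient records from a JSON Lines event file.

    Each line is one object tagged by ``record_type``: a ``patient`` header
    (consent and demographics) or one of ``diagnosis``, ``medication``,
    ``adr``, ``lab``, ``imaging``.  Line order is irrelevant; events are
    grouped by ``patient_id`` and returned sorted by patient id.

    Raises :class:`RecordParseError` naming the offending line for malformed
    JSON, unknown record types, duplicate patient headers, or events whose
    patient never appears as a header.
    """
    if format.upper() != "JSONL":
        raise ValueError(f"unsupported format: {format!r}")
    headers: dict[str, dict] = {}
    events: dict[str, dict[str, list[_Event]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise RecordParseError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
            if not isinstance(obj, dict) or "record_type" not in obj:
                raise RecordParseError(f"line {lineno}: missing record_type")
            rtype = obj.pop("record_type")
            if rtype == "patient":
                pid = obj.get("patient_id")
                if not pid:
                    raise RecordParseError(f"line {lineno}: patient header without patient_id")
                if pid in headers:
                    raise RecordParseError(
                        f"line {lineno}: duplicate patient header for {pid!r}"
                    )
                headers[pid] = obj
            elif rtype in _EVENT_TYPES:
                try:
                    ev = _EVENT_TYPES[rtype].model_validate(obj)
                except Exception as exc:
                    raise RecordParseError(f"line {lineno}: invalid {rtype} event: {exc}") from exc
                events.setdefault(ev.patient_id, {}).setdefault(rtype, []).append(ev)
            else:
                raise RecordParseError(f"line {lineno}: unknown record_type {rtype!r}")
    orphans = sorted(set(events) - set(headers))
    if orphans:
        raise RecordParseError(f"events for patients without a header line: {orphans}")
    records = []
    for pid in sorted(headers):
        fields = {_KIND_FIELD[rt]: tuple(evs) for rt, evs in events.get(pid, {}).items()}
        header = dict(headers[pid])
        header.pop("patient_id", None)
        try:
            records.append(PatientRecord(patient_id=pid, **header, **fields))
        except ValueError as exc:
            raise RecordParseError(f"invalid record for patient {pid!r}: {exc}") from exc
    return records


def _dump_line(record_type: str, model: BaseModel) -> str:
    obj = model.model_dump(mode="json")
    obj["record_type"] = record_type
    return json.dumps(obj, sort_keys=True, ensure_ascii=False)


def write_records(records: Sequence[PatientRecord], path: str | Path, format: str = "JSONL") -> None:
    """Write records as deterministic JSON Lines (sorted keys, ISO dates).

    The output is byte-stable for a given set of records: patients are
    ordered by id, events by their canonical sort, and open-ended
    medication stops serialize as ``null``.
    """
    if format.upper() != "JSONL":
        raise ValueError(f"unsupported format: {format!r}")
    lines: list[str] = []
    for rec in sorted(records, key=lambda r: r.patient_id):
        header = rec.model_dump(
            mode="json",
            exclude={"diagnoses", "medications", "adverse_reactions", "labs", "imaging"},
        )
        header["record_type"] = "patient"
        lines.append(json.dumps(header, sort_keys=True, ensure_ascii=False))
        for rtype, field in _KIND_FIELD.items():
            for ev in getattr(rec, field):
                lines.append(_dump_line(rtype, ev))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def restrict_to_consented(
    record: PatientRecord,
    home_hospital_id: str,
    registry: dict[str, Hospital] | None = None,
) -> PatientRecord:
    """Apply consent gating: without sharing consent, only events recorded
    at the home (treating) hospital are visible.

    Idempotent, and never adds events.  ``home_hospital_id`` must exist in
    the hospital registry (default: the seven-site network).
    """
    registry = CCHS_HOSPITALS if registry is None else registry
    if home_hospital_id not in registry:
        raise ValueError(f"unknown hospital id: {home_hospital_id!r}")
    if record.sharing_consent:
        return record
    kept = {
        field: tuple(e for e in getattr(record, field) if e.hospital_id == home_hospital_id)
        for field in _KIND_FIELD.values()
    }
    return record.model_copy(update=kept)


def export_diagnoses_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write one row per diagnosis event for spreadsheet inspection."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["patient_id", "hospital_id", "concept", "code", "code_system", "date", "encounter_kind"]
        )
        for rec in sorted(records, key=lambda r: r.patient_id):
            for d in rec.diagnoses:
                writer.writerow(
                    [d.patient_id, d.hospital_id, d.concept, d.code,
                     d.code_system.value, d.date.isoformat(), d.encounter_kind.value]
                )
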