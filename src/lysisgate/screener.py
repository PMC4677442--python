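"""Evaluate the contraindication catalog against a patient record.

The screen answers, at a code-stroke index time, which catalog items are
TRIGGERED by the patient's multi-hospital history (with full evidence
provenance), which are CLEAR, and which are NOT_EXTRACTABLE because they
require on-site measurement.  Two execution paths exist and are
guaranteed equivalent:

* a fresh screen over the full (consent-gated) record, and
* a daily-built snapshot database queried at alarm time and merged with
  a live pass over events recorded after the snapshot build.

Window semantics: a clause with lookback W matches events dated in the
closed interval [index − W days, index]; events after the index are
ignored entirely.  Medication clauses use interval overlap with a
30-day recency window when their lookback is unlimited (see
knowledge_base.MEDICATION_RECENCY_DAYS).
"""

from __future__ import annotations

import datetime as dt
import json
from enum import Enum
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .ehr_model import (
    AdverseDrugReaction,
    DiagnosisEvent,
    Hospital,
    ImagingResult,
    LabResult,
    MedicationEvent,
    PatientRecord,
    restrict_to_consented,
    _Event,
)
from .knowledge_base import (
    MEDICATION_RECENCY_DAYS,
    AllOf,
    AnyOf,
    Catalog,
    ContraindicationRule,
    Exists,
    ExistsClause,
    Predicate,
    Source,
)

__all__ = [
    "Status",
    "Evidence",
    "ScreenFinding",
    "ScreenReport",
    "SnapshotDatabase",
    "evaluate_rule",
    "screen_patient",
    "build_snapshot",
    "screen_with_snapshot",
    "render_report",
    "save_snapshot",
    "load_snapshot",
]

#: Labs and imaging shown alongside the screen are those generated in the
#: 24 hours before the index time (closed interval).
RECENT_WINDOW = dt.timedelta(hours=24)


class Status(str, Enum):
    TRIGGERED = "TRIGGERED"
    CLEAR = "CLEAR"
    NOT_EXTRACTABLE = "NOT_EXTRACTABLE"


class Evidence(BaseModel):
    """Provenance of one matching event: where, when, and what concept."""

    model_config = ConfigDict(frozen=True)

    source: Source
    hospital_id: str
    concept: str
    date: dt.date
    end_date: Optional[dt.date] = None  # medications: interval end (None = open)
    code: Optional[str] = None

    @classmethod
    def from_event(cls, source: Source, event: _Event) -> "Evidence":
        if source is Source.DIAGNOSIS:
            return cls(source=source, hospital_id=event.hospital_id,
                       concept=event.concept, date=event.date,
                       code=event.code or None)
        if source is Source.MEDICATION:
            return cls(source=source, hospital_id=event.hospital_id,
                       concept=event.drug_concept, date=event.start_date,
                       end_date=event.stop_date)
        return cls(source=source, hospital_id=event.hospital_id,
                   concept=event.drug_concept, date=event.date)


class ScreenFinding(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_id: int
    status: Status
    evidence: tuple[Evidence, ...] = ()


class ScreenReport(BaseModel):
    patient_id: str
    index_datetime: dt.datetime
    snapshot_time: Optional[dt.datetime] = None
    findings: tuple[ScreenFinding, ...]
    advisories: tuple[tuple[str, tuple[Evidence, ...]], ...] = ()
    recent_labs: tuple[LabResult, ...] = ()
    recent_imaging: tuple[ImagingResult, ...] = ()

    def triggered_items(self) -> set[int]:
        return {f.item_id for f in self.findings if f.status is Status.TRIGGERED}

    def equivalent_to(self, other: "ScreenReport") -> bool:
        """Equality of everything except the snapshot provenance stamp."""
        mine = self.model_dump(exclude={"snapshot_time"})
        theirs = other.model_dump(exclude={"snapshot_time"})
        return mine == theirs


def _clause_matches(clause: ExistsClause, record: PatientRecord,
                    index: dt.datetime) -> list[tuple[Source, _Event]]:
    """Events of the record matching one existence clause at the index."""
    index_date = index.date()
    window_start: Optional[dt.date] = None
    if clause.lookback_days is not None:
        window_start = index_date - dt.timedelta(days=clause.lookback_days)
    out: list[tuple[Source, _Event]] = []
    if clause.source is Source.DIAGNOSIS:
        for ev in record.diagnoses:
            if ev.date > index_date:
                continue
            if window_start is not None and ev.date < window_start:
                continue
            if clause.concepts.matches_label(ev.concept) or (
                ev.code and clause.concepts.matches_code(ev.code_system, ev.code)
            ):
                out.append((Source.DIAGNOSIS, ev))
    elif clause.source is Source.MEDICATION:
        # Interval-overlap semantics: the order's [start, stop] (stop open =
        # still taking) must overlap [index - W, index]; an unlimited
        # lookback uses the medication recency window instead.
        recency = clause.lookback_days if clause.lookback_days is not None else MEDICATION_RECENCY_DAYS
        overlap_start = index_date - dt.timedelta(days=recency)
        for ev in record.medications:
            if ev.start_date > index_date:
                continue
            if ev.stop_date is not None and ev.stop_date < overlap_start:
                continue
            if clause.concepts.matches_label(ev.drug_concept) or any(
                clause.concepts.matches_label(t) for t in ev.tags
            ):
                out.append((Source.MEDICATION, ev))
    elif clause.source is Source.ADR:
        for ev in record.adverse_reactions:
            if ev.date > index_date:
                continue
            if window_start is not None and ev.date < window_start:
                continue
            if clause.concepts.matches_label(ev.drug_concept) or clause.concepts.matches_label(ev.reaction):
                out.append((Source.ADR, ev))
    return out


def _eval_predicate(pred: Predicate, record: PatientRecord,
                    index: dt.datetime) -> tuple[bool, list[tuple[Source, _Event]]]:
    """Returns (satisfied, union of clause-matching events).

    The match list is collected from every leaf regardless of overall
    satisfaction; it is both the evidence (when satisfied) and the
    clause-level index stored in the daily snapshot.
    """
    if isinstance(pred, Exists):
        matches = _clause_matches(pred.exists, record, index)
        return bool(matches), matches
    children = pred.all if isinstance(pred, AllOf) else pred.any
    results = [_eval_predicate(c, record, index) for c in children]
    sat = (all if isinstance(pred, AllOf) else any)(r[0] for r in results)
    merged: list[tuple[Source, _Event]] = []
    for _, m in results:
        merged.extend(m)
    return sat, merged


def _sorted_evidence(matches: Sequence[tuple[Source, _Event]]) -> tuple[Evidence, ...]:
    seen: set[str] = set()
    evidence = []
    for source, ev in matches:
        key = source.value + ev._dedupe_key()
        if key in seen:
            continue
        seen.add(key)
        evidence.append(Evidence.from_event(source, ev))
    evidence.sort(key=lambda e: (e.date, e.hospital_id, e.concept))
    return tuple(evidence)


def evaluate_rule(rule: ContraindicationRule, record: PatientRecord,
                  index: dt.datetime) -> ScreenFinding:
    """Evaluate one catalog item; TRIGGERED findings list every matching
    event across all hospitals, sorted by date then hospital then concept."""
    if not rule.extractable:
        return ScreenFinding(item_id=rule.item_id, status=Status.NOT_EXTRACTABLE)
    sat, matches = _eval_predicate(rule.predicate, record, index)
    if not sat:
        return ScreenFinding(item_id=rule.item_id, status=Status.CLEAR)
    return ScreenFinding(item_id=rule.item_id, status=Status.TRIGGERED,
                         evidence=_sorted_evidence(matches))


def _recent(record: PatientRecord, index: dt.datetime):
    labs = tuple(l for l in record.labs if index - RECENT_WINDOW <= l.collected_at <= index)
    imaging = tuple(i for i in record.imaging if index - RECENT_WINDOW <= i.acquired_at <= index)
    return labs, imaging


def screen_patient(record: PatientRecord, catalog: Catalog, index: dt.datetime,
                   home_hospital: str = "CCH",
                   registry: dict[str, Hospital] | None = None) -> ScreenReport:
    """Fresh screen: consent-gate the record, evaluate every catalog item
    and advisory, and collect labs/imaging from the 24-h window."""
    visible = restrict_to_consented(record, home_hospital, registry)
    findings = tuple(evaluate_rule(rule, visible, index) for rule in catalog.items)
    advisories = []
    for adv in catalog.advisories:
        sat, matches = _eval_predicate(adv.predicate, visible, index)
        if sat:
            advisories.append((adv.label, _sorted_evidence(matches)))
    labs, imaging = _recent(visible, index)
    return ScreenReport(
        patient_id=record.patient_id,
        index_datetime=index,
        findings=findings,
        advisories=tuple(advisories),
        recent_labs=labs,
        recent_imaging=imaging,
    )


class SnapshotDatabase(BaseModel):
    """The daily-built screening index.

    For every consented patient it precomputes the TRIGGERED findings as
    of the build time (for instant display) and keeps the clause-level
    match index — the events that matched any rule or advisory clause.
    Because clause windows slide forward with the index time, any
    pre-build event that can contribute to a screen at a later index
    already matched its clause at build time, so merging this index with
    events recorded after the build reproduces a fresh screen exactly.
    """

    build_time: dt.datetime
    findings: dict[str, tuple[ScreenFinding, ...]] = {}
    matched: dict[str, PatientRecord] = {}


def _clip_record(record: PatientRecord, as_of_date: dt.date) -> PatientRecord:
    return record.model_copy(update={
        "diagnoses": tuple(e for e in record.diagnoses if e.date <= as_of_date),
        "medications": tuple(e for e in record.medications if e.start_date <= as_of_date),
        "adverse_reactions": tuple(e for e in record.adverse_reactions if e.date <= as_of_date),
        "labs": (),
        "imaging": (),
    })


def build_snapshot(records: Sequence[PatientRecord], catalog: Catalog,
                   as_of: dt.datetime) -> SnapshotDatabase:
    """Nightly build: screen every *consented* patient over events dated up
    to the build time.  Unconsented patients are omitted entirely."""
    findings: dict[str, tuple[ScreenFinding, ...]] = {}
    matched: dict[str, PatientRecord] = {}
    for record in records:
        if not record.sharing_consent:
            continue
        visible = _clip_record(record, as_of.date())
        triggered = []
        matches: list[tuple[Source, _Event]] = []
        for rule in catalog.items:
            if not rule.extractable:
                continue
            sat, m = _eval_predicate(rule.predicate, visible, as_of)
            matches.extend(m)
            if sat:
                triggered.append(ScreenFinding(
                    item_id=rule.item_id, status=Status.TRIGGERED,
                    evidence=_sorted_evidence(m)))
        for adv in catalog.advisories:
            _, m = _eval_predicate(adv.predicate, visible, as_of)
            matches.extend(m)
        findings[record.patient_id] = tuple(triggered)
        matched[record.patient_id] = _match_index_record(record, matches)
    return SnapshotDatabase(build_time=as_of, findings=findings, matched=matched)


def _match_index_record(record: PatientRecord,
                        matches: Sequence[tuple[Source, _Event]]) -> PatientRecord:
    by_kind: dict[Source, dict[str, _Event]] = {s: {} for s in Source}
    for source, ev in matches:
        by_kind[source][ev._dedupe_key()] = ev
    return PatientRecord(
        patient_id=record.patient_id,
        sharing_consent=True,
        diagnoses=tuple(by_kind[Source.DIAGNOSIS].values()),
        medications=tuple(by_kind[Source.MEDICATION].values()),
        adverse_reactions=tuple(by_kind[Source.ADR].values()),
    )


def _merge_events(base: PatientRecord, live: PatientRecord,
                  build_date: dt.date) -> PatientRecord:
    """Union of the snapshot match index and live events after the build."""
    def union(kind: str, live_pred) -> tuple:
        seen: dict[str, _Event] = {}
        for ev in getattr(base, kind):
            seen[ev._dedupe_key()] = ev
        for ev in getattr(live, kind):
            if live_pred(ev):
                seen[ev._dedupe_key()] = ev
        return tuple(seen.values())

    return live.model_copy(update={
        "diagnoses": union("diagnoses", lambda e: e.date > build_date),
        "medications": union("medications", lambda e: e.start_date > build_date),
        "adverse_reactions": union("adverse_reactions", lambda e: e.date > build_date),
    })


def screen_with_snapshot(snapshot: SnapshotDatabase, record: PatientRecord,
                         catalog: Catalog, index: dt.datetime,
                         home_hospital: str = "CCH",
                         registry: dict[str, Hospital] | None = None) -> ScreenReport:
    """Code-stroke query path: snapshot lookup plus a live refresh over
    events recorded after the snapshot build (and the 24-h lab/imaging
    window).  The result is identical to a fresh ``screen_patient`` on
    the full record, up to the snapshot provenance stamp.

    A patient absent from the snapshot (e.g. no consent at build time)
    falls back to a full live screen.
    """
    if snapshot.build_time > index:
        raise ValueError("snapshot built after the index time")
    if record.patient_id in snapshot.matched and record.sharing_consent:
        base = snapshot.matched[record.patient_id]
        merged = _merge_events(base, record, snapshot.build_time.date())
        merged = PatientRecord.model_validate(merged.model_dump())
        report = screen_patient(merged, catalog, index, home_hospital, registry)
    else:
        report = screen_patient(record, catalog, index, home_hospital, registry)
    return report.model_copy(update={"snapshot_time": snapshot.build_time})


def save_snapshot(snapshot: SnapshotDatabase, path) -> None:
    from pathlib import Path
    Path(path).write_text(snapshot.model_dump_json(indent=1), encoding="utf-8")


def load_snapshot(path) -> SnapshotDatabase:
    from pathlib import Path
    return SnapshotDatabase.model_validate_json(Path(path).read_text(encoding="utf-8"))


def render_report(report: ScreenReport, catalog: Catalog) -> tuple[str, dict]:
    """Human-readable checklist plus a JSON document.

    TRIGGERED items cite evidence as ``Concept (HOSPITAL, year)``; the
    output is byte-stable for identical inputs so reports can be diffed.
    """
    lines = [
        f"Thrombolysis contraindication screen — patient {report.patient_id}",
        f"index time: {report.index_datetime.isoformat()}",
    ]
    if report.snapshot_time is not None:
        lines.append(f"snapshot: {report.snapshot_time.isoformat()}")
    status_tag = {
        Status.TRIGGERED: "TRIGGERED",
        Status.CLEAR: "clear",
        Status.NOT_EXTRACTABLE: "check on site",
    }
    for finding in sorted(report.findings, key=lambda f: f.item_id):
        rule = catalog.rule(finding.item_id)
        tag = status_tag[finding.status]
        if finding.status is Status.NOT_EXTRACTABLE and rule.on_site_note:
            tag = f"check on site: {rule.on_site_note}"
        lines.append(f"item {finding.item_id:>2}  [{tag}]  {rule.label}")
        for ev in finding.evidence:
            lines.append(f"           - {_format_evidence(ev)}")
    if report.advisories:
        lines.append("advisories (attention, not exclusion):")
        for label, evidence in sorted(report.advisories):
            cites = "; ".join(_format_evidence(e) for e in evidence)
            lines.append(f"  * {label}: {cites}")
    lines.append(f"recent labs (24 h): {len(report.recent_labs)}; "
                 f"recent imaging (24 h): {len(report.recent_imaging)}")
    text = "\n".join(lines) + "\n"
    doc = json.loads(report.model_dump_json())
    return text, doc


def _format_evidence(ev: Evidence) -> str:
    concept = ev.concept[:1].upper() + ev.concept[1:]
    return f"{concept} ({ev.hospital_id}, {ev.date.year})"
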