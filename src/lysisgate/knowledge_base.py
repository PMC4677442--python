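"""The contraindication catalog and its monotone rule language.

Thrombolysis with tPA is gated by 26 contraindication items; 17 of them
concern history that can be extracted from prior medical records (65 %),
the rest require on-site measurement (stroke-scale score, platelets,
glucose, blood pressure, ...).  Extractable items are encoded as
negation-free predicates — AND/OR trees over existence clauses — so that
rule evaluation is monotone: adding events to a record can only turn
findings on, never off.  That property is what makes a precomputed daily
snapshot safely mergeable with a live refresh.

Clauses match events by canonical concept label (case-insensitive) first
and optionally by (code system, code) pairs; the shipped default catalog
is label-based, with codes left user-configurable, because no
authoritative per-condition code list is bundled.
"""

from __future__ import annotations

import math
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    field_serializer,
    field_validator,
    model_validator,
)

from .ehr_model import CodeSystem

__all__ = [
    "Source",
    "Severity",
    "ConceptSet",
    "ExistsClause",
    "Exists",
    "AllOf",
    "AnyOf",
    "Predicate",
    "ContraindicationRule",
    "AdvisoryRule",
    "Catalog",
    "CatalogError",
    "default_catalog",
    "load_catalog",
    "save_catalog",
    "catalog_stats",
    "MEDICATION_RECENCY_DAYS",
]

#: "Current use" window for medication clauses with unlimited lookback: an
#: order counts if its interval overlaps the `MEDICATION_RECENCY_DAYS` days
#: before the index time, or is open-ended and started before it.  Covers
#: dispense gaps for chronic anticoagulation.
MEDICATION_RECENCY_DAYS = 30


class Source(str, Enum):
    DIAGNOSIS = "DIAGNOSIS"
    MEDICATION = "MEDICATION"
    ADR = "ADR"


class Severity(str, Enum):
    EXCLUSION = "EXCLUSION"
    ADVISORY = "ADVISORY"


class ConceptSet(BaseModel):
    """A named vocabulary bundle: condition/drug labels plus optional codes."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str = Field(min_length=1)
    labels: frozenset[str] = frozenset()
    codes: frozenset[tuple[CodeSystem, str]] = frozenset()

    @field_validator("labels", mode="after")
    @classmethod
    def _lower(cls, v: frozenset[str]) -> frozenset[str]:
        return frozenset(s.strip().lower() for s in v)

    @model_validator(mode="after")
    def _non_empty(self) -> "ConceptSet":
        if not self.labels and not self.codes:
            raise ValueError(f"concept set {self.name!r} has neither labels nor codes")
        return self

    @field_serializer("labels")
    def _ser_labels(self, v: frozenset[str]) -> list[str]:
        return sorted(v)

    @field_serializer("codes")
    def _ser_codes(self, v: frozenset) -> list[list[str]]:
        return sorted([cs.value, code] for cs, code in v)

    def matches_label(self, label: str) -> bool:
        return label.strip().lower() in self.labels

    def matches_code(self, code_system: CodeSystem, code: str) -> bool:
        return (code_system, code) in self.codes


class ExistsClause(BaseModel):
    """Does an event of this source, in this concept set, exist within the
    lookback window ending at the index time?  ``lookback_days=None`` means
    unlimited (any time in the record)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    source: Source
    concepts: ConceptSet
    lookback_days: Optional[int] = Field(default=None, ge=1)

    @field_validator("lookback_days", mode="before")
    @classmethod
    def _unlimited(cls, v):
        if isinstance(v, str) and v.lower() == "unlimited":
            return None
        return v


class Exists(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")
    exists: ExistsClause


class AllOf(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")
    all: tuple["Predicate", ...] = Field(min_length=1)


class AnyOf(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")
    any: tuple["Predicate", ...] = Field(min_length=1)


#: Negation-free predicate tree.  The absence of a NOT node is what makes
#: every rule monotone in the event set.
Predicate = Union[Exists, AllOf, AnyOf]

AllOf.model_rebuild()
AnyOf.model_rebuild()


def predicate_clauses(pred: Predicate) -> list[ExistsClause]:
    """Flatten a predicate tree to its existence-clause leaves."""
    if isinstance(pred, Exists):
        return [pred.exists]
    children = pred.all if isinstance(pred, AllOf) else pred.any
    out: list[ExistsClause] = []
    for child in children:
        out.extend(predicate_clauses(child))
    return out


class ContraindicationRule(BaseModel):
    """One numbered catalog item.

    ``extractable`` items carry a predicate over record events;
    non-extractable ones carry an ``on_site_note`` describing the bedside
    measurement instead (and are reported NOT_EXTRACTABLE by the screen).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    item_id: int = Field(ge=1, le=26)
    label: str = Field(min_length=1)
    severity: Severity = Severity.EXCLUSION
    extractable: bool
    predicate: Optional[Predicate] = None
    on_site_note: Optional[str] = None

    @model_validator(mode="after")
    def _predicate_iff_extractable(self) -> "ContraindicationRule":
        if self.extractable and self.predicate is None:
            raise ValueError(f"item {self.item_id}: extractable rule needs a predicate")
        if not self.extractable:
            if self.predicate is not None:
                raise ValueError(f"item {self.item_id}: non-extractable rule must not have a predicate")
            if not self.on_site_note:
                raise ValueError(f"item {self.item_id}: non-extractable rule needs an on_site_note")
        return self


class AdvisoryRule(BaseModel):
    """A record finding that warrants attention without excluding
    treatment (e.g. atrial fibrillation, dementia, heart failure)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    label: str = Field(min_length=1)
    predicate: Predicate


class CatalogError(ValueError):
    """Invalid catalog structure or configuration."""


class Catalog(BaseModel):
    model_config = ConfigDict(frozen=True)

    items: tuple[ContraindicationRule, ...]
    advisories: tuple[AdvisoryRule, ...] = ()

    @model_validator(mode="after")
    def _unique(self) -> "Catalog":
        ids = [r.item_id for r in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item_ids: {dupes}")
        labels = [a.label for a in self.advisories]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate advisory labels")
        object.__setattr__(self, "items", tuple(sorted(self.items, key=lambda r: r.item_id)))
        return self

    def rule(self, item_id: int) -> ContraindicationRule:
        for r in self.items:
            if r.item_id == item_id:
                return r
        raise KeyError(item_id)


def _dx(name: str, *labels: str, lookback_days: Optional[int] = None) -> Exists:
    return Exists(
        exists=ExistsClause(
            source=Source.DIAGNOSIS,
            concepts=ConceptSet(name=name, labels=frozenset(labels)),
            lookback_days=lookback_days,
        )
    )


def _extractable(item_id: int, label: str, pred: Predicate) -> ContraindicationRule:
    return ContraindicationRule(item_id=item_id, label=label, extractable=True, predicate=pred)


def _on_site(item_id: int, label: str, note: str) -> ContraindicationRule:
    return ContraindicationRule(item_id=item_id, label=label, extractable=False, on_site_note=note)


def default_catalog() -> Catalog:
    """The shipped 26-item contraindication catalog (17 extractable).

    Items 1, 3, 13, 15, 16 and 17 follow the documented semantics of the
    screening tool this package models: prior intracranial hemorrhage at
    any time; ischemic stroke within 90 days; significant liver disease;
    severe renal disease on hemodialysis; current oral anticoagulant use
    (warfarin, dabigatran or rivaroxaban, or any order tagged
    "anticoagulant"); and a known history of both diabetes and stroke.
    The remaining items are populated from standard tPA exclusion
    criteria so the catalog is complete; their numbering is a packaging
    convention and they are fully user-configurable (see
    docs/methods.md).
    """
    anticoagulant_clause = Exists(
        exists=ExistsClause(
            source=Source.MEDICATION,
            concepts=ConceptSet(
                name="oral anticoagulants",
                labels=frozenset({"warfarin", "dabigatran", "rivaroxaban", "anticoagulant"}),
            ),
            lookback_days=None,
        )
    )
    items = (
        _extractable(1, "Previous intracranial hemorrhage at any time",
                     _dx("intracranial hemorrhage", "intracranial hemorrhage",
                         "intracerebral hemorrhage")),
        _extractable(2, "Significant head trauma within 3 months",
                     _dx("head trauma", "head trauma", lookback_days=90)),
        _extractable(3, "Ischemic stroke within 3 months",
                     _dx("recent ischemic stroke", "ischemic stroke", lookback_days=90)),
        _extractable(4, "Major surgery within 14 days",
                     _dx("major surgery", "major surgery", lookback_days=14)),
        _extractable(5, "Gastrointestinal hemorrhage within 21 days",
                     _dx("gastrointestinal hemorrhage", "gastrointestinal hemorrhage",
                         lookback_days=21)),
        _extractable(6, "Urinary tract hemorrhage within 21 days",
                     _dx("urinary tract hemorrhage", "urinary tract hemorrhage",
                         lookback_days=21)),
        _extractable(7, "Arterial puncture at a noncompressible site within 7 days",
                     _dx("arterial puncture", "arterial puncture noncompressible site",
                         lookback_days=7)),
        _extractable(8, "Lumbar puncture within 7 days",
                     _dx("lumbar puncture", "lumbar puncture", lookback_days=7)),
        _extractable(9, "Myocardial infarction within 3 months",
                     _dx("myocardial infarction", "myocardial infarction", lookback_days=90)),
        _extractable(10, "Acute pericarditis",
                      _dx("pericarditis", "pericarditis", lookback_days=90)),
        _extractable(11, "Intracranial neoplasm",
                      _dx("intracranial neoplasm", "intracranial neoplasm", "brain tumor")),
        _extractable(12, "Intracranial arteriovenous malformation or aneurysm",
                      _dx("avm or aneurysm", "arteriovenous malformation",
                          "intracranial aneurysm")),
        _extractable(13, "Significant liver disease",
                      _dx("liver disease", "liver cirrhosis")),
        _extractable(14, "Known bleeding diathesis",
                      _dx("bleeding diathesis", "bleeding diathesis", "hemophilia")),
        _extractable(15, "Severe renal disease on hemodialysis (bleeding risk judged to outweigh benefit)",
                      _dx("hemodialysis", "hemodialysis")),
        _extractable(16, "Current oral anticoagulant use (warfarin, dabigatran, rivaroxaban)",
                      anticoagulant_clause),
        _extractable(17, "Known history of diabetes and stroke",
                      AllOf(all=(
                          _dx("diabetes", "diabetes", "diabetes mellitus"),
                          _dx("prior stroke", "ischemic stroke"),
                      ))),
        _on_site(18, "Severe stroke", "NIHSS > 25"),
        _on_site(19, "Thrombocytopenia", "platelet count <= 100,000/mm3"),
        _on_site(20, "Blood glucose out of treatable range", "blood glucose level"),
        _on_site(21, "Uncontrolled hypertension", "blood pressure > 185/110 mmHg"),
        _on_site(22, "Seizure at stroke onset", "witnessed seizure at onset"),
        _on_site(23, "Symptoms suggestive of subarachnoid hemorrhage",
                 "clinical assessment at presentation"),
        _on_site(24, "Rapidly improving or minor symptoms", "serial neurological examination"),
        _on_site(25, "Pregnancy", "pregnancy test / clinical assessment"),
        _on_site(26, "Onset beyond the treatment time window", "time of symptom onset"),
    )
    advisories = (
        AdvisoryRule(label="atrial fibrillation", predicate=_dx("atrial fibrillation", "atrial fibrillation")),
        AdvisoryRule(label="dementia", predicate=_dx("dementia", "dementia")),
        AdvisoryRule(label="heart failure", predicate=_dx("heart failure", "heart failure")),
    )
    return Catalog(items=items, advisories=advisories)


def load_catalog(path: str | Path, require_full_catalog: bool = True) -> Catalog:
    """Load a catalog from a YAML (or JSON) config file.

    The config has top-level ``items:`` and ``advisories:`` lists; predicate
    nodes are ``{all: [...]}``, ``{any: [...]}`` or
    ``{exists: {source, concepts, lookback_days}}`` with
    ``lookback_days: unlimited`` for open windows.  Schema violations —
    duplicate ids, an extractable item without a predicate, any
    unrecognized node such as a negation — are rejected with item-level
    messages.  With ``require_full_catalog`` the screening catalog must
    contain exactly 26 items.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise CatalogError("catalog config must be a mapping with 'items'")
    try:
        catalog = Catalog.model_validate(
            {"items": data.get("items", []), "advisories": data.get("advisories", [])}
        )
    except ValueError as exc:
        raise CatalogError(str(exc)) from exc
    if require_full_catalog and len(catalog.items) != 26:
        raise CatalogError(
            f"screening catalog must contain exactly 26 items, got {len(catalog.items)}"
        )
    return catalog


def save_catalog(catalog: Catalog, path: str | Path) -> None:
    """Serialize a catalog to YAML, round-trippable through load_catalog."""
    data = catalog.model_dump(mode="json", exclude_none=True)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def catalog_stats(catalog: Catalog) -> tuple[int, int, int]:
    """(n_items, n_extractable, pct_extractable) with the percentage
    rounded half-up to the nearest integer."""
    n = len(catalog.items)
    if n == 0:
        raise CatalogError("empty catalog")
    n_ex = sum(1 for r in catalog.items if r.extractable)
    pct = int(math.floor(100.0 * n_ex / n + 0.5))
    return n, n_ex, pct
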