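"""Screening semantics: reference case sets, windows, evidence, snapshot
merging and consent gating."""

import datetime as dt

import pytest

from lysisgate import (
    CohortSpec,
    DiagnosisEvent,
    LabResult,
    PatientRecord,
    Status,
    build_snapshot,
    evaluate_rule,
    generate_cohort,
    render_report,
    screen_patient,
    screen_with_snapshot,
)

EXPECTED_SETS = {
    "case-1": {3, 17},
    "case-2": {13, 15, 17},
    "case-3": {1},
    "case-4": {3, 16, 17},
}


def _case(records, n):
    return next(r for r in records if r.patient_id == f"case-{n}")


class TestEvaluateRule:
    def test_prior_hemorrhage_triggers_with_provenance(self, catalog, mock_cases):
        records, index = mock_cases
        finding = evaluate_rule(catalog.rule(1), _case(records, 3), index)
        assert finding.status is Status.TRIGGERED
        (ev,) = finding.evidence
        assert (ev.hospital_id, ev.date.year, ev.concept) == ("CCH", 2010, "intracranial hemorrhage")

    def test_old_stroke_outside_ninety_day_window_is_clear(self, catalog, mock_cases):
        records, index = mock_cases
        assert evaluate_rule(catalog.rule(3), _case(records, 2), index).status is Status.CLEAR

    def test_empty_record_is_clear_everywhere(self, catalog):
        empty = PatientRecord(patient_id="p", sharing_consent=True)
        index = dt.datetime(2014, 9, 1, 8)
        for rule in catalog.items:
            status = evaluate_rule(rule, empty, index).status
            assert status is (Status.NOT_EXTRACTABLE if not rule.extractable else Status.CLEAR)

    def test_window_boundary_is_closed(self, catalog):
        index = dt.datetime(2014, 9, 1, 8)
        on_edge = PatientRecord(patient_id="p", diagnoses=(DiagnosisEvent(
            patient_id="p", hospital_id="CCH", concept="ischemic stroke",
            date=dt.date(2014, 9, 1) - dt.timedelta(days=90)),))
        past_edge = PatientRecord(patient_id="p", diagnoses=(DiagnosisEvent(
            patient_id="p", hospital_id="CCH", concept="ischemic stroke",
            date=dt.date(2014, 9, 1) - dt.timedelta(days=91)),))
        assert evaluate_rule(catalog.rule(3), on_edge, index).status is Status.TRIGGERED
        assert evaluate_rule(catalog.rule(3), past_edge, index).status is Status.CLEAR

    def test_future_events_are_ignored(self, catalog):
        index = dt.datetime(2014, 9, 1, 8)
        future = PatientRecord(patient_id="p", diagnoses=(DiagnosisEvent(
            patient_id="p", hospital_id="CCH", concept="intracranial hemorrhage",
            date=dt.date(2014, 9, 2)),))
        assert evaluate_rule(catalog.rule(1), future, index).status is Status.CLEAR


class TestScreenPatient:
    def test_reference_case_sets(self, catalog, mock_cases):
        records, index = mock_cases
        for rec in records:
            report = screen_patient(rec, catalog, index)
            assert report.triggered_items() == EXPECTED_SETS[rec.patient_id], rec.patient_id
            assert len(report.findings) == 26
            assert "dementia" in {label for label, _ in report.advisories}

    def test_nine_findings_over_six_items(self, catalog, mock_cases):
        records, index = mock_cases
        reports = [screen_patient(r, catalog, index) for r in records]
        total = sum(len(r.triggered_items()) for r in reports)
        distinct = set().union(*(r.triggered_items() for r in reports))
        assert total == 9
        assert distinct == {1, 3, 13, 15, 16, 17}

    def test_case_4_anticoagulant_evidence_names_both_drugs(self, catalog, mock_cases):
        records, index = mock_cases
        report = screen_patient(_case(records, 4), catalog, index)
        item16 = next(f for f in report.findings if f.item_id == 16)
        assert {e.concept for e in item16.evidence} == {"warfarin", "rivaroxaban"}

    def test_consent_gating_yields_subset_of_findings(self, catalog, mock_cases):
        records, index = mock_cases
        for rec in records:
            private = rec.model_copy(update={"sharing_consent": False})
            gated = screen_patient(private, catalog, index).triggered_items()
            open_ = screen_patient(rec, catalog, index).triggered_items()
            assert gated <= open_

    def test_deterministic_rendering(self, catalog, mock_cases):
        records, index = mock_cases
        texts = {render_report(screen_patient(r, catalog, index), catalog)[0]
                 for r in records for _ in range(2)}
        assert len(texts) == 4  # byte-identical repeats collapse


class TestRecentResults:
    def test_24_hour_lab_window_boundaries(self, catalog):
        index = dt.datetime(2014, 9, 1, 8, 0)
        def lab(hours_before):
            return LabResult(patient_id="p", hospital_id="CCH", analyte="glucose",
                             value=100.0, units="mg/dL",
                             collected_at=index - dt.timedelta(hours=hours_before))
        rec = PatientRecord(patient_id="p", sharing_consent=True,
                            labs=(lab(25), lab(23)))
        report = screen_patient(rec, catalog, index)
        assert [l.collected_at for l in report.recent_labs] == [index - dt.timedelta(hours=23)]


class TestSnapshot:
    def test_snapshot_reproduces_reference_sets(self, catalog, mock_cases):
        records, index = mock_cases
        snap = build_snapshot(records, catalog, index)
        for rec in records:
            triggered = {f.item_id for f in snap.findings[rec.patient_id]}
            assert triggered == EXPECTED_SETS[rec.patient_id]

    def test_empty_build(self, catalog):
        snap = build_snapshot([], catalog, dt.datetime(2014, 9, 1))
        assert snap.findings == {} and snap.matched == {}

    def test_unconsented_patients_omitted(self, catalog, mock_cases):
        records, index = mock_cases
        private = [r.model_copy(update={"sharing_consent": False}) for r in records]
        snap = build_snapshot(private, catalog, index)
        assert snap.findings == {}

    def test_prior_day_snapshot_matches_fresh_screen(self, catalog, mock_cases):
        records, index = mock_cases
        snap = build_snapshot(records, catalog, index - dt.timedelta(days=1))
        for rec in records:
            merged = screen_with_snapshot(snap, rec, catalog, index)
            fresh = screen_patient(rec, catalog, index)
            assert merged.triggered_items() == EXPECTED_SETS[rec.patient_id]
            assert merged.equivalent_to(fresh)
            assert merged.snapshot_time == snap.build_time

    def test_snapshot_live_equivalence_on_random_cohort(self, catalog):
        """Snapshot + live refresh equals a fresh screen for 50 random
        patients whose events straddle the build time."""
        cohort = generate_cohort(CohortSpec(
            n_patients=50, seed=7, consent_rate=0.8,
            prevalence={"diabetes": 0.4, "ischemic stroke": 0.4, "dementia": 0.3,
                        "intracranial hemorrhage": 0.2, "hemodialysis": 0.2,
                        "liver cirrhosis": 0.2, "heart failure": 0.2,
                        "atrial fibrillation": 0.3},
            medication_prevalence={"warfarin": 0.3, "rivaroxaban": 0.2},
            start_date=dt.date(2013, 1, 1), end_date=dt.date(2014, 8, 31),
        ))
        index = dt.datetime(2014, 9, 1, 8)
        for build_days_back in (1, 60, 400):
            build = index - dt.timedelta(days=build_days_back)
            snap = build_snapshot(cohort, catalog, build)
            for rec in cohort:
                merged = screen_with_snapshot(snap, rec, catalog, index)
                fresh = screen_patient(rec, catalog, index)
                assert merged.equivalent_to(fresh), (rec.patient_id, build_days_back)

    def test_consent_granted_after_build_falls_back_to_live(self, catalog, mock_cases):
        records, index = mock_cases
        rec = _case(records, 2)
        private = rec.model_copy(update={"sharing_consent": False})
        snap = build_snapshot([private], catalog, index - dt.timedelta(days=1))
        assert rec.patient_id not in snap.findings
        report = screen_with_snapshot(snap, rec, catalog, index)
        assert report.equivalent_to(screen_patient(rec, catalog, index))

    def test_snapshot_after_index_rejected(self, catalog, mock_cases):
        records, index = mock_cases
        snap = build_snapshot(records, catalog, index + dt.timedelta(days=1))
        with pytest.raises(ValueError, match="after the index"):
            screen_with_snapshot(snap, records[0], catalog, index)


class TestRenderReport:
    def test_cites_evidence_in_table_notation(self, catalog, mock_cases):
        records, index = mock_cases
        text, doc = render_report(screen_patient(_case(records, 3), catalog, index), catalog)
        assert "Intracranial hemorrhage (CCH, 2010)" in text
        assert doc["patient_id"] == "case-3"

    def test_all_clear_report_shape(self, catalog):
        index = dt.datetime(2014, 9, 1, 8)
        report = screen_patient(PatientRecord(patient_id="p", sharing_consent=True),
                                catalog, index)
        text, doc = render_report(report, catalog)
        assert text.count("TRIGGERED") == 0
        assert text.count("check on site") == 9
        assert sum(1 for line in text.splitlines() if line.startswith("item ")) == 26
        parsed_statuses = {f["status"] for f in doc["findings"]}
        assert parsed_statuses == {"CLEAR", "NOT_EXTRACTABLE"}
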