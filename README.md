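# lysisgate

Contraindication screening for intravenous stroke thrombolysis over
multi-hospital electronic health records — plus the synthetic fixtures
and crossover-study analysis needed to evaluate such a tool end to end.

Intravenous tPA for acute ischemic stroke is highly time-critical and
restricted by a checklist of contraindications (prior intracranial
hemorrhage, recent stroke, anticoagulant use, ...). When the patient is
aphasic or confused, the relevant history is buried in records scattered
across hospitals. `lysisgate` is a screening engine for that problem,
aimed at clinical-informatics researchers and CDS developers:

* a **26-item contraindication catalog** (17 items extractable from
  records, 9 requiring bedside measurement) encoded in a negation-free
  AND/OR rule language over diagnosis/medication/ADR existence clauses
  with lookback windows — monotone by construction, YAML-configurable
  (`docs/schemas/catalog.schema.json`);
* a **screening engine** with consent-gated multi-hospital record
  access, full evidence provenance (`Intracranial hemorrhage (CCH,
  2010)`), a daily **snapshot database** and a live 24-hour refresh that
  is provably equivalent to a fresh screen;
* **bedside calculators**: NIHSS total (15-item instrument, 0–42) and
  weight-based tPA dosing (0.9 mg/kg, 90 mg cap, 10 % bolus);
* **synthetic EHR generation**: the four canonical mock cases (nine
  contraindications over six items) and randomized cohorts;
* the **crossover evaluation**: counterbalanced 12-physician /
  4-case assignment, per-arm summaries, and a test battery (pooled /
  Welch t, exact and asymptotic Mann-Whitney, chi-square with and
  without Yates correction).

## Worked example

```python
from lysisgate import default_catalog, make_mock_cases, screen_patient

catalog = default_catalog()          # 26 items, 17 extractable (65 %)
records, index = make_mock_cases()   # four mock patients, index 2014-09-01 08:00

for record in records:
    report = screen_patient(record, catalog, index)
    print(record.patient_id, sorted(report.triggered_items()))
```

prints

```
case-1 [3, 17]
case-2 [13, 15, 17]
case-3 [1]
case-4 [3, 16, 17]
```

— nine triggered findings over six distinct items: case 1 had a stroke
60 days before the index (item 3, 90-day window) and a diabetes-plus-
stroke history (item 17); case 2 has liver cirrhosis, hemodialysis and
item 17; case 3 a 2010 intracranial hemorrhage (item 1, any time); case
4 a recent stroke, open-ended warfarin and rivaroxaban orders (item 16)
and item 17. Replaying the recorded evaluation counts:

```python
from lysisgate.evaluation import replay_published_counts
control, intervention, tests = replay_published_counts()
print(control.display())       # {'total_missed': 23, 'pct_missed': 42.6, ...}
print(intervention.display())  # {'total_missed': 7,  'pct_missed': 13.0, ...}
print(round(tests["per_item_t"].statistic, 3))  # 2.263
```

With the screening tool, physicians missed 7 of 54 contraindication
opportunities (13.0 %) instead of 23 (42.6 %) — significant by t,
Mann-Whitney and chi-square.

The `examples/` directory holds one short script per capability
(screening, snapshot workflow, cohorts and consent, study replay, study
simulation, bedside calculators); each prints its numbers with a line on
what they mean. A thin CLI wraps the same functions:
`lysisgate screen|build-db|dose|fixtures|cohort|simulate-study|replay`.

## Layout

```
src/lysisgate/        ehr_model, knowledge_base, screener, bedside,
                      synthetic_ehr, evaluation (design, stats), cli
tests/                unit, property (hypothesis) and acceptance suites
examples/             narrative scripts, one per capability
docs/methods.md       model, assumptions, parameters, limitations
docs/schemas/         JSON-Schema for the catalog config and screen report
```
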