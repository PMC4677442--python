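# Methods

`lysisgate` models a clinical-decision-support workflow for intravenous
stroke thrombolysis in a multi-hospital health system with a shared
electronic medical record: when a code stroke is activated, the engine
screens the patient's cross-hospital history against a catalog of
treatment contraindications and reports each item as TRIGGERED (with
evidence), CLEAR, or NOT_EXTRACTABLE (requires bedside measurement).
Alongside the screening engine the package ships the synthetic fixtures
and the crossover-study analysis used to evaluate such a tool.

## The rule model

A contraindication catalog contains 26 numbered items, of which 17
(65 %) concern pre-stroke history extractable from records; the other 9
carry an `on_site_note` (NIHSS > 25, platelet count, glucose, blood
pressure, ...) and are never decided by the engine. Extractable items
are encoded in a deliberately small, **negation-free** predicate
language: AND/OR trees whose leaves assert the existence of a diagnosis,
medication, or adverse-drug-reaction event in a concept set, optionally
within a lookback window. Absence of a NOT node makes every rule
monotone in the event set — adding information can only turn findings
on. Monotonicity is what licenses the snapshot/live merge below and is
enforced structurally (an unknown `not:` node fails config validation)
and verified by property tests with random predicates and event sets.

Concept matching is by canonical lowercase label first, with optional
(code system, code) pairs as configurable secondary keys. The shipped
catalog is label-based using the condition vocabulary of the reference
mock cases (atrial fibrillation, dementia, diabetes, heart failure,
hemodialysis, ischemic stroke, intracranial hemorrhage, liver
cirrhosis) plus the oral anticoagulants warfarin, dabigatran and
rivaroxaban; no authoritative ICD code lists are bundled, since those
are site-specific IT policy rather than portable knowledge.

Semantics of the six documented items:

| item | rule | window |
|------|------|--------|
| 1 | prior intracranial hemorrhage | unlimited |
| 3 | ischemic stroke within 3 months | 90 days |
| 13 | significant liver disease (matches liver cirrhosis) | unlimited |
| 15 | severe renal disease on hemodialysis | unlimited |
| 16 | current oral anticoagulant use (named drugs or the `anticoagulant` class tag) | 30-day recency, see below |
| 17 | known history of diabetes AND stroke | both legs unlimited |

The remaining items (2, 4–12, 14, 18–26) complete the 26/17 split from
standard tPA exclusion criteria (recent head trauma, major surgery, GI
or urinary hemorrhage, noncompressible arterial puncture, lumbar
puncture, recent myocardial infarction, pericarditis, intracranial
neoplasm, AVM/aneurysm, bleeding diathesis, and the nine on-site
criteria). Their numbering and contents are a packaging convention of
this catalog, are fully user-configurable via the YAML config
(`docs/schemas/catalog.schema.json`), and are never relied on by the
fixture-driven tests.

**Windows.** A clause with lookback W matches events dated in the closed
interval [index − W days, index]; the "3 months" criterion is fixed at
90 days for determinism. Events dated after the index are ignored
entirely. Medication clauses use interval overlap: an order matches if
[start, stop] (open stop = still taking) overlaps [index − W, index],
with W = 30 days (`MEDICATION_RECENCY_DAYS`) when the clause's lookback
is unlimited — "current use" tolerant of dispense gaps. All timestamps
are naive local time (single-region system); item-level dates are
calendar dates.

**Advisories.** Atrial fibrillation, dementia and heart failure are
reported as advisories — findings that warrant attention (anticoagulation
risk, advanced-dementia judgement) without themselves excluding
treatment; only the advanced forms would exclude, and those are not
record-decidable.

## Consent gating and the snapshot database

Records carry a sharing-consent flag. Without consent, only events from
the treating (home) hospital are visible; the restriction is idempotent
and never adds events, so gated findings are always a subset of the
consented screen (tested as a property).

The production pattern this models builds a screening database nightly
and queries it at alarm time, supplemented by a live pass over the last
24 hours. `SnapshotDatabase` therefore stores, per consented patient,
(a) the TRIGGERED findings as of the build (for instant display) and
(b) a clause-level **match index**: every event that matched any rule or
advisory clause at build time. The match index — not just the triggered
findings — is required for exact merging: a conjunction such as item 17
may have one leg satisfied years before the build and the other arriving
after it, and the pre-build leg would be unrecoverable from triggered
findings alone. Correctness rests on a containment argument: clause
windows end at the query index ≥ build time, so any pre-build event that
matches a clause at query time already matched it at build time.
Consequently `screen_with_snapshot` (match index ∪ events dated after
the build, evaluated at the query index) is exactly equivalent to a
fresh `screen_patient` on the full record; the equivalence is asserted
over random 50-patient cohorts with build times 1–400 days before the
index, and reports are byte-stable for diffing. Labs and imaging are
always taken from the live record within the closed 24-hour window
before the index.

## Synthetic data

`make_mock_cases` emits the four canonical evaluation fixtures: four
multi-hospital patients carrying, between them, nine extractable
contraindications over six distinct items ({3,17}, {13,15,17}, {1},
{3,16,17}), each with a dementia history and sharing consent. The source
material dates events only by year, so dating is deterministic: the
index is 2014-09-01 08:00, "stroke in 3 months" entries are dated
index − 60 days (inside item 3's 90-day window), every other entry
July 1 of its year (the 2009–2012 strokes fall safely outside the
window), and the warfarin/rivaroxaban orders are open-ended from
2014-07-01. Every table cell appears exactly once as an event.

`generate_cohort` draws reproducible cohorts: per-concept Bernoulli
prevalences, events uniform over a date range, 1–7 hospitals per
patient, and a consent rate. It intentionally omits comorbidity
correlation, realistic code distributions and free-text — it exists to
exercise the engine's invariants at scale, so passing tests demonstrate
the screening logic, not epidemiological realism.

`simulate_responses` is the stand-in for physician behavior in the
crossover evaluation: each contraindication opportunity is missed
independently with the arm's probability (defaults 0.426 control /
0.130 intervention, the observed rates 23/54 and 7/54), and per-case
review times are log-normal with per-case means of half the observed
per-session values (14.6 ± 7.4 and 7.3 ± 5.2 minutes per two-case
session). Times are simulation realism only: human review speed is not
a computable target, and no test asserts it.

## The crossover evaluation

The study design is a fixed-sequence two-period crossover: 12
physicians each screen two cases without the tool and two different
cases with it, counterbalanced so each of the 4 cases appears exactly
6 times per arm — 6 × 9 = 54 contraindication opportunities per arm.
`counterbalanced_assignment` cycles the six ordered pair-splits of the
case set (requiring physician count divisible by 6); the unseeded
(12, 4) layout reproduces the reference assignment, and seeded variants
shuffle physicians while preserving balance exactly (validator-checked).

`summarize_arm` reports totals, percentage of opportunities, and
per-item / per-physician mean, sample SD (n − 1) and median, at full
precision with a separate half-up 1-decimal display view matching the
reference tables. Replaying the recorded per-item counts ([2,6,5,2,1,7]
vs [0,1,1,1,0,4]) gives 23 (42.6 %) vs 7 (13.0 %), per-item 3.8 ± 2.5
(median 3.5) vs 1.2 ± 1.5 (median 1.0), per-physician means 1.9 and 0.6.
Only the per-item margins of the source data are unambiguous, so
per-physician SDs and medians are computed only when individual
responses exist (e.g. from the simulator) and are never asserted against
the reference values.

The test battery: unpaired t (pooled variance by default — it reproduces
the reference per-item significance, t = 2.263, df 10, p ≈ 0.047; Welch
available), Mann-Whitney U, and chi-square on the 2 × 2 of missed vs
caught opportunities ([[23,31],[7,47]] → 11.82 uncorrected, 10.38 with
Yates, p ≈ 0.001 either way; both variants reported since small-cell
practice varies). t and chi-square are computed via scipy and verified
against closed-form oracles to 1e-10 in tests. The EXACT Mann-Whitney
is a full enumeration of all C(n₁+n₂, n₁) group assignments with
mid-ranks for ties and a symmetric two-sided tail — implemented here
because off-the-shelf exact methods decline tied data — limited to
combined n ≤ 20, and cross-checked in tests against an independent
exhaustive permutation oracle and, on tie-free data, against the
standard exact distribution; the tie-corrected normal approximation
with continuity correction is the large-sample path.

Known analysis limitations, inherited deliberately from the replayed
design: carryover/period effects are not modeled, and the chi-square
treats the 54 opportunities per arm as independent although they
cluster within physicians.

## Numerical and interface choices

* Display rounding is decimal half-up to 1 decimal; JSON outputs keep
  full precision. The extractable percentage is half-up to an integer.
* Evidence is ordered (date, hospital, concept) and deduplicated, so
  rendered reports are deterministic byte-for-byte.
* Degenerate analyses (zero-miss studies, zero-variance samples, zero
  marginals) return flagged, skipped test results from `analyze_study`
  rather than raising; the low-level test functions raise instead.
* Dose: total = min(0.9 × weight, 90) mg rounded to 0.1 mg, 10 % bolus;
  rounding to vial-practical increments is left to local policy.
* JSONL I/O preserves unknown fields, sorts keys and events, and is an
  exact round-trip on validated records (property-tested). Problem sizes
  in the test suite (50-patient equivalence cohorts, 2000-replicate
  Monte-Carlo recovery) were chosen as the smallest that pin the
  invariants with comfortable statistical margins.
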