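"""Screen the four canonical mock cases against the default catalog.

Builds the fixtures in memory, screens each patient at the code-stroke
index time, and prints the triggered contraindication items with their
evidence.  Expect 9 triggered findings over 6 distinct items:
{3,17}, {13,15,17}, {1} and {3,16,17}.
"""

from lysisgate import default_catalog, make_mock_cases, render_report, screen_patient

catalog = default_catalog()
records, index = make_mock_cases()

total, distinct = 0, set()
for record in records:
    report = screen_patient(record, catalog, index)
    items = sorted(report.triggered_items())
    total += len(items)
    distinct |= set(items)
    print(f"{record.patient_id}: triggered items {items}, "
          f"advisories {[label for label, _ in report.advisories]}")

print(f"\n{total} triggered findings over {len(distinct)} distinct items\n")

# full checklist for one case, in the evidence notation "Concept (HOSP, year)"
text, _ = render_report(screen_patient(records[2], catalog, index), catalog)
print(text)
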