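"""Replay the recorded crossover evaluation from its per-item counts.

The evaluation compared 12 physicians screening mock cases with and
without the decision-support tool, 54 contraindication opportunities per
arm.  Replaying the per-item missed counts ([2,6,5,2,1,7] control,
[0,1,1,1,0,4] intervention) reproduces the study's summary table and
test battery.
"""

from lysisgate.evaluation import replay_published_counts

control, intervention, tests = replay_published_counts()

for summary in (control, intervention):
    d = summary.display()
    print(f"{summary.arm:>12}: missed {d['total_missed']}/54 ({d['pct_missed']}%), "
          f"per-item {d['per_item_mean']} +/- {d['per_item_sd']} "
          f"(median {d['per_item_median']}), "
          f"per-physician mean {d['per_physician_mean']}")

print()
for name, t in tests.items():
    print(f"{name:>26}: statistic {t.statistic:7.3f}  p {t.p_value:.4f}")

print("\nThe tool cut missed contraindications from 23 (42.6%) to 7 (13.0%) of 54;")
print("all three tests agree the reduction is statistically significant.")
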