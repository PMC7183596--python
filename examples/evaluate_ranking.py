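"""Evaluate how well the combined score ranks decoys within each target.

Generates synthetic pools, scores them with the published weights, and
reports the standard model-selection metrics: per-target Pearson correlation
of the negated score with GDT-TS, the quality of the top-ranked model, the
best quality among the top five, and selection Z-scores computed against
each pool's population spread.
"""

from poorqa.evaluation import evaluate
from poorqa.scoring import PUBLISHED_WEIGHTS
from poorqa.synthetic import FixtureSpec, make_decoy_pools

pools = make_decoy_pools(FixtureSpec(n_targets=8, decoys_per_target=120,
                                     seed=5))
report = evaluate(pools, PUBLISHED_WEIGHTS)

print(f"{'target':<8}{'corr(-E,GDT)':>14}{'top1 GDT':>10}"
      f"{'best-of-5':>11}{'Z(top1)':>9}")
for tid, entry in sorted(report.per_target.items()):
    corr = "n/a" if entry.pearson_gdt is None else f"{entry.pearson_gdt:.3f}"
    print(f"{tid:<8}{corr:>14}{entry.top1_quality:>10.2f}"
          f"{entry.best_of_top5_quality:>11.2f}{entry.z_top1:>9.2f}")

print(f"\nmean correlation: {report.mean_pearson_gdt:.3f}")
print(f"mean top-1 GDT-TS: {report.mean_top1_quality:.2f}")
print(f"Z-score sums: top1 {report.z_sum_top1:.2f}, "
      f"best-of-5 {report.z_sum_best5:.2f}")
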