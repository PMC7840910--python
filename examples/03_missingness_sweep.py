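"""Missing-data threshold sweep on a 65-sample cohort in which 28 samples
exceed 90% missing SNPs.

Each row retains samples at or below the missingness threshold, rebuilds a
TN93/NJ tree with bootstrap supports, and reports mean internal support
plus the Robinson-Foulds distance to the previous row's tree. The starred
threshold is the most inclusive one within 2 support points of the best.
"""
import math

from mitoshell.phylo import missingness_sweep
from mitoshell.simulate import sweep_benchmark_cohort

matrix, groups = sweep_benchmark_cohort(seed=1)
report = missingness_sweep(matrix, n_reps=50, seed=0)

print("threshold  retained  mean_support  RF_to_prev")
for row in report.rows:
    ms = "-" if math.isnan(row.mean_support) else f"{row.mean_support:.1f}"
    rf = "-" if math.isnan(row.rf_to_previous) else f"{row.rf_to_previous:.0f}"
    star = " *" if row.threshold == report.selected_threshold else ""
    print(f"{row.threshold:<10} {row.n_retained:<9} {ms:<13} {rf}{star}")

print(f"\nselected threshold: {report.selected_threshold}% "
      "(support stabilises once the worst samples are excluded; "
      "the 90% row keeps 37 of 65 samples)")
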