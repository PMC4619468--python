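"""Single-feature threshold classification with a full ROC sweep.

Draws a 36-subject disease/control cohort from the preset feature
distributions, sweeps every candidate stride-length threshold, and prints
the accuracy-optimal cut with its sensitivity and specificity.  Subjects
below the threshold are classified as the disease (positive) class.
"""

from kinegait import roc_sweep, simulate_cohort
from kinegait.simulate import default_cohort

spec = default_cohort()
spec.groups = {k: v for k, v in spec.groups.items() if k != "STUD"}
table = simulate_cohort(spec, seed=7, mode="features").feature_table

y = (table.group == "PD").astype(int).to_numpy()
for column, unit in (("sl_m", "m"), ("gv_mps", "m/s")):
    sweep = roc_sweep(table[column].to_numpy(), y, "lower_is_positive")
    m = sweep.optimal_metrics
    print(
        f"{column:7s} optimal threshold {sweep.optimal_threshold:.3f} {unit}: "
        f"accuracy {100 * m.accuracy:.1f}%  "
        f"SE {100 * m.sensitivity:.1f}%  SP {100 * m.specificity:.1f}%"
    )
# Stride length separates the groups better than gait velocity: its
# distributions overlap less, so the optimal cut misclassifies fewer
# subjects (the population-level optima sit near 0.46 m and 0.72 m/s).
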