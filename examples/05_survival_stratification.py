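"""Four-group expression-stratified survival analysis.

Samples are split at the cohort median of a protein-coding gene (PCG) and a
lncRNA: group 1 = both high, 2 = PCG high only, 3 = lncRNA high only,
4 = both low.  Kaplan-Meier curves are estimated per group and compared with
a 3-degree-of-freedom log-rank test.  The synthetic cohort plants a hazard
gradient from group 1 (worst) to group 4 (best).
"""

from lncscreen import survival_by_expression_groups
from lncscreen.synthetic import generate_survival

records = generate_survival(
    n_per_group=80,
    hazards={1: 0.40, 2: 0.20, 3: 0.10, 4: 0.05},
    censor_rate=0.15,
    seed=11,
    with_expression=True,
)
res = survival_by_expression_groups(records)

print("median survival per group (product-limit estimate):")
for g in (1, 2, 3, 4):
    curve = res["curves"][g]
    n = int((res["groups"] == g).sum())
    print(f"  group {g} (n={n:3d}): median = {curve.median:6.2f}")

test = res["logrank"]
print(f"\nlog-rank: chi^2 = {test.chi_square:.2f} on {test.df} df, p = {test.p:.3g}")
print(
    "\nGroup 1 (both RNAs above the median) carries the highest hazard and"
    " the shortest median survival — the pattern expected when the two RNAs"
    " jointly mark aggressive disease."
)
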