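"""Moderated differential expression on simulated knockout counts.

Generates negative-binomial counts for a wild-type vs knockout design with
one gene planted at a 4-fold (log2FC = 2) increase, then runs the standard
chain: log2(x+1) transform, quantile normalization, empirical-Bayes
moderated t, BH-FDR, and threshold selection.
"""

from lncscreen import (
    Contrast,
    ThresholdRule,
    apply_thresholds,
    fit_de,
    log2_transform,
    quantile_normalize,
)
from lncscreen.synthetic import generate_counts, generate_genomes

ann, _, _, _ = generate_genomes(
    n_coding=300, n_lnc=0, n_planted=0, seed=1,
    conserved_decoy_frac=0.0, single_side_decoy_frac=0.0,
)
planted = {"A_cod00000": [0.0, 2.0]}  # 4-fold up in the knockout group
expr = generate_counts(ann, "two_group", planted_log2fc=planted, seed=2)

prepared = quantile_normalize(log2_transform(expr))
table = fit_de(prepared, Contrast("ko_over_wt", "ko", "wt"), method="moderated")
selected = apply_thresholds(table, ThresholdRule(1.5, 0.05, "raw_p"))

row = table.loc["A_cod00000"]
print(f"planted gene: log2FC={row['log2fc']:.2f}  t={row['t_mod']:.2f}  "
      f"p={row['p']:.2e}  q={row['q']:.2e}")
print(f"selected genes at (FC >= 1.5, p < 0.05): {len(selected)} of {len(table)}")
print(f"planted gene selected: {'A_cod00000' in selected.index} "
      f"({selected.loc['A_cod00000', 'direction'] if 'A_cod00000' in selected.index else '-'})")
print(
    "\nThe moderated t shrinks per-gene variances toward an empirical-Bayes"
    " prior, stabilising inference at n = 3 per group; the planted 4-fold"
    " change stands far above the 1.5x cut-off."
)
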