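# Methods

This note documents the models and procedures implemented in `lncscreen`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Coordinates and formats

All genomic intervals are 0-based half-open `[start, end)` internally, so
length = end − start and the gap arithmetic matches BED/bedtools
conventions. GTF (1-based inclusive) converts on read and write. Strands
other than `+`/`-` are rejected rather than guessed — orientation
classification is meaningless without a strand — with rejected records
counted per file. Biotype strings map onto three internal labels
(`coding`, `lncRNA`, `other`) through a configurable dictionary whose
default covers the Gencode `gene_type` vocabulary; unknown strings become
`other` and are excluded from pairing. One interval per gene: isoform
structure is out of scope.

## Neighbour pairing

A coding gene and a lncRNA pair when the number of bases strictly between
their intervals (0 if they overlap or abut) is at most the window,
**100 000 bp by default and inclusive at the boundary**. Distance is the
inter-interval gap rather than TSS-to-TSS because the screen operates on
gene intervals, as a bedtools-window run would; TSS-to-TSS is available as
an alternative anchor (`anchor="tss"`), and overlapping genes are eligible
as neighbours. Pairing is many-to-many with no nearest-only reduction
(a `nearest_only` flag exists for sensitivity analyses). Window queries run
against an interval tree; tests compare the output against a brute-force
all-pairs oracle and against `bedtools window`.

Orientation classes for a pair on one chromosome:

* overlapping intervals → `antisense_overlap` / `sense_overlap` by strand;
* disjoint, same strand → `tandem`;
* disjoint, opposite strands → `divergent` when the left gene is on `-`
  and the right on `+` (the two 5′ ends face each other across the gap,
  the head-to-head bidirectional-promoter arrangement), else `convergent`.

Because "divergent lncRNA" is often used loosely for any opposite-strand
neighbour, the filter accepts an `opposite_strand` alias covering
{divergent, convergent, antisense_overlap}. The default cascade does not
filter on orientation.

## Conservation join

lncRNA conservation is **positional only**: an A-pair and a B-pair form a
candidate when their coding genes are orthologous. One-to-many orthology
expands to all combinations (no best-hit reduction — downstream expression
filters prune, and any tie-breaking rule would be arbitrary). Ortholog
entries naming coding genes absent from either pair set are skipped with a
logged count. Universe accounting reports distinct coding and lncRNA genes
per species among candidates.

## Expression statistics

**Transform.** Counts are log2(x+1)-transformed before normalization and
testing. **Quantile normalization** forces every sample onto the per-rank
across-sample means; within a column, tied values receive the mean of the
reference values over the tied rank span. Both species are normalized by
default (`normalize` accepts `both|a|b|none`). Idempotence holds exactly
for tie-free data; with ties the tie-averaging rule makes repeated
application contractive rather than exactly idempotent, which is why the
contract tests use continuous data. Quantile normalization needs a
non-trivial number of genes; on near-degenerate matrices (a handful of
genes) it flattens real differences and should be disabled.

**Moderated t.** Per gene, log2FC is the difference of group means and
s²_g the pooled within-group variance on d_g = n₁+n₂−2 df. The prior
(d₀, s₀²) is estimated once per fit by moment matching of
e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the excess of the sample variance
of e over the chi-square sampling term ψ′(d_g/2) is inverted through the
trigamma function (Newton iteration); when the excess is non-positive,
d₀ = ∞ and s₀² is the arithmetic mean of the variances (the moment
estimate under pure chi-square sampling). Zero-variance genes are excluded
from prior estimation but still receive a positive posterior variance
through s₀². The total df d_g + d₀ is capped at the pooled residual df
across genes when the prior was estimated from the same matrix — an
internally estimated prior cannot carry more information than the data it
came from; a user-supplied prior is used uncapped. p-values are two-sided
from t(d_g+d₀) (normal when infinite). The implementation agrees with the
reference R implementation (limma) to ~1e-5 on shared inputs; that
comparison lives in the tests, never in the pipeline. On an all-constant
matrix no prior is estimable and the fit falls back to the ordinary path,
whose conventions are: zero variance with zero difference → p = 1, zero
variance with a difference → p = 0.

**Multiple testing** is Benjamini–Hochberg step-up
(q_(i) = min_{j≥i} p_(j)·m/j, capped at 1), the default FDR adjustment of
the field's DE tooling, computed within one contrast and within one gene
class. **Threshold rules** combine |log2FC| ≥ log2(min fold change) —
inclusive by default, a `strict` flag exists because "exceeding 1.5x" can
be read either way — with q < α (`fdr` scale) or p < α (`raw_p` scale).

## The selection cascade

Stage order is fixed: pair per species → conservation join (universe
accounting) → species-A filter → map survivors to species B → species-B
filter. Differential expression in species A runs **separately on the
universe's coding genes and on its lncRNAs** (each class gets its own BH
correction), per successive-stage contrast (stage2/stage1, stage3/stage2,
stage4/stage3 by default). Two deliberately exposed ambiguities:

* `de_combination` — `any_contrast` (default) requires the pair to pass in
  at least one transition; `all_contrasts` in every transition. Any-of is
  the default because a monotonically increasing gene is genuinely
  progression-associated yet can fail a middle transition.
* `pair_constraint` — `same_contrast` (default) requires the coding gene
  and lncRNA to pass in a **common** contrast, the natural reading of
  "within 100 kb of each other when comparing the same pairs of cells";
  `independent` only requires each to pass somewhere.

Genes present in the annotation but missing from an expression matrix are
dropped from the screen with a logged count, never an error. Soundness
(every final candidate independently satisfies orthology, both windows and
both rules) and completeness (equality with a filter-everything brute
force) are tested properties.

## Clinical scoring

The composite stain score is intensity (0–1) × percent positive tissue
(0–100), bounded in [0, 100]; localization summaries compute per-sample
cytoplasmic share 100·cyt/(cyt+nuc) of the compartment composite scores,
then average within tissue class, excluding zero-signal samples with a
warning. The four-group split uses strict `>` against each RNA's cohort
median (a value exactly at the median is "low"), numbering: 1 both high,
2 PCG high only, 3 lncRNA high only, 4 both low. For tissue cohorts whose
high/low cut-point is not prescribed, the median composite score is the
default.

Kaplan–Meier: S(t) = Π_{tᵢ≤t}(1 − dᵢ/nᵢ) over distinct event times, with
events processed before censorings at tied times; with no censoring the
curve equals the empirical survival function exactly. The K-group log-rank
statistic is (O−E)ᵀV⁻(O−E) over K−1 groups with the hypergeometric
variance d(n−d)/(n−1)·(diag(nᵢ/n) − (nᵢ/n)(nᵢ/n)ᵀ) summed over event
times; V⁻ is a pseudo-inverse so degenerate groups do not crash the test,
and the reference is χ²(K−1). A cohort with no events yields p = 1 with a
warning. Cox regression and hazard ratios are out of scope.

## Synthetic data

The generator lays loci sequentially with a guard gap of window+1 bases, so
the only within-window coding/lncRNA pairs are the intended ones: planted
conserved pairs (nearby lncRNA in both species, joint expression effects),
conserved decoys (same structure, null expression — they populate the
candidate universe and must be eliminated by the DE filters), single-side
decoys (eliminated by the join), and isolated genes (eliminated by
pairing). Planted gaps are uniform on [0, window]; orientations are
sampled over all five classes and shared across species (a conserved locus
keeps its arrangement); gene lengths are uniform (coding 5–30 kb, lncRNA
1–10 kb).

Counts are negative binomial with variance μ + φμ². Defaults, chosen as
typical of bulk RNA-seq of cell-line material: base mean 300 (a moderately
expressed gene), dispersion φ = 0.1, 3 replicates per group, planted
|log2FC| = 2. Non-planted genes draw a group-constant baseline log-normally
(σ = 0.8 on the natural log) around the base mean — baseline spread
matters, because quantile normalization distorts effect sizes when
perturbed genes are isolated rank outliers in an otherwise constant-mean
matrix. Both members of a planted pair share sign and onset transition
(divergent neighbours are co-regulated); effects are cumulative from the
onset stage, with a 30% chance of a second later step, so planted genes
are differential in one or more successive transitions — deliberately
exercising the any/all contrast ambiguity. The species-B effect reuses the
pair's sign and magnitude.

Stain intensities are Beta-distributed per tissue class with
clipped-normal proportions; compartment splits are Beta around the planted
cytoplasmic fraction. Survival times are exponential per group with
independent exponential censoring calibrated to the requested marginal
censoring probability.

Three bundled scenarios: `tiny` (3 planted pairs, ~60 genes/species, for
examples and determinism checks), `default` (12 planted pairs among 2000
decoy genes per species — the benchmark condition), `stress` (36 planted,
~6000 genes, with ortholog noise). Everything is reproducible from
(parameters, seed); per-stage seeds derive from one global seed through
`numpy.random.SeedSequence.spawn`.

**What the benchmark does not show.** The generator emulates the study
*design*, not real transcriptomes: no batch effects, no library-size or
GC biases, no correlated gene modules, ideal orthology, one interval per
gene, and guard gaps that make pairing unambiguous. Passing the planted
recovery benchmark demonstrates that the pipeline's logic and statistics
behave as specified under controlled conditions — not that real screens
will reach the same recall, and the original screens' dataset-specific
counts are not reproducible without their raw sequencing data.

## Problem sizes used in the checks

The acceptance checks run the screen over 20 seeds of the default scenario
(~2 s per seed), calibrate the null on 10 000 genes, use 500 replicates
for the BH simulation, 1000 for log-rank size at n = 50/group and 200 for
power at n = 100/group — sizes at which the Monte-Carlo standard errors
are comfortably below the tolerances being asserted.

## Known limitations

Two-group contrasts only (no multi-factor linear models, no count-weighted
moderation); quantile normalization is unsuitable for very small gene
sets; the log-rank chi-square reference is asymptotic and mildly liberal
at small samples; the interval model ignores isoforms, so a gene's TSS is
a single point; orthology must be supplied, never inferred.
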