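"""The cross-species selection cascade.

Pipeline order is fixed:

1. pair coding genes with lncRNA neighbours within the window, per species;
2. join the two pair sets through coding-gene orthology (the conserved
   candidate universe, with distinct-gene accounting per species);
3. species-A differential filter: per progression contrast, moderated DE is
   run separately on the universe's coding genes and on its lncRNAs; a
   candidate survives when its coding gene and lncRNA both pass the species-A
   threshold rule (by default in at least one common contrast);
4. survivors are mapped to their species-B coding genes and neighbouring
   lncRNAs;
5. species-B differential filter on both members of each candidate.

Counts at every stage are recorded in :class:`StageCounts`; within each
species/gene-class chain they are non-increasing by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Literal, Sequence

import pandas as pd

from ._util import atomic_open, logger
from .conservation import ConservedCandidate, join_conserved, summarize_universe
from .destats import (
    Contrast,
    ThresholdRule,
    apply_thresholds,
    fit_de,
    log2_transform,
    quantile_normalize,
)
from .io_formats import CODING, LNCRNA, AnnotationSet, ExpressionMatrix, OrthologMap
from .pairing import GenePair, pair_within_window


@dataclass(frozen=True)
class ScreenConfig:
    """All knobs of the screen; defaults are the canonical cut-offs
    (100 kb window; species A: fold change 1.5x at FDR 0.1; species B:
    fold change 1.5x at raw p < 0.05)."""

    window_bp: int = 100_000
    rule_a: ThresholdRule = field(default_factory=lambda: ThresholdRule(1.5, 0.1, "fdr"))
    rule_b: ThresholdRule = field(default_factory=lambda: ThresholdRule(1.5, 0.05, "raw_p"))
    contrasts_a: tuple[Contrast, ...] | None = None  # None: successive design groups
    contrast_b: Contrast | None = None  # None: second design group over first
    de_combination: Literal["any_contrast", "all_contrasts"] = "any_contrast"
    pair_constraint: Literal["same_contrast", "independent"] = "same_contrast"
    de_method: Literal["moderated", "ordinary"] = "moderated"
    input_scale: Literal["counts", "log2"] = "counts"
    normalize: Literal["both", "a", "b", "none"] = "both"
    distance_anchor: Literal["gap", "tss"] = "gap"
    nearest_only: bool = False


@dataclass
class StageCounts:
    """Distinct-gene accounting at every cascade stage."""

    universe_coding_a: int = 0
    universe_ncrna_a: int = 0
    universe_coding_b: int = 0
    universe_ncrna_b: int = 0
    de_coding_a: int = 0
    de_ncrna_a: int = 0
    mapped_coding_b: int = 0
    mapped_ncrna_b: int = 0
    final_coding_b: int = 0
    final_ncrna_b: int = 0
    n_candidates_universe: int = 0
    n_candidates_post_a: int = 0
    n_candidates_final: int = 0
    dropped_no_expression_a: int = 0
    dropped_no_expression_b: int = 0

    def to_dict(self) -> dict[str, int]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StageCounts":
        return cls(**{k: int(v) for k, v in d.items()})


@dataclass
class ScreenResult:
    candidates: list[ConservedCandidate]
    counts: StageCounts
    de_a: dict[str, pd.DataFrame] = field(default_factory=dict)
    de_b: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __iter__(self):  # allow ``candidates, counts = run_screen(...)``
        return iter((self.candidates, self.counts))


def _default_contrasts(expr: ExpressionMatrix) -> tuple[Contrast, ...]:
    groups = expr.groups
    if len(groups) < 2:
        raise ValueError("design needs at least two groups")
    return tuple(
        Contrast(name=f"{b}_over_{a}", group_numerator=b, group_denominator=a)
        for a, b in zip(groups, groups[1:])
    )


def _nearest_only(pairs: Sequence[GenePair]) -> list[GenePair]:
    """Keep, per coding gene, only its nearest lncRNA (ties: leftmost id)."""
    best: dict[str, GenePair] = {}
    for p in pairs:
        cur = best.get(p.coding.gene_id)
        if (
            cur is None
            or (p.distance_bp, p.ncrna.gene_id) < (cur.distance_bp, cur.ncrna.gene_id)
        ):
            best[p.coding.gene_id] = p
    return [p for p in pairs if best[p.coding.gene_id] is p]


def _prepare(expr: ExpressionMatrix, cfg: ScreenConfig, side: str) -> ExpressionMatrix:
    out = log2_transform(expr) if cfg.input_scale == "counts" else expr
    if cfg.normalize in ("both", side):
        out = quantile_normalize(out)
    return out


def _selected_sets(
    expr: ExpressionMatrix,
    gene_ids: set[str],
    contrasts: Sequence[Contrast],
    rule: ThresholdRule,
    method: str,
) -> tuple[dict[str, set[str]], int, dict[str, pd.DataFrame]]:
    """Per-contrast selected-gene sets for one gene class, DE run on that
    class alone (its own multiplicity correction).  Returns (selected sets,
    number of requested genes missing from the matrix, DE tables)."""
    present = [g for g in expr.values.index if g in gene_ids]
    n_missing = len(gene_ids) - len(present)
    sub = ExpressionMatrix(values=expr.values.loc[present], design=expr.design.copy())
    selected: dict[str, set[str]] = {}
    tables: dict[str, pd.DataFrame] = {}
    for c in contrasts:
        table = fit_de(sub, c, method=method)
        tables[c.name] = table
        selected[c.name] = set(apply_thresholds(table, rule).index)
    return selected, n_missing, tables


def _passes(
    coding_sel: dict[str, set[str]],
    ncrna_sel: dict[str, set[str]],
    coding_id: str,
    ncrna_id: str,
    combination: str,
    constraint: str,
) -> bool:
    names = list(coding_sel)
    both = [coding_id in coding_sel[n] and ncrna_id in ncrna_sel[n] for n in names]
    c_any = [coding_id in coding_sel[n] for n in names]
    n_any = [ncrna_id in ncrna_sel[n] for n in names]
    if combination == "all_contrasts":
        return all(both) if constraint == "same_contrast" else (all(c_any) and all(n_any))
    if constraint == "same_contrast":
        return any(both)
    return any(c_any) and any(n_any)


def run_screen(
    ann_a: AnnotationSet,
    ann_b: AnnotationSet,
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    orthomap: OrthologMap,
    cfg: ScreenConfig | None = None,
) -> ScreenResult:
    """Run the full cross-species screen; see the module docstring for stages."""
    cfg = cfg or ScreenConfig()
    counts = StageCounts()

    # stage 1: neighbour pairing per species
    pairs_a = pair_within_window(ann_a, cfg.window_bp, anchor=cfg.distance_anchor)
    pairs_b = pair_within_window(ann_b, cfg.window_bp, anchor=cfg.distance_anchor)
    if cfg.nearest_only:
        pairs_a = _nearest_only(pairs_a)
        pairs_b = _nearest_only(pairs_b)

    # stage 2: conservation join -> candidate universe
    universe = join_conserved(pairs_a, pairs_b, orthomap)
    uni = summarize_universe(universe)
    counts.universe_coding_a = uni["coding_a"]
    counts.universe_ncrna_a = uni["ncrna_a"]
    counts.universe_coding_b = uni["coding_b"]
    counts.universe_ncrna_b = uni["ncrna_b"]
    counts.n_candidates_universe = len(universe)

    if not universe:
        return ScreenResult(candidates=[], counts=counts)

    # stage 3: species-A differential filter
    prep_a = _prepare(expr_a, cfg, "a")
    contrasts_a = cfg.contrasts_a or _default_contrasts(prep_a)
    coding_ids_a = {c.coding_a for c in universe}
    ncrna_ids_a = {c.ncrna_a for c in universe}
    coding_sel_a, miss_c_a, tab_c_a = _selected_sets(
        prep_a, coding_ids_a, contrasts_a, cfg.rule_a, cfg.de_method
    )
    ncrna_sel_a, miss_n_a, tab_n_a = _selected_sets(
        prep_a, ncrna_ids_a, contrasts_a, cfg.rule_a, cfg.de_method
    )
    counts.dropped_no_expression_a = miss_c_a + miss_n_a
    if counts.dropped_no_expression_a:
        logger.warning(
            "species A: %d universe genes had no expression and were dropped",
            counts.dropped_no_expression_a,
        )
    survivors = [
        c
        for c in universe
        if _passes(
            coding_sel_a, ncrna_sel_a, c.coding_a, c.ncrna_a, cfg.de_combination, cfg.pair_constraint
        )
    ]
    counts.de_coding_a = len({c.coding_a for c in survivors})
    counts.de_ncrna_a = len({c.ncrna_a for c in survivors})
    counts.n_candidates_post_a = len(survivors)

    # stage 4: map to species-B coding genes and their neighbouring lncRNAs
    counts.mapped_coding_b = len({c.coding_b for c in survivors})
    counts.mapped_ncrna_b = len({c.ncrna_b for c in survivors})

    de_tables_a = {f"coding:{k}": v for k, v in tab_c_a.items()}
    de_tables_a.update({f"ncrna:{k}": v for k, v in tab_n_a.items()})
    if not survivors:
        return ScreenResult(candidates=[], counts=counts, de_a=de_tables_a)

    # stage 5: species-B differential filter on both members
    prep_b = _prepare(expr_b, cfg, "b")
    contrast_b = cfg.contrast_b
    if contrast_b is None:
        groups_b = prep_b.groups
        if len(groups_b) != 2:
            raise ValueError(
                "species B design must have exactly two groups when contrast_b is not given"
            )
        contrast_b = Contrast(
            name=f"{groups_b[1]}_over_{groups_b[0]}",
            group_numerator=groups_b[1],
            group_denominator=groups_b[0],
        )
    coding_ids_b = {c.coding_b for c in survivors}
    ncrna_ids_b = {c.ncrna_b for c in survivors}
    coding_sel_b, miss_c_b, tab_c_b = _selected_sets(
        prep_b, coding_ids_b, [contrast_b], cfg.rule_b, cfg.de_method
    )
    ncrna_sel_b, miss_n_b, tab_n_b = _selected_sets(
        prep_b, ncrna_ids_b, [contrast_b], cfg.rule_b, cfg.de_method
    )
    counts.dropped_no_expression_b = miss_c_b + miss_n_b
    if counts.dropped_no_expression_b:
        logger.warning(
            "species B: %d mapped genes had no expression and were dropped",
            counts.dropped_no_expression_b,
        )
    sel_c_b = coding_sel_b[contrast_b.name]
    sel_n_b = ncrna_sel_b[contrast_b.name]
    final = [c for c in survivors if c.coding_b in sel_c_b and c.ncrna_b in sel_n_b]
    counts.final_coding_b = len({c.coding_b for c in final})
    counts.final_ncrna_b = len({c.ncrna_b for c in final})
    counts.n_candidates_final = len(final)

    de_tables_b = {f"coding:{contrast_b.name}": tab_c_b[contrast_b.name]}
    de_tables_b[f"ncrna:{contrast_b.name}"] = tab_n_b[contrast_b.name]
    return ScreenResult(candidates=final, counts=counts, de_a=de_tables_a, de_b=de_tables_b)


_STAGE_LINES = [
    ("conserved candidate universe", "n_candidates_universe"),
    ("  species A coding genes", "universe_coding_a"),
    ("  species A non-coding RNAs", "universe_ncrna_a"),
    ("  species B coding genes", "universe_coding_b"),
    ("  species B non-coding RNAs", "universe_ncrna_b"),
    ("after species A differential filter", "n_candidates_post_a"),
    ("  selected species A coding genes", "de_coding_a"),
    ("  selected species A non-coding RNAs", "de_ncrna_a"),
    ("corresponding species B coding genes", "mapped_coding_b"),
    ("their neighbouring species B non-coding RNAs", "mapped_ncrna_b"),
    ("after species B differential filter", "n_candidates_final"),
    ("  final species B coding genes", "final_coding_b"),
    ("  final species B non-coding RNAs", "final_ncrna_b"),
]


def report_cascade(counts: StageCounts, path, log_path=None) -> None:
    """Write the stage accounting as JSON, plus an optional plain-text log."""
    with atomic_open(path) as fh:
        json.dump(counts.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if log_path is not None:
        with atomic_open(log_path) as fh:
            d = counts.to_dict()
            for label, key in _STAGE_LINES:
                fh.write(f"{label}: {d[key]}\n")


def read_cascade_report(path) -> StageCounts:
    with open(path) as fh:
        return StageCounts.from_dict(json.load(fh))
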