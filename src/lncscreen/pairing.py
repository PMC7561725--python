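"""Coding-gene / lncRNA neighbour pairing within a genomic window.

A coding gene and a lncRNA on the same chromosome form a :class:`GenePair`
when the gap between their intervals (number of bases strictly between them;
0 when they overlap or abut) is at most the window, 100 kb by default and
inclusive at the boundary.  Each pair is classified by transcriptional
orientation:

* ``divergent`` — disjoint, opposite strands, 5' ends (TSSs) facing each
  other across the gap (head-to-head, the classic bidirectional-promoter
  arrangement);
* ``convergent`` — disjoint, opposite strands, 3' ends facing each other;
* ``tandem`` — disjoint, same strand;
* ``antisense_overlap`` / ``sense_overlap`` — overlapping intervals on
  opposite / the same strand.

Pairing is many-to-many: every qualifying combination is kept, with no
nearest-neighbour reduction.  Window queries run against an interval-tree
index of the lncRNAs; distance is the inter-interval gap by default, with
TSS-to-TSS distance available as an alternative anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import CODING, LNCRNA, AnnotationSet, GeneRecord, write_table

DIVERGENT = "divergent"
CONVERGENT = "convergent"
TANDEM = "tandem"
ANTISENSE_OVERLAP = "antisense_overlap"
SENSE_OVERLAP = "sense_overlap"
ORIENTATIONS = (DIVERGENT, CONVERGENT, TANDEM, ANTISENSE_OVERLAP, SENSE_OVERLAP)

#: Convenience alias: every opposite-strand class, matching the loose field
#: usage of "divergent lncRNA" as any opposite-strand neighbour.
ORIENTATION_ALIASES = {
    "opposite_strand": frozenset({DIVERGENT, CONVERGENT, ANTISENSE_OVERLAP}),
    "all": frozenset(ORIENTATIONS),
}


@dataclass(frozen=True, slots=True)
class GenePair:
    coding: GeneRecord
    ncrna: GeneRecord
    distance_bp: int
    orientation: str


def gap(a: GeneRecord, b: GeneRecord) -> int:
    """Bases strictly between two intervals; 0 when they overlap or abut."""
    return max(a.start - b.end, b.start - a.end, 0)


def overlaps(a: GeneRecord, b: GeneRecord) -> bool:
    return a.start < b.end and b.start < a.end


def tss_distance(a: GeneRecord, b: GeneRecord) -> int:
    return abs(a.tss - b.tss)


def classify_orientation(coding: GeneRecord, ncrna: GeneRecord) -> str:
    """Orientation class of one coding/lncRNA pair on a shared chromosome."""
    if coding.chrom != ncrna.chrom:
        raise ValueError("orientation is defined only for genes on one chromosome")
    if overlaps(coding, ncrna):
        return SENSE_OVERLAP if coding.strand == ncrna.strand else ANTISENSE_OVERLAP
    if coding.strand == ncrna.strand:
        return TANDEM
    left, right = (coding, ncrna) if coding.start <= ncrna.start else (ncrna, coding)
    # Head-to-head: the left gene transcribes leftward (TSS at its right edge),
    # the right gene rightward, so the two TSSs face each other across the gap.
    return DIVERGENT if (left.strand, right.strand) == ("-", "+") else CONVERGENT


def pair_within_window(
    ann: AnnotationSet,
    window_bp: int = 100_000,
    anchor: str = "gap",
) -> list[GenePair]:
    """All coding/lncRNA pairs whose distance is <= ``window_bp`` (inclusive).

    ``anchor`` selects the distance definition: ``"gap"`` (inter-interval gap,
    bedtools-window-like) or ``"tss"`` (TSS-to-TSS).  Output order is
    deterministic: (chrom, coding start, ncrna start, ids).
    """
    if window_bp < 0:
        raise ValueError(f"window_bp must be non-negative, got {window_bp}")
    if anchor not in ("gap", "tss"):
        raise ValueError(f"anchor must be 'gap' or 'tss', got {anchor!r}")

    pairs: list[GenePair] = []
    for chrom in ann.chroms:
        records = ann.on_chrom(chrom)
        lncs = [r for r in records if r.biotype == LNCRNA]
        codings = [r for r in records if r.biotype == CODING]
        if not lncs or not codings:
            continue
        tree = IntervalTree()
        for i, lnc in enumerate(lncs):
            tree.addi(lnc.start, lnc.end, i)
        for cod in codings:
            # Query bounds chosen so that gap == window_bp is still returned
            # (intervaltree overlap is strict on both ends; coordinates are ints).
            hits = tree.overlap(cod.start - window_bp - 1, cod.end + window_bp + 1)
            for hit in hits:
                lnc = lncs[hit.data]
                d = gap(cod, lnc) if anchor == "gap" else tss_distance(cod, lnc)
                if d <= window_bp:
                    pairs.append(
                        GenePair(
                            coding=cod,
                            ncrna=lnc,
                            distance_bp=gap(cod, lnc),
                            orientation=classify_orientation(cod, lnc),
                        )
                    )
    pairs.sort(
        key=lambda p: (
            p.coding.chrom,
            p.coding.start,
            p.ncrna.start,
            p.coding.gene_id,
            p.ncrna.gene_id,
        )
    )
    return pairs


def _resolve_classes(classes: Iterable[str] | str) -> frozenset[str]:
    if isinstance(classes, str):
        classes = [classes]
    out: set[str] = set()
    for c in classes:
        if c in ORIENTATION_ALIASES:
            out |= ORIENTATION_ALIASES[c]
        elif c in ORIENTATIONS:
            out.add(c)
        else:
            raise ValueError(f"unknown orientation class {c!r}")
    return frozenset(out)


def filter_orientation(pairs: Sequence[GenePair], classes: Iterable[str] | str) -> list[GenePair]:
    """Keep pairs whose orientation is in ``classes`` (names or aliases), preserving order."""
    keep = _resolve_classes(classes)
    return [p for p in pairs if p.orientation in keep]


def pairs_to_frame(pairs: Sequence[GenePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "coding_id": p.coding.gene_id,
                "ncrna_id": p.ncrna.gene_id,
                "chrom": p.coding.chrom,
                "distance_bp": p.distance_bp,
                "orientation": p.orientation,
            }
            for p in pairs
        ],
        columns=["coding_id", "ncrna_id", "chrom", "distance_bp", "orientation"],
    )


def write_pairs(pairs: Sequence[GenePair], path, header_comment: str | None = None) -> None:
    write_table(pairs_to_frame(pairs), path, header_comment=header_comment)
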