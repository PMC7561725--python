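"""Ortholog-anchored joining of two species' coding/lncRNA pair sets.

lncRNA "conservation" here is positional, not sequence-based: a lncRNA in
species A corresponds to one in species B when both sit next to coding genes
that are orthologous.  The join is the full relational product — one-to-many
orthology and multi-neighbour loci expand to all combinations; downstream
differential-expression filters do the pruning.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import pandas as pd

from ._util import logger
from .io_formats import OrthologMap, write_table
from .pairing import GenePair


@dataclass(frozen=True, slots=True)
class ConservedCandidate:
    """A (species-A pair, species-B pair) tuple linked through coding orthology."""

    coding_a: str
    ncrna_a: str
    coding_b: str
    ncrna_b: str
    distance_a: int
    distance_b: int
    orientation_a: str
    orientation_b: str


def join_conserved(
    pairs_a: Sequence[GenePair],
    pairs_b: Sequence[GenePair],
    orthomap: OrthologMap,
) -> list[ConservedCandidate]:
    """All combinations of an A-pair and a B-pair with orthologous coding genes.

    Ortholog entries whose coding ids appear in no pair set are skipped with a
    logged count.  Output is deduplicated and deterministically ordered.
    """
    by_coding_a: dict[str, list[GenePair]] = {}
    for p in pairs_a:
        by_coding_a.setdefault(p.coding.gene_id, []).append(p)
    by_coding_b: dict[str, list[GenePair]] = {}
    for p in pairs_b:
        by_coding_b.setdefault(p.coding.gene_id, []).append(p)

    seen: dict[ConservedCandidate, None] = {}
    n_unmatched = 0
    for a_id, b_id in orthomap.pairs:
        a_pairs = by_coding_a.get(a_id)
        b_pairs = by_coding_b.get(b_id)
        if not a_pairs or not b_pairs:
            n_unmatched += 1
            continue
        for pa in a_pairs:
            for pb in b_pairs:
                cand = ConservedCandidate(
                    coding_a=pa.coding.gene_id,
                    ncrna_a=pa.ncrna.gene_id,
                    coding_b=pb.coding.gene_id,
                    ncrna_b=pb.ncrna.gene_id,
                    distance_a=pa.distance_bp,
                    distance_b=pb.distance_bp,
                    orientation_a=pa.orientation,
                    orientation_b=pb.orientation,
                )
                seen.setdefault(cand, None)
    if n_unmatched:
        logger.warning(
            "%d ortholog entries had no paired coding gene on one side; skipped", n_unmatched
        )
    out = list(seen)
    out.sort(key=lambda c: (c.coding_a, c.ncrna_a, c.coding_b, c.ncrna_b))
    return out


def summarize_universe(candidates: Sequence[ConservedCandidate]) -> dict[str, int]:
    """Distinct coding/lncRNA gene counts per species among the candidates."""
    return {
        "coding_a": len({c.coding_a for c in candidates}),
        "ncrna_a": len({c.ncrna_a for c in candidates}),
        "coding_b": len({c.coding_b for c in candidates}),
        "ncrna_b": len({c.ncrna_b for c in candidates}),
    }


def candidates_to_frame(candidates: Sequence[ConservedCandidate]) -> pd.DataFrame:
    cols = [
        "coding_a",
        "ncrna_a",
        "coding_b",
        "ncrna_b",
        "distance_a",
        "distance_b",
        "orientation_a",
        "orientation_b",
    ]
    return pd.DataFrame([asdict(c) for c in candidates], columns=cols)


def write_candidates(candidates: Sequence[ConservedCandidate], path, header_comment=None) -> None:
    write_table(candidates_to_frame(candidates), path, header_comment=header_comment)
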