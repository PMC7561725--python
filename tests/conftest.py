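"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use the dumbest possible algorithms (nested
loops over all combinations) so they stay independent of the library's
indexed/vectorised code paths they are checked against.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lncscreen.io_formats import CODING, LNCRNA, AnnotationSet, GeneRecord
from lncscreen.pairing import GenePair


def make_gene(
    gene_id="g1",
    chrom="chr1",
    start=0,
    end=1000,
    strand="+",
    biotype=CODING,
    species="speciesA",
) -> GeneRecord:
    return GeneRecord(gene_id, chrom, start, end, strand, biotype, species)


@pytest.fixture
def make_record():
    return make_gene


def random_annotation(
    rng: np.random.Generator,
    n_genes: int,
    species: str = "speciesA",
    n_chroms: int = 3,
    chrom_len: int = 2_000_000,
    lnc_frac: float = 0.5,
) -> AnnotationSet:
    """Random gene placement with overlaps allowed — a stress layout for pairing."""
    ann = AnnotationSet(species)
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, chrom_len))
        length = int(rng.integers(500, 40_000))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = LNCRNA if rng.random() < lnc_frac else CODING
        ann.add(GeneRecord(f"{species}_g{i:05d}", chrom, start, start + length, strand, biotype, species))
    return ann


def brute_force_pairs(ann: AnnotationSet, window_bp: int, anchor: str = "gap"):
    """All-pairs O(n^2) reference for pair_within_window (returns id tuples)."""
    out = set()
    records = list(ann)
    for c in records:
        if c.biotype != CODING:
            continue
        for n in records:
            if n.biotype != LNCRNA or n.chrom != c.chrom:
                continue
            g = max(c.start - n.end, n.start - c.end, 0)
            if anchor == "gap":
                d = g
            else:
                c_tss = c.start if c.strand == "+" else c.end - 1
                n_tss = n.start if n.strand == "+" else n.end - 1
                d = abs(c_tss - n_tss)
            if d <= window_bp:
                out.add((c.gene_id, n.gene_id, g))
    return out


def brute_force_join(pairs_a, pairs_b, orthomap):
    """Nested-loop reference for join_conserved (returns 4-id tuples)."""
    links = set(orthomap.pairs)
    out = set()
    for pa in pairs_a:
        for pb in pairs_b:
            if (pa.coding.gene_id, pb.coding.gene_id) in links:
                out.add(
                    (pa.coding.gene_id, pa.ncrna.gene_id, pb.coding.gene_id, pb.ncrna.gene_id)
                )
    return out


def random_pairs(rng, species: str, n: int, n_coding: int, n_lnc: int) -> list[GenePair]:
    """Random pair tables for join tests (geometry is irrelevant to the join)."""
    out = {}
    while len(out) < n:
        ci = int(rng.integers(0, n_coding))
        li = int(rng.integers(0, n_lnc))
        key = (ci, li)
        if key in out:
            continue
        c = make_gene(f"{species}_c{ci}", "chr1", 1000 * ci, 1000 * ci + 500, "+", CODING, species)
        l = make_gene(f"{species}_n{li}", "chr1", 1000 * li + 600, 1000 * li + 900, "-", LNCRNA, species)
        out[key] = GenePair(c, l, 100, "divergent")
    return list(out.values())


@pytest.fixture
def small_expr():
    """4 genes x 4 samples, two groups, counts-like values."""
    from lncscreen.io_formats import ExpressionMatrix

    values = pd.DataFrame(
        {
            "s1": [10.0, 5.0, 100.0, 1.0],
            "s2": [12.0, 6.0, 90.0, 2.0],
            "s3": [50.0, 5.5, 95.0, 1.5],
            "s4": [55.0, 6.5, 105.0, 2.5],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    design = pd.Series(["grp1", "grp1", "grp2", "grp2"], index=["s1", "s2", "s3", "s4"])
    return ExpressionMatrix(values=values, design=design)
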