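"""Readers and writers for every external format the screen touches.

All genomic coordinates are normalised to a single internal convention:
0-based, half-open ``[start, end)`` — the convention BED uses natively and the
one under which interval length is simply ``end - start``.  GTF (1-based,
inclusive) is converted on read and write.

Biotypes are collapsed to three internal labels: ``coding``, ``lncRNA`` and
``other``.  The mapping from annotation-source strings (Gencode
``gene_type``/``gene_biotype`` values) is configurable; unknown strings map to
``other`` and are excluded from neighbour pairing downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils.feature
import numpy as np
import pandas as pd

from ._util import atomic_open, logger

CODING = "coding"
LNCRNA = "lncRNA"
OTHER = "other"
BIOTYPES = (CODING, LNCRNA, OTHER)

#: Default mapping of Gencode gene_type strings onto the three internal labels.
#: Anything absent from the mapping becomes ``other``.
DEFAULT_BIOTYPE_RULES: dict[str, str] = {
    "protein_coding": CODING,
    "lncRNA": LNCRNA,
    "lincRNA": LNCRNA,
    "antisense": LNCRNA,
    "antisense_RNA": LNCRNA,
    "bidirectional_promoter_lncRNA": LNCRNA,
    "sense_intronic": LNCRNA,
    "sense_overlapping": LNCRNA,
    "macro_lncRNA": LNCRNA,
    "3prime_overlapping_ncRNA": LNCRNA,
    # internal labels round-trip through themselves
    CODING: CODING,
    LNCRNA: LNCRNA,
    OTHER: OTHER,
}

#: Internal label -> string emitted when writing GTF.
_GTF_BIOTYPE_OUT = {CODING: "protein_coding", LNCRNA: "lncRNA", OTHER: "other"}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class GtfParseError(FormatError):
    def __init__(self, path, lineno: int, reason: str):
        super().__init__(f"{path}:{lineno}: {reason}")
        self.lineno = lineno


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """One annotated gene as a single interval (no isoforms)."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'
    biotype: str  # coding | lncRNA | other
    species: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site: 5' end given the strand."""
        return self.start if self.strand == "+" else self.end - 1


class AnnotationSet:
    """All gene records of one species, indexed by chromosome and by id.

    Per-chromosome records are kept sorted by start.  ``skipped`` counts input
    records rejected on read (e.g. unknown strand symbols).
    """

    def __init__(self, species: str, records: Iterable[GeneRecord] = (), skipped: int = 0):
        self.species = species
        self.skipped = skipped
        self._by_id: dict[str, GeneRecord] = {}
        self._by_chrom: dict[str, list[GeneRecord]] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: GeneRecord) -> None:
        if rec.species != self.species:
            raise ValueError(
                f"record {rec.gene_id} has species {rec.species!r}, set is {self.species!r}"
            )
        if rec.gene_id in self._by_id:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
        self._by_id[rec.gene_id] = rec
        self._by_chrom.setdefault(rec.chrom, []).append(rec)
        self._by_chrom[rec.chrom].sort(key=lambda r: (r.start, r.end, r.gene_id))

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[GeneRecord]:
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def get(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def on_chrom(self, chrom: str) -> list[GeneRecord]:
        return list(self._by_chrom.get(chrom, []))

    def by_biotype(self, biotype: str) -> list[GeneRecord]:
        return [r for r in self if r.biotype == biotype]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AnnotationSet)
            and self.species == other.species
            and list(self) == list(other)
        )


def read_gtf(
    path: str | Path,
    species: str,
    biotype_rules: Mapping[str, str] | None = None,
) -> AnnotationSet:
    """Read gene features from a GTF2.2 file.

    Coordinates are converted from GTF's 1-based inclusive to the internal
    0-based half-open convention.  Records with strand symbols other than
    '+'/'-' are dropped with a warning and counted in ``AnnotationSet.skipped``.
    Malformed lines raise :class:`GtfParseError` naming the line number.
    """
    rules = DEFAULT_BIOTYPE_RULES if biotype_rules is None else biotype_rules
    ann = AnnotationSet(species)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GtfParseError(path, lineno, "expected 9 tab-separated fields")
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise GtfParseError(path, lineno, f"malformed GTF line ({exc})") from exc
            if feat.featuretype != "gene":
                continue
            if feat.strand not in ("+", "-"):
                logger.warning(
                    "%s:%d: unknown strand %r, record skipped", path, lineno, feat.strand
                )
                ann.skipped += 1
                continue
            attrs = feat.attributes
            try:
                gene_id = attrs["gene_id"][0]
            except KeyError as exc:
                raise GtfParseError(path, lineno, "missing gene_id attribute") from exc
            raw_biotype = (attrs.get("gene_type") or attrs.get("gene_biotype") or [OTHER])[0]
            ann.add(
                GeneRecord(
                    gene_id=gene_id,
                    chrom=feat.seqid,
                    start=feat.start - 1,  # GTF is 1-based inclusive
                    end=feat.end,
                    strand=feat.strand,
                    biotype=rules.get(raw_biotype, OTHER),
                    species=species,
                )
            )
    return ann


def write_gtf(ann: AnnotationSet, path: str | Path, header_comment: str | None = None) -> None:
    with atomic_open(path) as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for rec in ann:
            attrs = f'gene_id "{rec.gene_id}"; gene_type "{_GTF_BIOTYPE_OUT[rec.biotype]}";'
            fh.write(
                "\t".join(
                    [
                        rec.chrom,
                        "lncscreen",
                        "gene",
                        str(rec.start + 1),
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_bed(path: str | Path, species: str) -> AnnotationSet:
    """Read a BED6+1 file (column 7 = biotype).  Coordinates kept unchanged."""
    ann = AnnotationSet(species)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise FormatError(
                    f"{path}:{lineno}: BED6+1 requires >= 7 columns, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand, biotype = fields[:7]
            if strand not in ("+", "-"):
                logger.warning("%s:%d: unknown strand %r, record skipped", path, lineno, strand)
                ann.skipped += 1
                continue
            if biotype not in BIOTYPES:
                raise FormatError(f"{path}:{lineno}: unknown biotype label {biotype!r}")
            ann.add(
                GeneRecord(
                    gene_id=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    biotype=biotype,
                    species=species,
                )
            )
    return ann


def write_bed(ann: AnnotationSet, path: str | Path, header_comment: str | None = None) -> None:
    with atomic_open(path) as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for rec in ann:
            fh.write(
                "\t".join(
                    [rec.chrom, str(rec.start), str(rec.end), rec.gene_id, "0", rec.strand, rec.biotype]
                )
                + "\n"
            )


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix with a sample -> group design.

    ``values`` is a DataFrame (rows: gene ids, columns: sample ids); ``design``
    maps every sample to its group label.  Values must be finite and
    non-missing; gene ids must be unique.
    """

    values: pd.DataFrame
    design: pd.Series

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            self._raise_non_numeric()
        if self.values.isna().any().any():
            self._raise_non_numeric()
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise FormatError(f"samples absent from design: {missing}")
        self.design = self.design.reindex(self.values.columns)

    def _raise_non_numeric(self):
        numeric = self.values.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna()
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise FormatError(f"non-numeric or missing value at gene {row!r}, sample {col!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return list(self.design.index[self.design == group])

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.design:
            seen.setdefault(g, None)
        return list(seen)

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, design=self.design.copy())


def read_expression(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene id) and its design table."""
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    design_df = pd.read_csv(design_path, sep="\t", comment="#")
    if not {"sample", "group"}.issubset(design_df.columns):
        raise FormatError(f"{design_path}: design table needs columns 'sample' and 'group'")
    design = pd.Series(design_df["group"].values, index=design_df["sample"].values)
    if design.index.has_duplicates:
        raise FormatError(f"{design_path}: duplicate sample ids in design")
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & ~raw[col].isna()
        if bad.any():
            raise FormatError(
                f"non-numeric value at gene {raw.index[bad.argmax()]!r}, sample {col!r}"
            )
        raw[col] = coerced
    return ExpressionMatrix(values=raw, design=design)


def write_expression(
    expr: ExpressionMatrix,
    path: str | Path,
    design_path: str | Path | None = None,
    header_comment: str | None = None,
) -> None:
    with atomic_open(path) as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        expr.values.to_csv(fh, sep="\t", index_label="gene_id")
    if design_path is not None:
        design = pd.DataFrame({"sample": expr.design.index, "group": expr.design.values})
        write_table(design, design_path, header_comment=header_comment)


@dataclass(frozen=True)
class OrthologMap:
    """Pairs linking species-A to species-B gene ids; may be many-to-many."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate ortholog pairs")

    @classmethod
    def from_pairs(cls, pairs: Iterable[Sequence[str]]) -> "OrthologMap":
        seen: dict[tuple[str, str], None] = {}
        for a, b in pairs:
            seen.setdefault((str(a), str(b)), None)
        return cls(pairs=tuple(seen))

    def a_to_b(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, []).append(b)
        return out

    def transposed(self) -> "OrthologMap":
        return OrthologMap(pairs=tuple((b, a) for a, b in self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)


def read_orthologs(path: str | Path) -> OrthologMap:
    """Read a two-column TSV ortholog map (header row; extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: ortholog map needs two id columns")
    pairs = list(df.iloc[:, :2].itertuples(index=False, name=None))
    n_dup = len(pairs) - len(set(pairs))
    if n_dup:
        logger.warning("%s: dropped %d duplicate ortholog pairs", path, n_dup)
    return OrthologMap.from_pairs(pairs)


def write_orthologs(omap: OrthologMap, path: str | Path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(list(omap.pairs), columns=["gene_a", "gene_b"])
    write_table(df, path, header_comment=header_comment)


def write_table(
    records,
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write a DataFrame (or iterable of dataclass-like records) as a TSV file."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.__dict__ if hasattr(r, "__dict__") else r for r in records])
    with atomic_open(path) as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        records.to_csv(fh, sep="\t", index=False, quoting=csv.QUOTE_MINIMAL)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
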