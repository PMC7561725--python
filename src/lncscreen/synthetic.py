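"""Synthetic two-species study generator with planted ground truth.

The generator emulates the study design the screen was built for: a
four-stage progression series in species A (normal → transformed → in-situ →
invasive, three replicates per stage) and a two-group wild-type vs knockout
series in species B, over genomes where a chosen number of orthologous
coding genes carry a nearby lncRNA that is jointly differentially expressed
in both species.

Genome layout.  Genes are placed locus by locus along the chromosome(s) with
a guard gap of ``window_bp + 1`` between loci, so the only coding/lncRNA
pairs within the window are the ones planted deliberately:

* planted loci — an orthologous coding gene with a nearby lncRNA in *both*
  species (gap uniform on [0, window], orientation sampled over all five
  classes) carrying planted expression effects;
* conserved decoy loci — the same structure but with null expression, so
  they enter the candidate universe and must be removed by the differential
  filters;
* single-side decoy loci — a nearby lncRNA in only one species (removed by
  the conservation join);
* lone genes — far from everything (removed by pairing).

Counts are negative binomial with variance μ + φμ²; planted genes take
stage-cumulative log2 effects so a gene can be differential in one or
several successive transitions.  Everything is reproducible from
(parameters, seed), and a :class:`TruthManifest` records which genes should
survive each stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import atomic_open, rng_from, spawn_seeds
from .io_formats import (
    CODING,
    LNCRNA,
    AnnotationSet,
    ExpressionMatrix,
    GeneRecord,
    OrthologMap,
    write_bed,
    write_expression,
    write_orthologs,
)
from .pairing import (
    ANTISENSE_OVERLAP,
    CONVERGENT,
    DIVERGENT,
    ORIENTATIONS,
    SENSE_OVERLAP,
    TANDEM,
)

PROGRESSION_GROUPS = ("stage1", "stage2", "stage3", "stage4")
TWO_GROUPS = ("wt", "ko")


@dataclass
class TruthManifest:
    """Ground truth of one simulated study.

    ``planted`` rows describe the conserved differential pairs (ids, per-
    species gaps and orientations, per-transition log2 effects); ``decoys``
    lists the null structures by role; ``params`` echoes the simulation
    parameters.
    """

    planted: list[dict] = field(default_factory=list)
    decoys: dict[str, list[str]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def planted_pair_ids(self) -> set[tuple[str, str, str, str]]:
        return {
            (p["coding_a"], p["ncrna_a"], p["coding_b"], p["ncrna_b"]) for p in self.planted
        }

    def to_json(self, path) -> None:
        with atomic_open(path) as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _place_pair_locus(rng, orientation: str, window_bp: int) -> tuple[tuple, tuple, int]:
    """Local-coordinate geometry for one coding+lncRNA locus.

    Returns (coding (start, end, strand), lnc (start, end, strand), gap).
    """
    len_c = int(rng.integers(5_000, 30_001))
    len_n = int(rng.integers(1_000, 10_001))
    if orientation in (ANTISENSE_OVERLAP, SENSE_OVERLAP):
        c = (0, len_c)
        ls = int(rng.integers(-len_n + 1, len_c))  # guarantees overlap
        n = (ls, ls + len_n)
        s_c = rng.choice(["+", "-"])
        s_n = s_c if orientation == SENSE_OVERLAP else ("-" if s_c == "+" else "+")
        return (c[0], c[1], s_c), (n[0], n[1], s_n), 0
    g = int(rng.integers(0, window_bp + 1))
    lnc_right = bool(rng.integers(0, 2))
    if lnc_right:
        c = (0, len_c)
        n = (len_c + g, len_c + g + len_n)
        left_strand_of = "c"
    else:
        n = (0, len_n)
        c = (len_n + g, len_n + g + len_c)
        left_strand_of = "n"
    if orientation == TANDEM:
        s = rng.choice(["+", "-"])
        s_c = s_n = s
    else:
        left, right = (("-", "+") if orientation == DIVERGENT else ("+", "-"))
        if left_strand_of == "c":
            s_c, s_n = left, right
        else:
            s_n, s_c = left, right
    return (c[0], c[1], s_c), (n[0], n[1], s_n), g


class _Layout:
    """Sequential locus placement over one or more chromosomes."""

    def __init__(self, chrom_sizes: Mapping[str, int], guard: int):
        self.chrom_sizes = dict(chrom_sizes)
        self.guard = guard
        self._names = list(self.chrom_sizes)
        self._idx = 0
        self._cursor = 0

    def place(self, extent: int) -> tuple[str, int]:
        """Reserve ``extent`` bases; returns (chrom, offset)."""
        while self._idx < len(self._names):
            chrom = self._names[self._idx]
            if self._cursor + extent <= self.chrom_sizes[chrom]:
                offset = self._cursor
                self._cursor += extent + self.guard
                return chrom, offset
            self._idx += 1
            self._cursor = 0
        raise ValueError("chromosomes too small to host the requested genes")


def _build_species(
    rng,
    species: str,
    prefix: str,
    n_coding: int,
    n_lnc: int,
    roles: Sequence[str],
    orientations: Sequence[str | None],
    window_bp: int,
    chrom_sizes: Mapping[str, int] | None,
) -> tuple[AnnotationSet, list[dict]]:
    """Lay out one species' genome.

    ``roles[i]`` for coding gene i is 'near' (gets a nearby lncRNA) or
    'lone'; ``orientations[i]`` fixes the orientation of near loci.  Leftover
    lncRNAs become far decoys.  Returns the annotation and, per near locus,
    a dict with the pair's ids, gap and orientation.
    """
    n_near = sum(r == "near" for r in roles)
    if n_near > n_lnc:
        raise ValueError(f"{species}: {n_near} near loci requested but only {n_lnc} lncRNAs")
    if chrom_sizes is None:
        # generous auto-sizing: every locus fits on one synthetic chromosome
        per_locus = 2 * window_bp + 80_000
        chrom_sizes = {"chr1": (n_coding + n_lnc) * per_locus}
    layout = _Layout(chrom_sizes, guard=window_bp + 1)
    ann = AnnotationSet(species)
    near_info: list[dict] = []
    lnc_counter = 0
    for i, role in enumerate(roles):
        cod_id = f"{prefix}cod{i:05d}"
        if role == "near":
            orientation = orientations[i] or str(rng.choice(ORIENTATIONS))
            c_geom, n_geom, gap = _place_pair_locus(rng, orientation, window_bp)
            lo = min(c_geom[0], n_geom[0])
            hi = max(c_geom[1], n_geom[1])
            chrom, offset = layout.place(hi - lo)
            shift = offset - lo
            lnc_id = f"{prefix}lnc{lnc_counter:05d}"
            lnc_counter += 1
            ann.add(
                GeneRecord(cod_id, chrom, c_geom[0] + shift, c_geom[1] + shift, c_geom[2], CODING, species)
            )
            ann.add(
                GeneRecord(lnc_id, chrom, n_geom[0] + shift, n_geom[1] + shift, n_geom[2], LNCRNA, species)
            )
            near_info.append(
                {"coding": cod_id, "ncrna": lnc_id, "distance": gap, "orientation": orientation}
            )
        else:
            length = int(rng.integers(5_000, 30_001))
            chrom, offset = layout.place(length)
            strand = str(rng.choice(["+", "-"]))
            ann.add(GeneRecord(cod_id, chrom, offset, offset + length, strand, CODING, species))
    while lnc_counter < n_lnc:  # far decoy lncRNAs, isolated by the guard gap
        lnc_id = f"{prefix}lnc{lnc_counter:05d}"
        lnc_counter += 1
        length = int(rng.integers(1_000, 10_001))
        chrom, offset = layout.place(length)
        strand = str(rng.choice(["+", "-"]))
        ann.add(GeneRecord(lnc_id, chrom, offset, offset + length, strand, LNCRNA, species))
    return ann, near_info


def generate_genomes(
    n_coding: int,
    n_lnc: int,
    n_planted: int,
    window_bp: int = 100_000,
    chrom_sizes: Mapping[str, int] | None = None,
    seed: int = 0,
    conserved_decoy_frac: float = 0.2,
    single_side_decoy_frac: float = 0.1,
    ortholog_noise: float = 0.0,
) -> tuple[AnnotationSet, AnnotationSet, OrthologMap, TruthManifest]:
    """Two species' annotations, their ortholog map, and the truth manifest.

    ``conserved_decoy_frac`` of the decoy coding genes get a nearby null
    lncRNA in both species; ``single_side_decoy_frac`` in one species only.
    The ortholog map is one-to-one on all coding genes, plus optional
    one-to-many noise entries with probability ``ortholog_noise`` per gene.
    Planted pairs share their orientation class across species; geometry
    (gap, lengths, side) is sampled independently per species.
    """
    if n_planted > min(n_coding, n_lnc):
        raise ValueError("n_planted must not exceed n_coding or n_lnc")
    rng = rng_from(seed)

    n_decoy = n_coding - n_planted
    n_conserved_decoy = int(round(conserved_decoy_frac * n_decoy))
    n_single = int(round(single_side_decoy_frac * n_decoy))
    roles_a = ["near"] * n_planted + ["near"] * n_conserved_decoy
    roles_b = ["near"] * n_planted + ["near"] * n_conserved_decoy
    # single-side decoys: first half near in A only, second half near in B only
    for k in range(n_single):
        roles_a.append("near" if k % 2 == 0 else "lone")
        roles_b.append("lone" if k % 2 == 0 else "near")
    roles_a += ["lone"] * (n_coding - len(roles_a))
    roles_b += ["lone"] * (n_coding - len(roles_b))

    planted_orientations = [str(rng.choice(ORIENTATIONS)) for _ in range(n_planted)]
    orients_a: list[str | None] = list(planted_orientations) + [None] * (n_coding - n_planted)
    orients_b: list[str | None] = list(planted_orientations) + [None] * (n_coding - n_planted)

    ann_a, near_a = _build_species(
        rng, "speciesA", "A_", n_coding, n_lnc, roles_a, orients_a, window_bp, chrom_sizes
    )
    ann_b, near_b = _build_species(
        rng, "speciesB", "B_", n_coding, n_lnc, roles_b, orients_b, window_bp, chrom_sizes
    )
    near_a_by_coding = {d["coding"]: d for d in near_a}
    near_b_by_coding = {d["coding"]: d for d in near_b}

    pairs = [(f"A_cod{i:05d}", f"B_cod{i:05d}") for i in range(n_coding)]
    if ortholog_noise > 0:
        for i in range(n_coding):
            if rng.random() < ortholog_noise:
                j = int(rng.integers(0, n_coding))
                if j != i:
                    pairs.append((f"A_cod{i:05d}", f"B_cod{j:05d}"))
    orthomap = OrthologMap.from_pairs(pairs)

    manifest = TruthManifest(seed=seed)
    manifest.params = {
        "n_coding": n_coding,
        "n_lnc": n_lnc,
        "n_planted": n_planted,
        "window_bp": window_bp,
        "conserved_decoy_frac": conserved_decoy_frac,
        "single_side_decoy_frac": single_side_decoy_frac,
        "ortholog_noise": ortholog_noise,
    }
    for i in range(n_planted):
        a = near_a_by_coding[f"A_cod{i:05d}"]
        b = near_b_by_coding[f"B_cod{i:05d}"]
        manifest.planted.append(
            {
                "coding_a": a["coding"],
                "ncrna_a": a["ncrna"],
                "coding_b": b["coding"],
                "ncrna_b": b["ncrna"],
                "distance_a": a["distance"],
                "distance_b": b["distance"],
                "orientation_a": a["orientation"],
                "orientation_b": b["orientation"],
            }
        )
    planted_coding = {f"A_cod{i:05d}" for i in range(n_planted)}
    manifest.decoys = {
        "conserved_coding_a": [
            d["coding"] for d in near_a if d["coding"] not in planted_coding
            and f"B_{d['coding'][2:]}" in near_b_by_coding
        ],
        "conserved_ncrna_a": [
            d["ncrna"] for d in near_a if d["coding"] not in planted_coding
            and f"B_{d['coding'][2:]}" in near_b_by_coding
        ],
        "conserved_coding_b": [
            d["coding"] for d in near_b if f"A_{d['coding'][2:]}" not in planted_coding
            and f"A_{d['coding'][2:]}" in near_a_by_coding
        ],
        "conserved_ncrna_b": [
            d["ncrna"] for d in near_b if f"A_{d['coding'][2:]}" not in planted_coding
            and f"A_{d['coding'][2:]}" in near_a_by_coding
        ],
    }
    return ann_a, ann_b, orthomap, manifest


def generate_counts(
    ann: AnnotationSet,
    design: str,
    planted_log2fc: Mapping[str, Sequence[float]] | None = None,
    base_mean: float = 300.0,
    dispersion: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
) -> ExpressionMatrix:
    """Negative-binomial count matrix for one species' annotation.

    ``design`` is ``"progression"`` (four stages) or ``"two_group"``
    (wt/ko).  ``planted_log2fc`` maps gene id -> per-group log2 offsets
    (length = number of groups); the per-gene mean in group s is
    base·2^offset[s].  Non-planted genes get a group-constant mean drawn
    log-normally around ``base_mean``.  Count variance is μ + φμ²
    (``dispersion`` = φ; φ = 0 gives Poisson).
    """
    if design == "progression":
        groups = PROGRESSION_GROUPS
    elif design == "two_group":
        groups = TWO_GROUPS
    else:
        raise ValueError(f"unknown design {design!r}")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if base_mean <= 0 or n_reps < 1:
        raise ValueError("base_mean must be positive and n_reps >= 1")
    planted_log2fc = dict(planted_log2fc or {})
    for gid, offsets in planted_log2fc.items():
        if gid not in ann:
            raise ValueError(f"planted gene {gid!r} not in annotation")
        if len(offsets) != len(groups):
            raise ValueError(f"planted offsets for {gid!r} must have length {len(groups)}")
    rng = rng_from(seed)
    genes = [r.gene_id for r in ann]
    n_genes = len(genes)
    # group-constant baseline per gene; planted genes sit at base_mean exactly
    base = np.exp(rng.normal(np.log(base_mean), 0.8, size=n_genes))
    base[[i for i, g in enumerate(genes) if g in planted_log2fc]] = base_mean
    offsets = np.zeros((n_genes, len(groups)))
    for i, g in enumerate(genes):
        if g in planted_log2fc:
            offsets[i] = np.asarray(planted_log2fc[g], dtype=float)
    mu = base[:, None] * 2.0 ** offsets  # genes x groups
    samples = [f"{g}_r{r + 1}" for g in groups for r in range(n_reps)]
    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        m = mu[:, j // n_reps]
        if dispersion == 0:
            counts[:, j] = rng.poisson(m)
        else:
            size = 1.0 / dispersion
            counts[:, j] = rng.negative_binomial(size, size / (size + m))
    values = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    design_s = pd.Series([s.rsplit("_r", 1)[0] for s in samples], index=samples)
    return ExpressionMatrix(values=values, design=design_s)


def generate_stains(
    n_per_class: int,
    class_effects: Mapping[str, Mapping[str, float]],
    compartment_shift: Mapping[str, float] | None = None,
    seed: int = 0,
    marker: str = "marker1",
) -> pd.DataFrame:
    """Synthetic TMA stain table.

    ``class_effects[tissue_class]`` provides ``intensity_a``/``intensity_b``
    (Beta parameters for intensity in [0,1]) and ``proportion_mean``/
    ``proportion_sd`` (normal, clipped to [0,100]).  When
    ``compartment_shift`` gives a cytoplasmic fraction per class, each sample
    is emitted as a nuclear and a cytoplasmic row whose proportions split the
    total by a Beta-distributed share around that fraction.
    """
    rng = rng_from(seed)
    rows = []
    for tissue_class, eff in class_effects.items():
        for k in range(n_per_class):
            sample_id = f"{tissue_class}_{k:04d}"
            intensity = float(rng.beta(eff["intensity_a"], eff["intensity_b"]))
            proportion = float(
                np.clip(rng.normal(eff["proportion_mean"], eff["proportion_sd"]), 0.0, 100.0)
            )
            if compartment_shift is None:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "marker": marker,
                        "compartment": "",
                        "intensity": intensity,
                        "proportion": proportion,
                        "tissue_class": tissue_class,
                    }
                )
            else:
                f0 = compartment_shift[tissue_class]
                kappa = 30.0
                f = float(rng.beta(kappa * f0, kappa * (1.0 - f0))) if 0 < f0 < 1 else float(f0)
                for comp, share in (("cytoplasmic", f), ("nuclear", 1.0 - f)):
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "marker": marker,
                            "compartment": comp,
                            "intensity": intensity,
                            "proportion": proportion * share,
                            "tissue_class": tissue_class,
                        }
                    )
    return pd.DataFrame(rows)


def generate_survival(
    n_per_group: int,
    hazards: Mapping[object, float],
    censor_rate: float = 0.0,
    seed: int = 0,
    with_expression: bool = False,
) -> pd.DataFrame:
    """Exponential survival cohort with group-specific hazards.

    Censoring is an independent exponential chosen so the marginal censoring
    probability equals ``censor_rate``.  With ``with_expression=True`` the
    groups must be labelled 1–4 and each sample gets ``expr_pcg``/``expr_lnc``
    values consistent with its four-group definition (high ≈ +2, low ≈ −2),
    so the median-split assignment recovers the planted groups.
    """
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    for g, lam in hazards.items():
        if lam <= 0:
            raise ValueError(f"hazard for group {g!r} must be positive")
    rng = rng_from(seed)
    rows = []
    for g, lam in hazards.items():
        t_event = rng.exponential(1.0 / lam, size=n_per_group)
        if censor_rate > 0:
            lam_c = lam * censor_rate / (1.0 - censor_rate)
            t_cens = rng.exponential(1.0 / lam_c, size=n_per_group)
        else:
            t_cens = np.full(n_per_group, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        for k in range(n_per_group):
            row = {
                "sample_id": f"g{g}_{k:04d}",
                "group": g,
                "time": float(time[k]),
                "event": int(event[k]),
            }
            if with_expression:
                gi = int(g)
                if gi not in (1, 2, 3, 4):
                    raise ValueError("with_expression requires groups labelled 1-4")
                pcg_high = gi in (1, 2)
                lnc_high = gi in (1, 3)
                row["expr_pcg"] = float(rng.normal(2.0 if pcg_high else -2.0, 0.25))
                row["expr_lnc"] = float(rng.normal(2.0 if lnc_high else -2.0, 0.25))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario-driven simulation


@dataclass(frozen=True)
class Scenario:
    """Parameters of one end-to-end simulated study."""

    name: str
    n_coding: int
    n_lnc: int
    n_planted: int
    window_bp: int = 100_000
    planted_log2fc: float = 2.0
    base_mean: float = 300.0
    dispersion: float = 0.1
    n_reps: int = 3
    conserved_decoy_frac: float = 0.2
    single_side_decoy_frac: float = 0.1
    ortholog_noise: float = 0.0
    second_step_prob: float = 0.3

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with atomic_open(path) as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def load_scenario(name_or_path: str) -> Scenario:
    """Load a bundled scenario by name (tiny/default/stress) or a YAML path."""
    bundled = resources.files("lncscreen") / "scenarios" / f"{name_or_path}.yaml"
    if bundled.is_file():
        with resources.as_file(bundled) as p:
            return Scenario.from_yaml(p)
    if Path(name_or_path).is_file():
        return Scenario.from_yaml(name_or_path)
    raise ValueError(f"unknown scenario {name_or_path!r} (not bundled, not a file)")


@dataclass
class SimulatedStudy:
    ann_a: AnnotationSet
    ann_b: AnnotationSet
    orthomap: OrthologMap
    expr_a: ExpressionMatrix
    expr_b: ExpressionMatrix
    manifest: TruthManifest


def simulate_study(scenario: Scenario, seed: int = 0) -> SimulatedStudy:
    """Generate genomes, ortholog map and both species' count matrices.

    Each planted pair gets a shared sign and onset transition; its effect is
    cumulative from the onset stage onward, with an optional second step at a
    later transition, so planted genes are differential in one or more
    successive transitions.  Both pair members carry the same effects (the
    co-regulation expected of promoter-sharing neighbours), and the species-B
    effect uses the same sign.
    """
    seeds = spawn_seeds(seed, 4)
    ann_a, ann_b, orthomap, manifest = generate_genomes(
        n_coding=scenario.n_coding,
        n_lnc=scenario.n_lnc,
        n_planted=scenario.n_planted,
        window_bp=scenario.window_bp,
        seed=seeds[0],
        conserved_decoy_frac=scenario.conserved_decoy_frac,
        single_side_decoy_frac=scenario.single_side_decoy_frac,
        ortholog_noise=scenario.ortholog_noise,
    )
    rng = rng_from(seeds[1])
    effects_a: dict[str, list[float]] = {}
    effects_b: dict[str, list[float]] = {}
    n_stages = len(PROGRESSION_GROUPS)
    for p in manifest.planted:
        sign = float(rng.choice([-1.0, 1.0]))
        onset = int(rng.integers(1, n_stages))  # stage index at which the effect appears
        steps = {onset}
        if onset < n_stages - 1 and rng.random() < scenario.second_step_prob:
            steps.add(int(rng.integers(onset + 1, n_stages)))
        offsets = [0.0] * n_stages
        level = 0.0
        for s in range(1, n_stages):
            if s in steps:
                level += sign * scenario.planted_log2fc
            offsets[s] = level
        for gid in (p["coding_a"], p["ncrna_a"]):
            effects_a[gid] = offsets
        for gid in (p["coding_b"], p["ncrna_b"]):
            effects_b[gid] = [0.0, sign * scenario.planted_log2fc]
        p["sign"] = sign
        p["onset_stage"] = onset
        p["log2fc_per_transition"] = [offsets[s] - offsets[s - 1] for s in range(1, n_stages)]
        p["log2fc_b"] = sign * scenario.planted_log2fc
    manifest.params.update(
        {
            "scenario": scenario.name,
            "planted_log2fc": scenario.planted_log2fc,
            "base_mean": scenario.base_mean,
            "dispersion": scenario.dispersion,
            "n_reps": scenario.n_reps,
        }
    )
    expr_a = generate_counts(
        ann_a,
        "progression",
        planted_log2fc=effects_a,
        base_mean=scenario.base_mean,
        dispersion=scenario.dispersion,
        n_reps=scenario.n_reps,
        seed=seeds[2],
    )
    expr_b = generate_counts(
        ann_b,
        "two_group",
        planted_log2fc=effects_b,
        base_mean=scenario.base_mean,
        dispersion=scenario.dispersion,
        n_reps=scenario.n_reps,
        seed=seeds[3],
    )
    return SimulatedStudy(
        ann_a=ann_a, ann_b=ann_b, orthomap=orthomap, expr_a=expr_a, expr_b=expr_b, manifest=manifest
    )


def write_study(study: SimulatedStudy, outdir, seed: int | None = None) -> None:
    """Write every study component in the external formats of the pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comment = None if seed is None else f"seed={seed}"
    write_bed(study.ann_a, outdir / "annotation_a.bed", header_comment=comment)
    write_bed(study.ann_b, outdir / "annotation_b.bed", header_comment=comment)
    write_orthologs(study.orthomap, outdir / "orthologs.tsv", header_comment=comment)
    write_expression(
        study.expr_a, outdir / "counts_a.tsv", outdir / "design_a.tsv", header_comment=comment
    )
    write_expression(
        study.expr_b, outdir / "counts_b.tsv", outdir / "design_b.tsv", header_comment=comment
    )
    study.manifest.to_json(outdir / "manifest.json")
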