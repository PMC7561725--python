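"""Pair coding genes with lncRNA neighbours and classify their orientation.

Builds a six-gene toy chromosome, finds every coding/lncRNA pair within
100 kb, and prints the gap and orientation class of each pair.  A "divergent"
pair is the classic head-to-head arrangement in which the two transcription
start sites face each other — the configuration of a shared bidirectional
promoter.
"""

from lncscreen import AnnotationSet, GeneRecord, pair_within_window

ann = AnnotationSet("human")
for gene_id, start, end, strand, biotype in [
    ("oncogene_A", 100_000, 240_000, "+", "coding"),
    ("lnc_head_to_head", 60_000, 95_000, "-", "lncRNA"),  # divergent partner
    ("oncogene_B", 500_000, 560_000, "+", "coding"),
    ("lnc_antisense", 520_000, 540_000, "-", "lncRNA"),  # overlaps its coding gene
    ("lnc_downstream", 620_000, 640_000, "+", "lncRNA"),  # tandem, 60 kb away
    ("lnc_far", 2_000_000, 2_010_000, "-", "lncRNA"),  # > 100 kb from everything
]:
    ann.add(GeneRecord(gene_id, "chr12", start, end, strand, biotype, "human"))

pairs = pair_within_window(ann, window_bp=100_000)
print(f"{len(pairs)} coding/lncRNA pairs within 100 kb:")
for p in pairs:
    print(
        f"  {p.coding.gene_id:12s} + {p.ncrna.gene_id:18s} "
        f"gap={p.distance_bp:>6d} bp  {p.orientation}"
    )
print(
    "\nThe far lncRNA is unpaired: its gap exceeds the window. Distances are"
    " inter-interval gaps (0 = overlapping), the bedtools-window convention."
)
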