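"""Built-in annotations for tests, examples, and simulation defaults.

Two annotations are provided:

``toy_annotation``
    A five-gene miniature of the mitochondrial ribosomal gene cluster
    (tRNA - rRNA - tRNA - rRNA - tRNA) on a 1 kb genome.  Small enough
    that every classification decision can be checked by hand.

``mouse_like_annotation``
    The full murine heavy-strand gene order (leader, mtF, 12S, mtV,
    16S, mtL1, mtNd1, ... mtCytb, mtT) with the light-strand tRNA
    clusters, the mtAtp8/6 and mtNd4/4L bicistrons, and the
    non-canonical mRNA-mRNA junctions (mtAtp8/6--mtCo3,
    mtNd5--mtCytb).  Gene lengths are realistic for mammalian mtDNA
    (tRNAs ~70 nt, 12S ~950 nt, 16S ~1580 nt) but the coordinates are
    synthetic: genes are laid out abutting in the real order rather
    than copied from a reference assembly, which is all the interval
    statistics need.
"""

from __future__ import annotations

from .annotation import GeneFeature, GenomeAnnotation, build_annotation

__all__ = [
    "toy_annotation",
    "mouse_like_annotation",
    "example_cleavage_probs",
    "RRNA_CLUSTER_UNITS",
]


def toy_annotation() -> GenomeAnnotation:
    """tF-rnS-tV-rnL-tL1 on a 1,000 nt genome, all heavy strand."""
    feats = [
        GeneFeature("tF", 0, 70, "+", "tRNA"),
        GeneFeature("rnS", 70, 370, "+", "rRNA"),
        GeneFeature("tV", 370, 440, "+", "tRNA"),
        GeneFeature("rnL", 440, 900, "+", "rRNA"),
        GeneFeature("tL1", 900, 970, "+", "tRNA"),
    ]
    return build_annotation(feats, genome_length=1000, genome_id="toy")


# (name, length, strand, biotype) in heavy-strand genome order; light-strand
# tRNA clusters interleave at their true positions in the gene order.
_MOUSE_ORDER = [
    ("leader", 16, "+", "leader"),  # heavy-strand promoter 5' leader of mtF
    ("mtF", 70, "+", "tRNA"),
    ("mt-Rnr1", 955, "+", "rRNA"),  # 12S
    ("mtV", 69, "+", "tRNA"),
    ("mt-Rnr2", 1582, "+", "rRNA"),  # 16S
    ("mtL1", 75, "+", "tRNA"),
    ("mtNd1", 957, "+", "mRNA"),
    ("mtI", 69, "+", "tRNA"),
    ("mtQ", 72, "-", "tRNA"),
    ("mtM", 68, "+", "tRNA"),
    ("mtNd2", 1038, "+", "mRNA"),
    ("mtW", 69, "+", "tRNA"),
    ("mtA", 69, "-", "tRNA"),
    ("mtN", 73, "-", "tRNA"),
    ("mtC", 66, "-", "tRNA"),
    ("mtY", 68, "-", "tRNA"),
    ("mtCo1", 1545, "+", "mRNA"),
    ("mtS1", 70, "-", "tRNA"),
    ("mtD", 68, "+", "tRNA"),
    ("mtCo2", 684, "+", "mRNA"),
    ("mtK", 70, "+", "tRNA"),
    ("mtAtp8", 204, "+", "mRNA"),
    ("mtAtp6", 681, "+", "mRNA"),
    ("mtCo3", 784, "+", "mRNA"),
    ("mtG", 68, "+", "tRNA"),
    ("mtNd3", 348, "+", "mRNA"),
    ("mtR", 66, "+", "tRNA"),
    ("mtNd4l", 297, "+", "mRNA"),
    ("mtNd4", 1378, "+", "mRNA"),
    ("mtH", 69, "+", "tRNA"),
    ("mtS2", 59, "+", "tRNA"),
    ("mtL2", 71, "+", "tRNA"),
    ("mtNd5", 1824, "+", "mRNA"),
    ("mtNd6", 519, "-", "mRNA"),
    ("mtE", 69, "-", "tRNA"),
    ("mtCytb", 1144, "+", "mRNA"),
    ("mtT", 67, "+", "tRNA"),
    ("mtP", 66, "-", "tRNA"),
]

#: declared multi-gene units: the two murine bicistrons
MOUSE_UNIT_SPEC = {
    "mtAtp8/6": ["mtAtp8", "mtAtp6"],
    "mtNd4/4l": ["mtNd4l", "mtNd4"],
}


def mouse_like_annotation() -> GenomeAnnotation:
    """Murine heavy/light-strand gene order with synthetic abutting coordinates."""
    feats = []
    pos = 0
    for name, length, strand, biotype in _MOUSE_ORDER:
        feats.append(GeneFeature(name, pos, pos + length, strand, biotype))
        pos += length
    genome_length = pos + 880  # control region downstream of mtP
    return build_annotation(
        feats,
        genome_length=genome_length,
        genome_id="chrM_synthetic",
        unit_spec=MOUSE_UNIT_SPEC,
    )


#: heavy-strand units of the ribosomal gene cluster (the RNA4 region) plus
#: its downstream tricistron partner mtNd1
RRNA_CLUSTER_UNITS = ("leader", "mtF", "mt-Rnr1", "mtV", "mt-Rnr2", "mtL1", "mtNd1")

#: canonical junctions whose cleavage collapses when the methylation-dependent
#: tRNA-punctuation machinery fails: the rRNA gene cluster, the mtNd2 region
#: and the mtR--mtNd4/4l region
_METHYLATION_SENSITIVE = (
    "leader|mtF",
    "mtF|mt-Rnr1",
    "mt-Rnr1|mtV",
    "mtV|mt-Rnr2",
    "mt-Rnr2|mtL1",
    "mtL1|mtNd1",
    "mtM|mtNd2",
    "mtNd2|mtW",
    "mtNd3|mtR",
    "mtR|mtNd4/4l",
)


def example_cleavage_probs(annotation, condition: str) -> dict[str, float]:
    """Per-junction cleavage probabilities for the two study conditions.

    ``"ctrl"``: efficient canonical cleavage (0.97) with slightly less
    efficient non-canonical sites (0.90), so a few percent of reads stay
    unprocessed and the most abundant intermediates sit at mRNA--mRNA
    junctions.  ``"ko"``: cleavage at the methylation-sensitive canonical
    junctions drops to 0.55 while non-canonical sites are untouched,
    concentrating the unprocessed pool in the rRNA gene cluster.
    """
    if condition not in ("ctrl", "ko"):
        raise ValueError(f"unknown condition {condition!r}")
    probs: dict[str, float] = {}
    for j in annotation.junctions:
        p = 0.97 if j.kind == "canonical" else 0.90
        if condition == "ko" and j.label in _METHYLATION_SENSITIVE:
            p = 0.55
        probs[j.label] = p
    return probs
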