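"""Gene annotation of a polycistronic mitochondrial genome.

Mammalian mitochondrial DNA is transcribed as near-genome-length
polycistronic precursors in which most mRNAs and rRNAs are flanked by
tRNAs.  Nucleolytic excision of the tRNAs ("tRNA punctuation") releases
the mature transcripts, so the annotation of gene boundaries doubles as
the catalogue of cleavage sites.  This module loads such an annotation
(GFF3 or BED), groups genes into processed transcript units (single
genes by default; bicistrons such as mtAtp8/6 and mtNd4/4L are declared
explicitly), and derives the ordered list of unit-to-unit junctions,
each labelled canonical (tRNA-flanked, an mtRNase P/Z substrate) or
non-canonical (cleaved by other machinery, e.g. the mtAtp8/6--mtCo3
site).

Coordinates are 0-based half-open throughout; GFF3 input (1-based,
closed) is converted on load.  All interval arithmetic operates on the
linearised genome with the origin used by the alignment reference, so
features that span the origin must be supplied as two arcs.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field, replace

import gffutils

__all__ = [
    "GeneFeature",
    "ProcessedUnit",
    "Junction",
    "GenomeAnnotation",
    "load_annotation",
    "build_annotation",
    "junction_kind",
    "trna_centres",
    "write_bed",
]

BIOTYPES = frozenset({"mRNA", "rRNA", "tRNA", "leader", "noncoding"})

#: biotypes whose presence at a cleavage site makes the junction canonical
_PUNCTUATION_BIOTYPE = "tRNA"


@dataclass(frozen=True)
class GeneFeature:
    """One gene on the linearised genome (0-based, half-open)."""

    name: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.name}: unknown biotype {self.biotype!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.name}: invalid interval [{self.start}, {self.end})")

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ProcessedUnit:
    """A mature transcript unit: one gene, or a declared multi-gene unit.

    ``start``/``end`` give the unit span including any declared UTR
    extensions; a read whose both ends land within tolerance of this
    span is a fully processed molecule of this species.
    """

    name: str
    members: tuple[str, ...]
    start: int
    end: int
    strand: str
    biotypes: tuple[str, ...]

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2

    @property
    def is_coding_like(self) -> bool:
        """True if the unit carries an mRNA or rRNA (a stable mature species)."""
        return any(b in ("mRNA", "rRNA") for b in self.biotypes)


@dataclass(frozen=True)
class Junction:
    """A cleavage site between two adjacent processed units on one strand."""

    upstream_unit: str
    downstream_unit: str
    position: int
    strand: str
    kind: str  # "canonical" | "non-canonical"

    @property
    def label(self) -> str:
        return f"{self.upstream_unit}|{self.downstream_unit}"


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotations."""


@dataclass
class GenomeAnnotation:
    """Validated annotation: ordered features, units, and derived junctions."""

    genome_length: int
    genome_id: str
    features: tuple[GeneFeature, ...]
    units: tuple[ProcessedUnit, ...] = field(default=())
    junctions: tuple[Junction, ...] = field(default=())

    def __post_init__(self) -> None:
        self.features = tuple(sorted(self.features, key=lambda f: (f.start, f.end)))
        self._validate_features()
        if not self.units:
            raise AnnotationError(
                "construct annotations via build_annotation()/load_annotation()"
            )
        self.junctions = self._derive_junctions()
        self._by_name = {f.name: f for f in self.features}
        self._unit_by_name = {u.name: u for u in self.units}

    # -- construction helpers -------------------------------------------------

    def _validate_features(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.name in seen:
                raise AnnotationError(f"duplicate gene name {f.name!r}")
            seen.add(f.name)
            if f.end > self.genome_length:
                raise AnnotationError(
                    f"{f.name}: end {f.end} outside genome of length {self.genome_length}"
                )

    def _derive_junctions(self) -> tuple[Junction, ...]:
        """Unit-to-unit transition points, per strand, in genome order.

        The junction position is the transition coordinate between the two
        unit spans (end of the upstream-in-genome unit).  A junction is
        canonical iff a tRNA gene abuts it on either side.
        """
        out: list[Junction] = []
        for strand in ("+", "-"):
            strand_units = sorted(
                (u for u in self.units if u.strand == strand), key=lambda u: u.start
            )
            for left, right in zip(strand_units, strand_units[1:]):
                position = left.end
                # genome-order flanks; strand only affects which is "upstream"
                flank_left = self._member_feature(left.members[-1])
                flank_right = self._member_feature(right.members[0])
                kind = (
                    "canonical"
                    if _PUNCTUATION_BIOTYPE in (flank_left.biotype, flank_right.biotype)
                    else "non-canonical"
                )
                if strand == "+":
                    up, down = left.name, right.name
                else:
                    up, down = right.name, left.name
                out.append(Junction(up, down, position, strand, kind))
        return tuple(out)

    def _member_feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise AnnotationError(f"unknown feature {name!r}")

    # -- queries --------------------------------------------------------------

    def feature(self, name: str) -> GeneFeature:
        try:
            return self._by_name[name]
        except KeyError:
            raise AnnotationError(f"unknown feature {name!r}") from None

    def unit(self, name: str) -> ProcessedUnit:
        try:
            return self._unit_by_name[name]
        except KeyError:
            raise AnnotationError(f"unknown unit {name!r}") from None

    def units_on_strand(self, strand: str) -> tuple[ProcessedUnit, ...]:
        return tuple(u for u in self.units if u.strand == strand)

    def trnas(self, strand: str | None = None) -> tuple[GeneFeature, ...]:
        return tuple(
            f
            for f in self.features
            if f.biotype == "tRNA" and (strand is None or f.strand == strand)
        )

    def junction(self, label: str) -> Junction:
        for j in self.junctions:
            if j.label == label:
                return j
        raise AnnotationError(f"unknown junction {label!r}")


# -- unit construction --------------------------------------------------------


def _build_units(
    features: tuple[GeneFeature, ...],
    unit_spec: dict[str, list[str]] | None,
    utr_spec: dict[str, tuple[int, int]] | None,
) -> tuple[ProcessedUnit, ...]:
    """Group features into processed units.

    ``unit_spec`` maps a unit name to its ordered member genes (e.g.
    ``{"mtAtp8/6": ["mtAtp8", "mtAtp6"]}``); every gene not named there
    becomes its own single-gene unit.  ``utr_spec`` maps a unit name to
    (5'-extension, 3'-extension) in nt applied strand-aware.
    """
    unit_spec = unit_spec or {}
    utr_spec = utr_spec or {}
    by_name = {f.name: f for f in features}
    claimed: set[str] = set()
    units: list[ProcessedUnit] = []

    for uname, members in unit_spec.items():
        feats = []
        for m in members:
            if m not in by_name:
                raise AnnotationError(f"unit {uname!r}: member {m!r} not in annotation")
            if m in claimed:
                raise AnnotationError(f"gene {m!r} assigned to more than one unit")
            claimed.add(m)
            feats.append(by_name[m])
        strands = {f.strand for f in feats}
        if len(strands) != 1:
            raise AnnotationError(f"unit {uname!r}: members on mixed strands")
        feats_sorted = sorted(feats, key=lambda f: f.start)
        # contiguity: no unclaimed same-strand gene may fall inside the span
        span = (feats_sorted[0].start, feats_sorted[-1].end)
        for f in features:
            if f.name in members or f.strand != feats_sorted[0].strand:
                continue
            if f.start >= span[0] and f.end <= span[1]:
                raise AnnotationError(
                    f"unit {uname!r}: members not contiguous ({f.name!r} intervenes)"
                )
        units.append(
            ProcessedUnit(
                name=uname,
                members=tuple(f.name for f in feats_sorted),
                start=span[0],
                end=span[1],
                strand=feats_sorted[0].strand,
                biotypes=tuple(f.biotype for f in feats_sorted),
            )
        )

    for f in features:
        if f.name not in claimed:
            units.append(
                ProcessedUnit(
                    name=f.name,
                    members=(f.name,),
                    start=f.start,
                    end=f.end,
                    strand=f.strand,
                    biotypes=(f.biotype,),
                )
            )

    # UTR extensions, strand-aware
    extended: list[ProcessedUnit] = []
    for u in units:
        five, three = utr_spec.get(u.name, (0, 0))
        if u.strand == "+":
            u = replace(u, start=u.start - five, end=u.end + three)
        else:
            u = replace(u, start=u.start - three, end=u.end + five)
        if u.start < 0:
            raise AnnotationError(f"unit {u.name!r}: UTR extension crosses coordinate 0")
        extended.append(u)
    units = sorted(extended, key=lambda u: (u.start, u.end))

    # reject overlapping same-strand units
    for strand in ("+", "-"):
        su = [u for u in units if u.strand == strand]
        for a, b in zip(su, su[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"same-strand units overlap: {a.name!r} and {b.name!r}"
                )
    return tuple(units)


def build_annotation(
    features,
    genome_length: int,
    genome_id: str = "toy",
    unit_spec: dict[str, list[str]] | None = None,
    utr_spec: dict[str, tuple[int, int]] | None = None,
) -> GenomeAnnotation:
    """Assemble a validated :class:`GenomeAnnotation` from features in memory."""
    feats = tuple(features)
    units = _build_units(feats, unit_spec, utr_spec)
    ann = GenomeAnnotation.__new__(GenomeAnnotation)
    ann.genome_length = genome_length
    ann.genome_id = genome_id
    ann.features = tuple(sorted(feats, key=lambda f: (f.start, f.end)))
    ann.units = units
    ann._validate_features()
    ann.junctions = ann._derive_junctions()
    ann._by_name = {f.name: f for f in ann.features}
    ann._unit_by_name = {u.name: u for u in ann.units}
    return ann


# -- file I/O -----------------------------------------------------------------


def _read_bed_features(path: str) -> tuple[list[GeneFeature], str]:
    feats = []
    genome_id = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise AnnotationError(f"{path}:{lineno}: need >=6 BED columns")
            chrom, start, end, name, _score, strand = cols[:6]
            biotype = cols[6] if len(cols) > 6 else None
            if biotype is None:
                raise AnnotationError(
                    f"{path}:{lineno}: BED annotation needs a 7th 'biotype' column"
                )
            genome_id = genome_id or chrom
            feats.append(GeneFeature(name, int(start), int(end), strand, biotype))
    return feats, genome_id or "unknown"


def _read_gff3_features(path: str) -> tuple[list[GeneFeature], str]:
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    genome_id = ""
    gene_like = {"gene", "tRNA", "rRNA", "mRNA", "transcript"}
    for rec in db.all_features():
        if rec.featuretype not in gene_like:
            continue
        name = rec.attributes.get("Name", rec.attributes.get("ID", [rec.id]))[0]
        biotype = rec.attributes.get(
            "biotype", rec.attributes.get("gene_biotype", [None])
        )[0]
        if biotype is None:
            biotype = rec.featuretype if rec.featuretype in BIOTYPES else None
        if biotype is None:
            raise AnnotationError(f"feature {name!r}: no biotype attribute")
        genome_id = genome_id or rec.seqid
        # GFF3 is 1-based closed; convert to 0-based half-open
        feats.append(GeneFeature(name, rec.start - 1, rec.end, rec.strand, biotype))
    return feats, genome_id or "unknown"


def load_annotation(
    path: str,
    genome_length: int,
    unit_spec: dict[str, list[str]] | None = None,
    utr_spec: dict[str, tuple[int, int]] | None = None,
) -> GenomeAnnotation:
    """Load a GFF3 or BED annotation and derive units and junctions.

    Format is chosen by extension (.gff/.gff3 vs anything else = BED6+1
    with a biotype in column 7).  ``unit_spec`` and ``utr_spec`` come
    from the analysis config (multi-gene units and UTR extents are
    declarations, not inferences).
    """
    ext = os.path.splitext(path)[1].lower()
    if ext in (".gff", ".gff3"):
        feats, genome_id = _read_gff3_features(path)
    else:
        feats, genome_id = _read_bed_features(path)
    if not feats:
        raise AnnotationError(f"{path}: no gene features found")
    return build_annotation(
        feats, genome_length, genome_id, unit_spec=unit_spec, utr_spec=utr_spec
    )


def write_bed(annotation: GenomeAnnotation, path: str) -> None:
    """Write features as BED6+1 (biotype in column 7); round-trips with load."""
    with open(path, "w") as fh:
        for f in annotation.features:
            fh.write(
                f"{annotation.genome_id}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\t{f.biotype}\n"
            )


# -- small public queries -----------------------------------------------------


def junction_kind(annotation: GenomeAnnotation, junction: Junction | str) -> str:
    """Canonical iff a tRNA abuts the cleavage site on either side."""
    label = junction if isinstance(junction, str) else junction.label
    return annotation.junction(label).kind


def trna_centres(annotation: GenomeAnnotation) -> dict[str, int]:
    """Midpoint (floor) of every tRNA; the coverage anchor for read-through calls."""
    return {f.name: f.centre for f in annotation.trnas()}
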