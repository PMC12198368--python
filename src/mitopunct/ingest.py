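"""Ingestion of aligned long-read records.

Direct RNA nanopore reads arrive either as BED6 intervals (the output of
``bedtools bamtobed`` on a sorted BAM) or as SAM/BAM alignments, which
are collapsed here to the same reference spans.  Either route yields an
immutable :class:`ReadSet` whose ``total_aligned`` is the denominator of
every downstream fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pysam

__all__ = ["AlignedRead", "ReadSet", "read_bed", "read_alignments"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignedRead:
    """One primary alignment span on the mitochondrial contig."""

    read_id: str
    start: int
    end: int
    strand: str
    sample_id: str
    mapq: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"read {self.read_id!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id!r}: bad strand {self.strand!r}")

    def five_prime(self) -> int:
        """Strand-aware 5' terminus (last covered base on '-' reads)."""
        return self.start if self.strand == "+" else self.end - 1

    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class ReadSet:
    sample_id: str
    reads: tuple[AlignedRead, ...]

    @property
    def total_aligned(self) -> int:
        return len(self.reads)


class BedParseError(ValueError):
    pass


def read_bed(path: str, sample_id: str) -> ReadSet:
    """Parse a BED6 file of read alignments into a :class:`ReadSet`.

    Malformed lines raise :class:`BedParseError` naming the line; an
    empty file gives an empty set with a warning (an empty sample is a
    data problem, not a parse problem).
    """
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise BedParseError(f"{path}:{lineno}: expected >=6 columns")
            _chrom, start_s, end_s, name, score, strand = cols[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start:
                raise BedParseError(f"{path}:{lineno}: end {end} <= start {start}")
            if strand not in ("+", "-"):
                raise BedParseError(f"{path}:{lineno}: missing/invalid strand")
            mapq = int(score) if score.isdigit() else 0
            reads.append(AlignedRead(name, start, end, strand, sample_id, mapq))
    if not reads:
        log.warning("%s: no reads parsed for sample %s", path, sample_id)
    return ReadSet(sample_id, tuple(reads))


def read_alignments(
    path: str,
    sample_id: str,
    min_mapq: int = 0,
    contig: str | None = None,
) -> ReadSet:
    """Read primary alignments from SAM/BAM into a :class:`ReadSet`.

    Each primary alignment contributes one record spanning its outer
    reference coordinates — identical to running ``bedtools bamtobed``
    and :func:`read_bed` on the same file (spliced alignments collapse
    to min start..max end).  Secondary and supplementary records are
    dropped; no MAPQ filter is applied by default.  Reads on contigs
    other than ``contig`` (when given) are skipped with a logged count.
    """
    reads: list[AlignedRead] = []
    skipped_contig = 0
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if contig is not None and aln.reference_name != contig:
                skipped_contig += 1
                continue
            strand = "-" if aln.is_reverse else "+"
            reads.append(
                AlignedRead(
                    aln.query_name,
                    aln.reference_start,
                    aln.reference_end,
                    strand,
                    sample_id,
                    aln.mapping_quality,
                )
            )
    if skipped_contig:
        log.info(
            "%s: skipped %d reads on non-target contigs", path, skipped_contig
        )
    return ReadSet(sample_id, tuple(reads))
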