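"""Summary statistics over read classifications.

The quantities here mirror how transcript-processing defects are
quantified from direct RNA long reads:

* per-sample counts of processed vs unprocessed reads and per-junction
  group counts;
* the composition of the unprocessed pool, with rare groups pooled into
  "other";
* the delta-unprocessed statistic: for each junction group,
  ``100 * (count_ko / total_ko - count_ctrl / total_ctrl)`` — the
  difference, in percentage points of *total* aligned reads, between a
  knockout and a control sample;
* the composition of the positive deltas (each positive delta as a
  percentage of the summed positive deltas);
* tRNA read-through fractions (reads covering a tRNA's centre, relative
  to reads containing the neighbouring mRNA/rRNA unit);
* 5' start-site tables for reads containing a given gene.

Deltas are fractions of total aligned reads; compositions are fractions
of the unprocessed pool.  Output tables carry both counts and
percentages so that no information is lost to rounding.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

from .annotation import GenomeAnnotation
from .classify import (
    CAT_INTERNAL,
    AnalysisParams,
    ReadClassification,
    reads_containing_unit,
)
from .ingest import ReadSet

__all__ = [
    "SampleSummary",
    "DeltaRecord",
    "summarize",
    "composition",
    "delta_unprocessed",
    "positive_delta_composition",
    "PositiveDeltaComposition",
    "trna_passthrough_fraction",
    "PassthroughResult",
    "five_prime_start_table",
]

log = logging.getLogger(__name__)

#: label under which groupless internal fragments appear in compositions
INTERNAL_LABEL = "internal_fragment"


@dataclass(frozen=True)
class SampleSummary:
    sample_id: str
    total_reads: int
    processed_count: int
    unprocessed_count: int
    group_counts: dict[str, int] = field(default_factory=dict)
    unit_counts: dict[str, int] = field(default_factory=dict)
    internal_count: int = 0

    @property
    def unprocessed_fraction(self) -> float:
        return self.unprocessed_count / self.total_reads if self.total_reads else 0.0


@dataclass(frozen=True)
class DeltaRecord:
    junction_label: str
    delta: float  # percentage points of total reads (ko - ctrl)
    ko_fraction: float  # percent of total ko reads
    ctrl_fraction: float  # percent of total ctrl reads
    visualised: bool


def summarize(
    classifications: Iterable[ReadClassification], sample_id: str
) -> SampleSummary:
    """Tally one sample's classifications into exact counts."""
    total = processed = unprocessed = internal = 0
    groups: Counter[str] = Counter()
    units: Counter[str] = Counter()
    for c in classifications:
        total += 1
        if c.status == "processed":
            processed += 1
            units[c.unit] += 1
        else:
            unprocessed += 1
            if c.category == CAT_INTERNAL:
                internal += 1
            elif c.group:
                groups[c.group_label] += 1
    if total == 0:
        log.warning("sample %s: no classifications to summarise", sample_id)
    return SampleSummary(
        sample_id=sample_id,
        total_reads=total,
        processed_count=processed,
        unprocessed_count=unprocessed,
        group_counts=dict(groups),
        unit_counts=dict(units),
        internal_count=internal,
    )


def composition(summary: SampleSummary, pool_threshold: float = 0.02) -> dict[str, float]:
    """Shares of the unprocessed pool per junction group.

    Internal fragments (unprocessed but groupless) appear under their
    own label so shares sum to 1 before pooling; groups below
    ``pool_threshold`` are merged into "other".
    """
    if summary.unprocessed_count == 0:
        return {}
    denom = summary.unprocessed_count
    raw: dict[str, float] = {
        label: n / denom for label, n in summary.group_counts.items()
    }
    if summary.internal_count:
        raw[INTERNAL_LABEL] = summary.internal_count / denom
    ungrouped = denom - sum(summary.group_counts.values()) - summary.internal_count
    if ungrouped:
        raw["ungrouped"] = ungrouped / denom
    pooled: dict[str, float] = {}
    other = 0.0
    for label, share in sorted(raw.items(), key=lambda kv: (-kv[1], kv[0])):
        if share < pool_threshold:
            other += share
        else:
            pooled[label] = share
    if other:
        pooled["other"] = other
    return pooled


def delta_unprocessed(
    ko: SampleSummary,
    ctrl: SampleSummary,
    vis_threshold: float = 0.5,
) -> list[DeltaRecord]:
    """Per-junction difference in percent of total reads between samples.

    One record per junction-group label present in either sample (an
    absent label counts 0).  Records with |delta| <= ``vis_threshold``
    percentage points are flagged non-visualised but kept in the table.
    """
    if ko.total_reads == 0 or ctrl.total_reads == 0:
        raise ValueError("both samples need a non-zero read total")
    labels = sorted(set(ko.group_counts) | set(ctrl.group_counts))
    out = []
    for label in labels:
        f_ko = 100.0 * ko.group_counts.get(label, 0) / ko.total_reads
        f_ctrl = 100.0 * ctrl.group_counts.get(label, 0) / ctrl.total_reads
        delta = f_ko - f_ctrl
        out.append(
            DeltaRecord(label, delta, f_ko, f_ctrl, abs(delta) > vis_threshold)
        )
    out.sort(key=lambda r: -r.delta)
    return out


class PositiveDeltaComposition(NamedTuple):
    shares: dict[str, float]  # label -> percent of total positive delta (all positives)
    included: dict[str, float]  # subset meeting the minimum contribution
    excluded: dict[str, float]  # positives below the minimum contribution


def positive_delta_composition(
    deltas: Iterable[DeltaRecord], min_contribution: float = 0.02
) -> PositiveDeltaComposition:
    """Express each positive delta as a percent of the summed positive deltas.

    Negative deltas are discarded; the positive ones are summed to a
    total signal and each is expressed as a percentage of it.  Labels
    contributing less than ``min_contribution`` (fraction) are reported
    separately rather than shown.
    """
    positives = {r.junction_label: r.delta for r in deltas if r.delta > 0}
    if not positives:
        log.warning("no positive deltas; empty composition")
        return PositiveDeltaComposition({}, {}, {})
    total = sum(positives.values())
    shares = {label: 100.0 * d / total for label, d in positives.items()}
    included = {l: s for l, s in shares.items() if s >= 100.0 * min_contribution}
    excluded = {l: s for l, s in shares.items() if s < 100.0 * min_contribution}
    return PositiveDeltaComposition(shares, included, excluded)


class PassthroughResult(NamedTuple):
    fraction: float  # read-through fraction relative to the neighbour unit
    n_passing: int
    n_neighbour: int
    neighbour_unit: str
    reported: bool  # passing reads exceed the abundance cutoff of total reads


def _downstream_neighbour(annotation: GenomeAnnotation, trna_name: str):
    """Nearest same-strand mRNA/rRNA unit downstream in the direction of transcription."""
    t = annotation.feature(trna_name)
    if t.biotype != "tRNA":
        raise ValueError(f"{trna_name!r} is not a tRNA")
    candidates = [
        u
        for u in annotation.units_on_strand(t.strand)
        if u.is_coding_like
        and (u.start >= t.end if t.strand == "+" else u.end <= t.start)
    ]
    if not candidates:
        raise ValueError(f"{trna_name!r} has no downstream mRNA/rRNA neighbour")
    return min(candidates, key=lambda u: u.start - t.end if t.strand == "+" else t.start - u.end)


def trna_passthrough_fraction(
    reads: ReadSet,
    trna_name: str,
    annotation: GenomeAnnotation,
    params: AnalysisParams = AnalysisParams(),
) -> PassthroughResult:
    """Fraction of the neighbouring transcript's reads reading through a tRNA.

    Denominator: reads containing the nearest downstream same-strand
    mRNA/rRNA unit (under ``params.contain_rule``).  Numerator: those
    whose span also covers the tRNA's centre — molecules in which the
    tRNA was not excised.  The species is flagged unreported when the
    passing reads are fewer than ``params.abundance_cutoff`` of total.
    """
    t = annotation.feature(trna_name)
    neighbour = _downstream_neighbour(annotation, trna_name)
    containing = reads_containing_unit(reads, neighbour, params)
    centre = t.centre
    passing = [r for r in containing if r.start <= centre < r.end]
    frac = len(passing) / len(containing) if containing else math.nan
    reported = (
        reads.total_aligned > 0
        and len(passing) / reads.total_aligned > params.abundance_cutoff
    )
    return PassthroughResult(frac, len(passing), len(containing), neighbour.name, reported)


def five_prime_start_table(
    reads: ReadSet,
    gene: str,
    annotation: GenomeAnnotation,
    params: AnalysisParams = AnalysisParams(),
    reference_starts: Iterable[int] = (),
) -> pd.DataFrame:
    """Distribution of strand-aware 5' positions of reads containing a gene.

    Selects reads containing the gene's unit (``contain_rule``), bins
    their 5' termini by exact position, and reports counts, the percent
    of selected reads, the offset from the gene's annotated 5' end
    (negative = upstream, e.g. retained leader), and whether the
    position is a configured reference start site (e.g. the heavy-strand
    promoter).
    """
    # the gene may be a member of a multi-gene unit; find its unit
    unit = None
    for u in annotation.units:
        if gene in u.members or u.name == gene:
            unit = u
            break
    if unit is None:
        raise ValueError(f"unknown gene {gene!r}")
    feat = annotation.feature(gene) if gene in {f.name for f in annotation.features} else None
    anchor = feat if feat is not None else unit
    annotated_5p = anchor.start if unit.strand == "+" else anchor.end - 1

    selected = reads_containing_unit(reads, unit, params)
    counts = Counter(r.five_prime() for r in selected)
    refs = set(reference_starts)
    rows = []
    for pos in sorted(counts):
        n = counts[pos]
        offset = pos - annotated_5p if unit.strand == "+" else annotated_5p - pos
        rows.append(
            {
                "position": pos,
                "count": n,
                "pct_of_selected": 100.0 * n / len(selected),
                "offset_from_annotated_start": offset,
                "is_reference_start": pos in refs,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "position",
            "count",
            "pct_of_selected",
            "offset_from_annotated_start",
            "is_reference_start",
        ],
    )
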