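# Methods

## Classification model

The unit of analysis is one primary alignment span per long read
(0-based, half-open coordinates on the linearised mitochondrial
genome). The annotation defines *processed units*: single genes by
default, multi-gene units (the murine mtAtp8/6 and mtNd4/4l bicistrons)
and UTR extensions by declaration in the config. Junctions are the
transition points between adjacent same-strand units; a junction is
*canonical* when a tRNA abuts it on either side (a substrate of the
mtRNase P/Z punctuation machinery) and *non-canonical* otherwise.

A read is processed iff both ends fall within a tolerance `tol`
(default 20 nt) of one same-strand unit's boundaries; when several
units qualify (possible only for overlapping tolerance windows), the
unit with the smallest total end offset is taken. All other reads are
unprocessed and subdivided:

* **junction** — the tol-trimmed span overlaps ≥ 2 units; the group is
  the ordered unit list along the read's strand, labelled
  `gene1,gene2,…`. Trimming `tol` nt from each read end before the
  overlap test prevents end jitter of the same magnitude as the
  classification tolerance from creating spurious group members. Reads
  shorter than `2·tol` are trimmed symmetrically down to a 1–2 nt
  core, which keeps the rule invariant under genome mirroring.
* **boundary_extension** — one unit plus unannotated flanking sequence
  beyond `tol`; the flank appears in the group label as
  `5'ext(unit)` / `3'ext(unit)`.
* **internal_fragment** — both ends strictly inside one unit. These are
  counted in the unprocessed total (the partition
  processed + unprocessed = total is exact) but carry no junction
  group, because the junction statistics are cleavage-centric and a
  fragment evidences degradation, not failed cleavage.
* **intergenic/antisense** — no same-strand unit overlapped. Group
  labels are prefixed `antisense:` so they can never collide with
  sense junction groups in delta tables.

Antisense reads are never matched to opposite-strand units: direct RNA
sequencing is strand-specific. The systematic 5′ truncation of direct
RNA nanopore reads (~12 ± 2 nt) is deliberately not corrected before
classification; the 20 nt tolerance absorbs it (the analytic tail
probability of a rounded N(12, 2) exceeding 20 nt is ~2·10⁻⁵), and the
5′ start-site table serves as the diagnostic for the offset
distribution instead.

## Summary statistics

* Unprocessed fraction: unprocessed / total aligned reads.
* Composition: junction-group counts over the unprocessed pool;
  internal fragments appear under their own label so shares sum to 1;
  groups under `pool_threshold` (default 2 %) merge into "other".
* Δ-unprocessed: `100·(n_j/N)_KO − 100·(n_j/N)_Ctrl` per junction
  group, denominators being each sample's **total** aligned reads
  (compositions, by contrast, use the unprocessed pool — both
  denominators are stated in the output headers). Labels absent from
  one sample count zero; |Δ| ≤ 0.5 pp records are flagged
  non-visualised but retained.
* Positive-Δ composition: positive deltas as percentages of their sum;
  labels under 2 % of the total are reported separately, not dropped.
* tRNA read-through: among reads containing the tRNA's nearest
  *downstream* same-strand mRNA/rRNA unit (the direction of
  transcription matches the punctuation reading; "nearest flanking" was
  the alternative and is not used), the fraction whose span covers the
  tRNA's centre (`floor((start+end)/2)`). Species whose passing reads
  are under `abundance_cutoff` (default 0.01 %) of total reads are
  flagged unreported.
* "Containing a unit" defaults to covering the unit's centre point
  (`contain_rule: centre`); `full` and `frac50` are available for
  sensitivity analysis.
* 5′ start-site table: exact-position bins of strand-aware 5′ termini
  of reads containing a gene, with offsets from the annotated start
  (negative = upstream, e.g. a retained promoter-proximal leader) and
  optional reference start-site annotation.

No significance machinery is attached to Δ: it is a descriptive
statistic; counts are always emitted alongside percentages (rounded to
4 decimals in tables) so nothing is lost to rounding.

## Synthetic data generator

Each simulated read is produced by: (1) drawing a transcription start
site by weight — defaults are one promoter per strand at the strand's
first unit, weighted by the strand's mRNA/rRNA unit count so the
heavy strand dominates as in poly(A)-selected mitochondrial data;
(2) materialising the precursor to the strand terminator; (3) cleaving
each internal junction independently with its `cleavage_prob`
(`hierarchical: true` instead forbids cutting any junction 3′ of an
uncut one — useful for contrasting signatures of a strict 5′→3′
hierarchy against the independent model); (4) sampling one fragment
with probability ∝ length × stability × poly(A) capture;
(5) applying 5′ truncation `round(N(12, 2))` clipped at 0, strand-aware,
plus optional 3′ jitter, then clipping to the genome.

Turnover is a static retention weight (default 1.0 processed vs 0.35
unprocessed — unprocessed intermediates clear faster), not a kinetic
model: steady-state composition is all the downstream statistics
observe. Poly(A) capture acts on the fragment's 3′-terminal biotype
(default mRNA 0.9, rRNA 0.25, tRNA/leader/noncoding 0.05): a fragment
ending in an mRNA is captured efficiently even if mostly rRNA, which
reproduces the enrichment of rRNA-cluster precursors attached to mtNd1.
The capture values are modelling placeholders, not measured quantities.

The two named study conditions (`example_cleavage_probs`) are: control —
canonical junctions cleaved at 0.97, non-canonical at 0.90 (non-canonical
processing is inherently less efficient, so a healthy sample's
unprocessed pool is dominated by mRNA–mRNA junctions); knockout —
cleavage at the canonical junctions of the rRNA gene cluster, the mtNd2
region and the mtR–mtNd4/4l region reduced to 0.55, non-canonical sites
untouched. With 20,000 reads per sample these settings give ~3 %
(control) and ~11 % (knockout) unprocessed reads.

Every read carries a truth record (source fragment, uncleaved junctions,
pre-noise span), and `recovery_report` scores estimated per-junction
unprocessed incidence against the realised truth. An exact enumeration
oracle over all cleavage patterns (test code) provides the expected
fractions for Monte-Carlo comparison.

What the generator does **not** emulate: base-level sequence or error
profiles (no FASTQ), chimeric/split alignments, replicate structure,
template switching, degradation from the 3′ end, or transcription
termination heterogeneity. Passing recovery tests therefore show that
the statistics are correct for interval-level data with these noise
modes — not that every artefact of real nanopore runs is handled.

## Annotations

`toy_annotation` is a five-gene miniature of the rRNA cluster
(tRNA–rRNA–tRNA–rRNA–tRNA on 1 kb) for hand-checkable tests.
`mouse_like_annotation` carries the real murine heavy/light-strand gene
order, biotypes and bicistrons with realistic gene lengths, but
synthetic abutting coordinates; the interval statistics depend only on
order and adjacency, not on absolute positions. The heavy-strand 5′
leader upstream of mtF is an explicit `leader` unit so reads starting
at the promoter classify as unprocessed (leader-retaining) rather than
unmapped. Features spanning the circular origin must be supplied as two
arcs; all queries operate on the linearisation used by the alignment
reference. One simplification: a junction between same-strand units
separated by an opposite-strand cluster (e.g. mtW→mtCo1 across the
light-strand tRNA cluster) is represented as a single site, although
in vivo the two flanks are cleaved by different machineries.

## Numerical and design choices

* Coordinates are converted from GFF3 (1-based closed) to 0-based
  half-open on load; BED is native. Round-tripping an annotation
  through BED is exact.
* `min_mapq` defaults to 0 — no filter beyond primary-alignment
  status, to avoid silently adding filters the classification rule does
  not assume. Spliced alignments collapse to their outer reference
  span, matching `bedtools bamtobed` on the same records (verified
  against bamtobed in the test suite).
* Pooled analysis of merged replicate files is the default; per-replicate
  totals can be kept by ingesting replicates as separate samples.
* Unit ties in the processed rule are broken by the smallest total end
  offset; exact ties cannot occur between non-overlapping units.
* 0/0 fully-processed fractions are NaN, never 0.
* Problem sizes in the validation suite: 1,000 random reads for exact
  oracle equivalence; 10,000 simulated reads for truncation-robustness
  and parameter-recovery checks (3 binomial SE bands); 20,000 reads per
  sample in the worked example and the acceptance script.

## Known limitations

* No novel start/end-site calling: reads are classified only against
  given boundaries.
* Circular-origin-spanning reads are not reassembled across the origin.
* The Δ statistic compares two pooled samples; replicate-level variance
  is not modelled.
* Simulator turnover and capture weights are plausible defaults, not
  fitted parameters; absolute unprocessed percentages from the
  simulator should be read as qualitative.
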