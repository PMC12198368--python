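# mitopunct

Processing analysis for long-read mitochondrial transcriptomes.

Mammalian mitochondrial DNA is transcribed as near-genome-length
polycistronic precursors. Mature mRNAs and rRNAs are released by
nucleolytic cleavage at the tRNAs that flank them (the tRNA punctuation
model); a handful of junctions lack a tRNA and are cleaved by other
machinery. When processing fails, direct RNA long reads no longer match
the boundaries of single transcript units — they span gene junctions.
`mitopunct` quantifies this from aligned nanopore reads: it classifies
every read as processed or unprocessed against an annotated genome,
accounts for which junctions the unprocessed reads span, and compares
conditions (e.g. a knockout against a control). It is aimed at anyone
studying mitochondrial RNA processing, precursor turnover, or
mitoribosome assembly with ONT direct RNA sequencing.

## Model and statistics

A read with span $[s, e)$ on strand $\sigma$ is **processed** iff some
annotated transcript unit $u$ on $\sigma$ (single genes by default;
declared bicistrons and UTR extensions included) satisfies

$$|s - u_{start}| \le \tau \quad\text{and}\quad |e - u_{end}| \le \tau,$$

with tolerance $\tau = 20$ nt by default. The tolerance absorbs the
platform's systematic loss of ~12 ± 2 nt at read 5′ ends. Every other
read is **unprocessed** and is assigned a *junction group*: the ordered
units its span overlaps (after trimming $\tau$ nt from each end to
suppress jitter-induced members), labelled `gene1,gene2,…`.

Per-junction enrichment between a knockout (KO) and control (Ctrl)
sample is the **Δ-unprocessed** statistic, in percentage points of total
aligned reads:

$$\Delta_{j} = 100\left(\frac{n_{j}^{KO}}{N^{KO}} - \frac{n_{j}^{Ctrl}}{N^{Ctrl}}\right)$$

where $n_j$ counts unprocessed reads in junction group $j$ and $N$ is
the sample's total aligned reads. Positive Δ values are additionally
expressed as percentages of their sum (the total unprocessed signal).
Further metrics: composition of the unprocessed pool (groups < 2 %
pooled into "other"), per-unit fully-processed fractions, tRNA
read-through fractions (reads covering a tRNA's centre relative to reads
containing its downstream mRNA/rRNA), and 5′ start-site tables.

A built-in simulator generates reads with the same generative structure
— per-junction cleavage failure, faster turnover of unprocessed
intermediates, poly(A)-capture bias, 5′ truncation — and exports
per-read ground truth, so every statistic can be validated by parameter
recovery.

## Worked example

Simulate a KO-vs-control comparison on the built-in mouse-like
annotation (real murine gene order and bicistrons, synthetic abutting
coordinates) and run the whole pipeline:

```sh
mitopunct run --config examples/mouse_ko_vs_ctrl.yaml --seed 7 --out out/
```

`out/summary.tsv`:

```text
sample  total_reads  processed  unprocessed  unprocessed_pct_of_total
ctrl    20000        19393      607          3.035
ko      20000        17792      2208         11.04
```

The control behaves like a healthy sample — ~3 % of reads are
unprocessed, and `out/composition.tsv` shows its unprocessed pool
dominated by the tRNA-less (non-canonical) junctions `mtNd5,mtCytb` and
`mtAtp8/6,mtCo3`, which are inherently cleaved less efficiently. In the
KO, cleavage failure at the methylation-sensitive canonical junctions
lifts the unprocessed fraction to ~11 %, and `out/delta.tsv` ranks the
junction groups by Δ:

```text
junction_label      delta  ko_fraction  ctrl_fraction  visualised
mtNd3,mtR,mtNd4/4l  1.505  1.52         0.015          True
mtR,mtNd4/4l        1.385  1.475        0.09           True
mt-Rnr2,mtL1,mtNd1  1.04   1.055        0.015          True
```

i.e. the intermediates that accumulate sit in the rRNA gene cluster and
the mtR–mtNd4/4l region, exactly the junctions whose cleavage the
simulation impaired — while the non-canonical junctions contribute no
positive Δ. `out/trna_passthrough.tsv` shows the fraction of 16S reads
reading through the tRNA mtV rising from ~1 % (ctrl) to ~38 % (ko).

The same steps are available as individual subcommands
(`mitopunct simulate | classify | summarize | delta | trna-metrics`)
and as library functions (`classify_read`, `summarize`,
`delta_unprocessed`, …).

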