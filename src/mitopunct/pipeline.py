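"""Config-driven pipeline orchestration: classify -> summarise -> delta -> report.

The pipeline is configured by one YAML file and writes plain TSV tables
plus a JSON run manifest with content hashes of every input, so that
two runs with identical hashes and seeds are byte-identical (the
manifest's timestamp is the only field allowed to differ).

Config schema (all coordinates 0-based half-open)::

    genome:
      builtin: mouse_like | toy          # or:
      annotation: path.bed|path.gff3
      length: 16299
      units: {"mtAtp8/6": [mtAtp8, mtAtp6]}
      utr: {"mtNd1": [0, 30]}            # [5' ext, 3' ext] in nt
    params: {tol: 20, pool_threshold: 0.02, delta_vis_threshold: 0.5,
             abundance_cutoff: 0.0001, contain_rule: centre}
    samples:
      ko:   {bed: ko.bed}                # or {alignments: ko.bam}
      ctrl: {bed: ctrl.bed}
    simulate:                            # used when a sample has no file
      ko:   {n_reads: 20000, default_cleavage: 0.9,
             cleavage_prob: {"mtF|mt-Rnr1": 0.55}}
      ctrl: {n_reads: 20000, default_cleavage: 0.97}
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import zlib
from dataclasses import asdict

import pandas as pd
import yaml

from . import __version__
from .annotation import GenomeAnnotation, load_annotation
from .classify import AnalysisParams, ReadClassification, classify_readset
from .fixtures import example_cleavage_probs, mouse_like_annotation, toy_annotation
from .ingest import ReadSet, read_alignments, read_bed
from .simulate import SimulationConfig, simulate_reads
from .stats import (
    composition,
    delta_unprocessed,
    positive_delta_composition,
    summarize,
    trna_passthrough_fraction,
)

__all__ = ["load_config", "annotation_from_config", "params_from_config", "run_pipeline"]

log = logging.getLogger(__name__)

_BUILTINS = {"mouse_like": mouse_like_annotation, "toy": toy_annotation}


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path: str) -> dict:
    if not os.path.exists(path):
        raise PipelineError("config", f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "genome" not in cfg:
        raise PipelineError("config", "missing 'genome' section")
    return cfg


def annotation_from_config(cfg: dict) -> GenomeAnnotation:
    g = cfg["genome"]
    if "builtin" in g:
        try:
            return _BUILTINS[g["builtin"]]()
        except KeyError:
            raise PipelineError("annotation", f"unknown builtin {g['builtin']!r}") from None
    path = g.get("annotation")
    if not path or not os.path.exists(path):
        raise PipelineError("annotation", f"annotation file not found: {path}")
    utr = {k: tuple(v) for k, v in (g.get("utr") or {}).items()}
    return load_annotation(
        path, genome_length=g["length"], unit_spec=g.get("units"), utr_spec=utr
    )


def params_from_config(cfg: dict) -> AnalysisParams:
    return AnalysisParams(**(cfg.get("params") or {}))


def _load_sample(
    name: str, spec: dict, cfg: dict, annotation: GenomeAnnotation, seed: int | None
) -> ReadSet:
    if spec and "bed" in spec:
        if not os.path.exists(spec["bed"]):
            raise PipelineError("ingest", f"sample {name}: missing BED {spec['bed']}")
        return read_bed(spec["bed"], name)
    if spec and "alignments" in spec:
        if not os.path.exists(spec["alignments"]):
            raise PipelineError(
                "ingest", f"sample {name}: missing alignments {spec['alignments']}"
            )
        return read_alignments(
            spec["alignments"], name, min_mapq=spec.get("min_mapq", 0)
        )
    sim_specs = cfg.get("simulate") or {}
    if name in sim_specs:
        s = dict(sim_specs[name])
        # `condition: ko|ctrl` expands to the built-in per-junction cleavage
        # profile; explicit cleavage_prob entries override it
        condition = s.pop("condition", None)
        if condition is not None:
            probs = example_cleavage_probs(annotation, condition)
            probs.update(s.get("cleavage_prob") or {})
            s["cleavage_prob"] = probs
        s.setdefault("seed", seed if seed is not None else 0)
        if seed is not None:
            # per-sample seeds derived from the run seed, kept below 2**31;
            # crc32 is stable across processes (unlike hash())
            s["seed"] = (s["seed"] + zlib.crc32(name.encode()) % 10007) % (2**31)
        sim = SimulationConfig(annotation=annotation, sample_id=name, **s)
        reads, _truth = simulate_reads(sim)
        return reads
    raise PipelineError("ingest", f"sample {name}: no input file and no simulate entry")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def classifications_table(classifications: list[ReadClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [c.read_id for c in classifications],
            "sample": [c.sample_id for c in classifications],
            "status": [c.status for c in classifications],
            "category": [c.category for c in classifications],
            "unit_or_group": [
                c.unit if c.unit else (c.group_label or "") for c in classifications
            ],
            "trna_5prime": [c.trna_5prime for c in classifications],
            "trna_3prime": [c.trna_3prime for c in classifications],
            "trna_centres_covered": [
                ",".join(c.trna_centres_covered) for c in classifications
            ],
        }
    )


def run_pipeline(config_path: str, out_dir: str, seed: int | None = None) -> dict:
    """Execute classify -> summarize -> delta -> report; return the manifest.

    Writes per-sample classification TSVs, the five summary tables
    (summary, composition, delta, positive-delta composition, tRNA
    passthrough) and ``manifest.json`` into ``out_dir``.  Expects
    exactly the samples named ``ko`` and ``ctrl`` for the delta stage;
    with other sample names the delta tables are skipped.
    """
    t0 = time.time()
    cfg = load_config(config_path)
    out = {}
    os.makedirs(out_dir, exist_ok=True)

    annotation = annotation_from_config(cfg)
    params = params_from_config(cfg)
    sample_specs = cfg.get("samples") or {}
    if not sample_specs and cfg.get("simulate"):
        sample_specs = {name: {} for name in cfg["simulate"]}
    if not sample_specs:
        raise PipelineError("config", "no samples configured")

    summaries = {}
    for name, spec in sample_specs.items():
        reads = _load_sample(name, spec, cfg, annotation, seed)
        log.info("sample %s: %d aligned reads in", name, reads.total_aligned)
        cls = classify_readset(reads, annotation, params)
        classifications_table(cls).to_csv(
            os.path.join(out_dir, f"classified_{name}.tsv"), sep="\t", index=False
        )
        summaries[name] = (reads, summarize(cls, name))
        log.info(
            "sample %s: %d processed / %d unprocessed",
            name,
            summaries[name][1].processed_count,
            summaries[name][1].unprocessed_count,
        )

    # summary table (denominator: total aligned reads)
    pd.DataFrame(
        [
            {
                "sample": name,
                "total_reads": s.total_reads,
                "processed": s.processed_count,
                "unprocessed": s.unprocessed_count,
                "unprocessed_pct_of_total": round(100.0 * s.unprocessed_fraction, 4),
            }
            for name, (_r, s) in summaries.items()
        ]
    ).to_csv(os.path.join(out_dir, "summary.tsv"), sep="\t", index=False)

    # composition of the unprocessed pool per sample
    comp_rows = []
    for name, (_r, s) in summaries.items():
        for label, share in composition(s, params.pool_threshold).items():
            comp_rows.append(
                {
                    "sample": name,
                    "group": label,
                    "share_of_unprocessed_pool": round(share, 6),
                }
            )
    pd.DataFrame(comp_rows).to_csv(
        os.path.join(out_dir, "composition.tsv"), sep="\t", index=False
    )

    # delta tables (denominator: total aligned reads, in percent)
    if {"ko", "ctrl"} <= set(summaries):
        deltas = delta_unprocessed(
            summaries["ko"][1], summaries["ctrl"][1], params.delta_vis_threshold
        )
        delta_df = pd.DataFrame([asdict(d) for d in deltas])
        for col in ("delta", "ko_fraction", "ctrl_fraction"):
            delta_df[col] = delta_df[col].round(4)
        delta_df.to_csv(os.path.join(out_dir, "delta.tsv"), sep="\t", index=False)
        pdc = positive_delta_composition(deltas)
        pd.DataFrame(
            [
                {
                    "group": label,
                    "pct_of_positive_delta": round(share, 4),
                    "included": label in pdc.included,
                }
                for label, share in pdc.shares.items()
            ]
        ).to_csv(os.path.join(out_dir, "positive_delta.tsv"), sep="\t", index=False)
    else:
        log.info("samples are not named ko/ctrl; skipping delta tables")

    # tRNA read-through per sample
    pt_rows = []
    for name, (reads, _s) in summaries.items():
        for t in annotation.trnas():
            try:
                res = trna_passthrough_fraction(reads, t.name, annotation, params)
            except ValueError:
                continue
            pt_rows.append(
                {
                    "sample": name,
                    "trna": t.name,
                    "neighbour_unit": res.neighbour_unit,
                    "passthrough_fraction": res.fraction,
                    "n_passing": res.n_passing,
                    "n_neighbour_reads": res.n_neighbour,
                    "reported": res.reported,
                }
            )
    pd.DataFrame(pt_rows).to_csv(
        os.path.join(out_dir, "trna_passthrough.tsv"), sep="\t", index=False
    )

    manifest = {
        "tool": "mitopunct",
        "version": __version__,
        "seed": seed,
        "config_sha256": _sha256(config_path),
        "annotation": cfg["genome"].get("builtin")
        or _sha256(cfg["genome"]["annotation"]),
        "input_sha256": {
            name: _sha256(spec["bed"])
            for name, spec in sample_specs.items()
            if spec and "bed" in spec
        },
        "samples": {
            name: {"total_reads": s.total_reads} for name, (_r, s) in summaries.items()
        },
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
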