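"""Independent reference implementations used only to check the package.

These deliberately share no code with :mod:`mitopunct`: the classifier
oracle is a direct nested-loop transcription of the classification
rules, and the simulator oracle computes expected junction-spanning
fractions by exhaustive enumeration of cleavage patterns rather than by
sampling.
"""

from __future__ import annotations

import itertools
import math


def brute_force_classify(read, annotation, tol):
    """(status, category, unit, group) by exhaustive loops over units."""
    units = [u for u in annotation.units if u.strand == read.strand]

    matches = []
    for u in units:
        if abs(read.start - u.start) <= tol and abs(read.end - u.end) <= tol:
            matches.append((abs(read.start - u.start) + abs(read.end - u.end), u.name))
    if matches:
        matches.sort()
        return ("processed", "processed", matches[0][1], ())

    trim = min(tol, (read.end - read.start - 1) // 2)
    lo, hi = read.start + trim, read.end - trim
    hit = []
    for u in sorted(units, key=lambda u: u.start):
        if min(hi, u.end) - max(lo, u.start) > 0:
            hit.append(u)
    if not hit:
        over = []
        for u in sorted(annotation.units, key=lambda u: u.start):
            if min(read.end, u.end) - max(read.start, u.start) > 0:
                over.append(u.name)
        if read.strand == "-":
            over = over[::-1]
        return ("unprocessed", "intergenic/antisense", None, tuple(over))
    if len(hit) >= 2:
        names = [u.name for u in hit]
        if read.strand == "-":
            names = names[::-1]
        return ("unprocessed", "junction", None, tuple(names))
    u = hit[0]
    left = read.start < u.start - tol
    right = read.end > u.end + tol
    if not left and not right:
        return ("unprocessed", "internal_fragment", u.name, ())
    names = []
    if left:
        names.append(f"5'ext({u.name})" if read.strand == "+" else f"3'ext({u.name})")
    names.append(u.name)
    if right:
        names.append(f"3'ext({u.name})" if read.strand == "+" else f"5'ext({u.name})")
    if read.strand == "-":
        names = names[::-1]
    return ("unprocessed", "boundary_extension", None, tuple(names))


def _fragment_weight(config, frag_units, frag_span):
    length = frag_span[1] - frag_span[0]
    processed = len(frag_units) == 1 and frag_span == (
        frag_units[0].start,
        frag_units[0].end,
    )
    stab = config.stability["processed" if processed else "unprocessed"]
    capture = config.polya_capture.get(frag_units[-1].biotypes[-1], 0.05)
    return length * stab * capture


def enumerate_junction_span_probs(config) -> dict[str, float]:
    """Expected fraction of emitted reads whose fragment spans each junction.

    Enumerates every cleavage pattern of every transcription unit
    (independent cleavage mode only) and accumulates exact
    fragment-selection probabilities — the closed-form counterpart of
    one Monte-Carlo draw in the simulator.
    """
    from mitopunct.simulate import _transcript_layout

    out: dict[str, float] = {j.label: 0.0 for j in config.annotation.junctions}
    total_w = sum(w for _p, _s, w in config.tss)
    for pos, strand, w_tss in config.tss:
        span, units, junctions = _transcript_layout(config, pos, strand)
        probs = [config.junction_p(j.label) for j in junctions]
        for pattern in itertools.product([True, False], repeat=len(junctions)):
            p_pattern = math.prod(
                p if c else 1 - p for p, c in zip(probs, pattern)
            )
            if p_pattern == 0.0:
                continue
            fragments = []
            run = []
            for k, u in enumerate(units):
                run.append(u)
                if k == len(units) - 1 or pattern[k]:
                    lo = min(v.start for v in run)
                    hi = max(v.end for v in run)
                    fragments.append((list(run), (max(lo, span[0]), min(hi, span[1]))))
                    run = []
            weights = [_fragment_weight(config, fu, fs) for fu, fs in fragments]
            total = sum(weights)
            for (fu, _fs), wf in zip(fragments, weights):
                names = {u.name for u in fu}
                for j, c in zip(junctions, pattern):
                    if not c and j.upstream_unit in names and j.downstream_unit in names:
                        out[j.label] += (w_tss / total_w) * p_pattern * wf / total
    return out


def tally_tsv_summary(rows):
    """Naive single-pass tally over per-read classification rows.

    ``rows`` are dicts with 'status' and 'unit_or_group' / 'category'
    keys as written to the classification TSV.
    """
    processed = unprocessed = 0
    groups: dict[str, int] = {}
    for r in rows:
        if r["status"] == "processed":
            processed += 1
        else:
            unprocessed += 1
            if r["category"] in (
                "junction",
                "boundary_extension",
                "intergenic/antisense",
            ):
                label = r["unit_or_group"]
                if label:  # reads overlapping no unit have no group
                    groups[label] = groups.get(label, 0) + 1
    return processed, unprocessed, groups
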