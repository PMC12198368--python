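import numpy as np
import pytest

from mitopunct import (
    ReadSet,
    SampleSummary,
    classify_readset,
    composition,
    delta_unprocessed,
    five_prime_start_table,
    positive_delta_composition,
    summarize,
    trna_passthrough_fraction,
)
from mitopunct.classify import AnalysisParams
from .conftest import make_read
from .oracles import tally_tsv_summary


def make_summary(sample_id, total, groups, processed=None):
    unprocessed = sum(groups.values())
    return SampleSummary(
        sample_id=sample_id,
        total_reads=total,
        processed_count=total - unprocessed if processed is None else processed,
        unprocessed_count=unprocessed,
        group_counts=dict(groups),
    )


# -- summarize ----------------------------------------------------------------


def test_summarize_fraction(toy_ann, params):
    reads = [make_read(70, 370, read_id=f"p{i}") for i in range(961)]
    reads += [make_read(72, 500, read_id=f"u{i}") for i in range(39)]
    s = summarize(classify_readset(ReadSet("s", tuple(reads)), toy_ann, params), "s")
    assert s.total_reads == 1000
    assert s.unprocessed_fraction == pytest.approx(0.039)
    assert s.group_counts == {"rnS,tV,rnL": 39}


def test_summarize_all_processed(toy_ann, params):
    reads = tuple(make_read(70, 370, read_id=f"p{i}") for i in range(10))
    s = summarize(classify_readset(ReadSet("s", reads), toy_ann, params), "s")
    assert s.unprocessed_fraction == 0
    assert s.unit_counts == {"rnS": 10}


def test_summarize_matches_naive_tally(toy_ann, params, random_toy_reads):
    """Module counts equal a one-pass tally over the per-read table rows."""
    cls = classify_readset(random_toy_reads, toy_ann, params)
    s = summarize(cls, "rand")
    rows = [
        {
            "status": c.status,
            "category": c.category,
            "unit_or_group": c.unit if c.unit else (c.group_label or ""),
        }
        for c in cls
    ]
    processed, unprocessed, groups = tally_tsv_summary(rows)
    assert (s.processed_count, s.unprocessed_count) == (processed, unprocessed)
    assert s.group_counts == groups
    assert sum(s.group_counts.values()) <= s.unprocessed_count


# -- composition --------------------------------------------------------------


def test_composition_pools_below_threshold():
    s = make_summary("s", 2000, {"A": 500, "B": 300, "C": 180, "D": 15, "E": 5})
    comp = composition(s, pool_threshold=0.02)
    assert comp == pytest.approx({"A": 0.50, "B": 0.30, "C": 0.18, "other": 0.02})


def test_composition_shares_sum_to_one_before_pooling(toy_ann, params, random_toy_reads):
    s = summarize(classify_readset(random_toy_reads, toy_ann, params), "rand")
    comp = composition(s, pool_threshold=0.0)
    assert sum(comp.values()) == pytest.approx(1.0, abs=1e-12)


def test_composition_single_group_and_all_below():
    only = make_summary("s", 100, {"A": 10})
    assert composition(only, 0.02) == {"A": 1.0}
    tiny = make_summary("s", 100000, {chr(65 + i): 1 for i in range(10)})
    assert composition(tiny, 0.5) == pytest.approx({"other": 1.0})


def test_composition_empty_pool():
    assert composition(make_summary("s", 100, {}), 0.02) == {}


# -- delta (knockout minus control, pp of total reads) ------------------------


def test_delta_hand_computed_value():
    ko = make_summary("ko", 1000, {"J": 392})
    ctrl = make_summary("ctrl", 1000, {"J": 36})
    (rec,) = delta_unprocessed(ko, ctrl, vis_threshold=0.5)
    assert rec.delta == pytest.approx(35.6)
    assert rec.ko_fraction == pytest.approx(39.2)
    assert rec.ctrl_fraction == pytest.approx(3.6)
    assert rec.visualised


def test_delta_identical_samples_zero():
    s = make_summary("a", 500, {"J1": 30, "J2": 10})
    for rec in delta_unprocessed(s, s, 0.5):
        assert rec.delta == 0.0
        assert not rec.visualised


def test_delta_antisymmetric_under_swap():
    ko = make_summary("ko", 1000, {"J1": 392, "J2": 5})
    ctrl = make_summary("ctrl", 2000, {"J1": 36, "J3": 40})
    fwd = {r.junction_label: r.delta for r in delta_unprocessed(ko, ctrl, 0.5)}
    rev = {r.junction_label: r.delta for r in delta_unprocessed(ctrl, ko, 0.5)}
    assert fwd.keys() == rev.keys()
    for label in fwd:
        assert fwd[label] == pytest.approx(-rev[label])


def test_delta_absent_label_counts_zero():
    ko = make_summary("ko", 1000, {"J1": 100})
    ctrl = make_summary("ctrl", 1000, {"J2": 50})
    recs = {r.junction_label: r for r in delta_unprocessed(ko, ctrl, 0.5)}
    assert recs["J1"].ctrl_fraction == 0.0
    assert recs["J2"].ko_fraction == 0.0
    assert recs["J2"].delta == pytest.approx(-5.0)


def test_delta_scale_invariance():
    ko = make_summary("ko", 1000, {"J1": 392, "J2": 7})
    ko10 = make_summary("ko", 10000, {"J1": 3920, "J2": 70})
    ctrl = make_summary("ctrl", 500, {"J1": 18})
    ctrl10 = make_summary("ctrl", 5000, {"J1": 180})
    a = {r.junction_label: r.delta for r in delta_unprocessed(ko, ctrl, 0.5)}
    b = {r.junction_label: r.delta for r in delta_unprocessed(ko10, ctrl10, 0.5)}
    assert a == pytest.approx(b)


def test_delta_visualisation_threshold():
    ko = make_summary("ko", 1000, {"big": 100, "small": 4})
    ctrl = make_summary("ctrl", 1000, {"big": 10, "small": 1})
    recs = {r.junction_label: r for r in delta_unprocessed(ko, ctrl, 0.5)}
    assert recs["big"].visualised  # |9.0| > 0.5
    assert not recs["small"].visualised  # |0.3| <= 0.5, retained in the table


def test_delta_zero_total_rejected():
    empty = SampleSummary("e", 0, 0, 0)
    ok = make_summary("ko", 10, {"J": 1})
    with pytest.raises(ValueError):
        delta_unprocessed(ok, empty)


# -- positive-delta composition ----------------------------------------------


def test_positive_delta_composition_arithmetic():
    ko = make_summary("ko", 100, {"J1": 8, "J2": 2})
    ctrl = make_summary("ctrl", 100, {"J3": 5})
    res = positive_delta_composition(delta_unprocessed(ko, ctrl, 0.5))
    assert res.shares == pytest.approx({"J1": 80.0, "J2": 20.0})
    assert res.included == res.shares
    assert res.excluded == {}


def test_positive_delta_single_positive():
    ko = make_summary("ko", 100, {"J": 3})
    ctrl = make_summary("ctrl", 100, {})
    res = positive_delta_composition(delta_unprocessed(ko, ctrl, 0.5))
    assert res.shares == {"J": 100.0}


def test_positive_delta_minimum_contribution_filter():
    ko = make_summary("ko", 1000, {"J1": 980, "J2": 10, "J3": 10})
    ctrl = make_summary("ctrl", 1000, {})
    res = positive_delta_composition(delta_unprocessed(ko, ctrl, 0.5), 0.02)
    assert set(res.included) == {"J1"}
    assert set(res.excluded) == {"J2", "J3"}
    assert sum(res.shares.values()) == pytest.approx(100.0)


def test_positive_delta_no_positives_is_empty():
    ko = make_summary("ko", 100, {})
    ctrl = make_summary("ctrl", 100, {"J": 10})
    res = positive_delta_composition(delta_unprocessed(ko, ctrl, 0.5))
    assert res.shares == {}


# -- tRNA read-through --------------------------------------------------------


def test_passthrough_fraction_counts(toy_ann, params):
    """12 of 100 rnL-containing reads also cover the tV centre -> 0.12."""
    reads = [make_read(445, 895, read_id=f"n{i}") for i in range(88)]
    reads += [make_read(380, 895, read_id=f"p{i}") for i in range(12)]
    rs = ReadSet("s", tuple(reads))
    res = trna_passthrough_fraction(rs, "tV", toy_ann, params)
    assert res.neighbour_unit == "rnL"
    assert res.fraction == pytest.approx(0.12)
    assert res.reported


def test_passthrough_limits(toy_ann, params):
    none = ReadSet("s", tuple(make_read(445, 895, read_id=f"r{i}") for i in range(10)))
    assert trna_passthrough_fraction(none, "tV", toy_ann, params).fraction == 0.0
    allthrough = ReadSet(
        "s", tuple(make_read(360, 895, read_id=f"r{i}") for i in range(10))
    )
    assert trna_passthrough_fraction(allthrough, "tV", toy_ann, params).fraction == 1.0


def test_passthrough_abundance_cutoff(toy_ann):
    """A single passing read among many totals falls below the 0.01% cutoff."""
    reads = [make_read(445, 895, read_id=f"n{i}") for i in range(20000)]
    reads.append(make_read(380, 895, read_id="p"))
    rs = ReadSet("s", tuple(reads))
    res = trna_passthrough_fraction(rs, "tV", toy_ann, AnalysisParams())
    assert res.n_passing == 1
    assert not res.reported  # 1/20001 < 0.0001


def test_passthrough_requires_downstream_neighbour(toy_ann, params):
    rs = ReadSet("s", (make_read(445, 895),))
    with pytest.raises(ValueError, match="no downstream"):
        trna_passthrough_fraction(rs, "tL1", toy_ann, params)


# -- 5' start-site table ------------------------------------------------------


def test_start_table_single_bin(toy_ann, params):
    rs = ReadSet("s", tuple(make_read(12, 970, read_id=f"r{i}") for i in range(10)))
    tab = five_prime_start_table(rs, "tF", toy_ann, params)
    assert len(tab) == 1
    row = tab.iloc[0]
    assert (row["position"], row["count"], row["pct_of_selected"]) == (12, 10, 100.0)
    assert row["offset_from_annotated_start"] == 12


def test_start_table_reference_start_annotation(toy_ann, params):
    rs = ReadSet("s", tuple(make_read(0, 970, read_id=f"r{i}") for i in range(3)))
    tab = five_prime_start_table(rs, "tF", toy_ann, params, reference_starts=[0])
    assert bool(tab.iloc[0]["is_reference_start"])


def test_start_table_modal_bin_under_truncation(toy_ann, params):
    """5' offsets drawn at ~12 +/- 2 nt put the modal start within [10, 14]."""
    rng = np.random.default_rng(11)
    offsets = np.clip(np.rint(rng.normal(12, 2, size=500)).astype(int), 0, None)
    rs = ReadSet(
        "s",
        tuple(
            make_read(int(o), 970, read_id=f"r{i}") for i, o in enumerate(offsets)
        ),
    )
    tab = five_prime_start_table(rs, "tF", toy_ann, params)
    modal = tab.loc[tab["count"].idxmax(), "position"]
    assert 10 <= modal <= 14
    assert tab["count"].sum() == 500
    assert tab["pct_of_selected"].sum() == pytest.approx(100.0)


def test_start_table_negative_offsets_for_leader_retaining_reads():
    """Reads starting upstream of the annotated gene start report negative offsets."""
    from mitopunct import GeneFeature, build_annotation

    ann = build_annotation(
        [
            GeneFeature("leader", 0, 30, "+", "leader"),
            GeneFeature("tF", 30, 100, "+", "tRNA"),
            GeneFeature("rnS", 100, 400, "+", "rRNA"),
        ],
        genome_length=500,
    )
    rs = ReadSet("s", (make_read(5, 400, read_id="hsp"),))
    tab = five_prime_start_table(rs, "tF", ann, AnalysisParams())
    assert tab.iloc[0]["offset_from_annotated_start"] == -25
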