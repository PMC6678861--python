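"""Gene-segment mapping, separation filter, SAR classification and
frequency/partner-count bookkeeping, checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from sarloc.colocalization import (
    ColocalizationIndex,
    FrequencyResult,
    classify_sar,
    filter_intra_by_separation,
    genes_colocalized,
    map_genes_to_segments,
    partner_count_summary,
    pooled_frequency,
    regulon_index_sets,
)

from conftest import make_genes, make_interactions, make_regulon
from oracles import classify_bruteforce, random_instance


# ---------------------------------------------------------------------------
# gene -> segment mapping
# ---------------------------------------------------------------------------

def test_map_genes_to_segments_distance_rule():
    genes = make_genes(
        [
            ("gA", "chr1", "+", 5000),   # gap to [6000, 8000] = 1000 -> mapped
            ("gB", "chr1", "+", 3499),   # gap 2501 -> not mapped
            ("gC", "chr1", "+", 7000),   # inside the interval -> mapped
            ("gD", "chr2", "+", 7000),   # other chromosome, same coordinates
        ]
    )
    inter = make_interactions(
        [("s1", "chr1", 6000, 8000), ("s2", "chr2", 50000, 52000)], [("s1", "s2")]
    )
    gmap = map_genes_to_segments(genes, inter, tss_window_bp=2500)
    assert gmap.segments_of("gA") == {"s1"}
    assert gmap.segments_of("gB") == frozenset()
    assert gmap.segments_of("gC") == {"s1"}
    assert gmap.segments_of("gD") == frozenset()
    # containment maps at any window, including zero
    gmap0 = map_genes_to_segments(genes, inter, tss_window_bp=0)
    assert gmap0.segments_of("gC") == {"s1"}
    assert gmap0.segments_of("gA") == frozenset()


# ---------------------------------------------------------------------------
# intra separation filter
# ---------------------------------------------------------------------------

def _sep_toy():
    return make_interactions(
        [
            ("a", "chr1", 9500, 10500),     # midpoint 10000
            ("b", "chr1", 68500, 69500),    # midpoint 69000
            ("c", "chr1", 69500, 70500),    # midpoint 70000
            ("d", "chr2", 1, 1000),
        ],
        [("a", "b"), ("a", "c"), ("a", "d")],
    )


def test_filter_intra_by_separation_boundary():
    inter = _sep_toy()
    kept = filter_intra_by_separation(inter, min_sep_bp=60000)
    pairs = set(map(tuple, kept.pairs[["seg_a", "seg_b"]].to_numpy()))
    assert ("a", "b") not in pairs     # 59000 < 60000
    assert ("a", "c") in pairs         # exactly 60000 kept
    assert ("a", "d") in pairs         # inter pairs untouched


def test_filter_intra_monotone_in_cutoff():
    inter = _sep_toy()
    n = [filter_intra_by_separation(inter, s).n_pairs for s in (0, 30000, 59000, 60001, 10**6)]
    assert n == sorted(n, reverse=True)


# ---------------------------------------------------------------------------
# pairwise colocalization
# ---------------------------------------------------------------------------

def _coloc_toy():
    genes = make_genes(
        [("g1", "chr1", "+", 500), ("g2", "chr1", "+", 500), ("g3", "chr2", "+", 500)]
    )
    inter = make_interactions(
        [("s1", "chr1", 1, 1000), ("s3", "chr2", 1, 1000), ("s4", "chr2", 100000, 101000)],
        [("s1", "s3")],
    )
    gmap = map_genes_to_segments(genes, inter, 2500)
    return genes, inter, gmap


def test_genes_colocalized_direct_lookup():
    genes, inter, gmap = _coloc_toy()
    assert genes_colocalized("g1", "g3", gmap, inter, "inter")
    assert not genes_colocalized("g1", "g3", gmap, inter, "intra")
    assert genes_colocalized("g3", "g1", gmap, inter, "inter")  # symmetric


def test_shared_segment_alone_is_not_colocalization():
    genes, inter, gmap = _coloc_toy()
    # g1 and g2 both map only to s1; no pair connects s1 to itself
    assert gmap.segments_of("g1") == gmap.segments_of("g2") == {"s1"}
    assert not genes_colocalized("g1", "g2", gmap, inter, "inter")
    assert not genes_colocalized("g1", "g2", gmap, inter, "intra")


def test_empty_segment_set_never_colocalized():
    genes = make_genes([("g1", "chr3", "+", 500), ("g3", "chr2", "+", 500)])
    inter = make_interactions(
        [("s1", "chr1", 1, 1000), ("s3", "chr2", 1, 1000)], [("s1", "s3")]
    )
    gmap = map_genes_to_segments(genes, inter, 2500)
    assert gmap.segments_of("g1") == frozenset()
    assert not genes_colocalized("g1", "g3", gmap, inter, "inter")


# ---------------------------------------------------------------------------
# SAR classification
# ---------------------------------------------------------------------------

def test_classify_sar_toy_and_no_interactions():
    genes, inter, gmap = _coloc_toy()
    reg = make_regulon("tf1", bound=["g3"], ko=["g1"])
    cls = classify_sar(reg, gmap, inter)
    assert cls.is_sar("g1", "inter") and not cls.is_sar("g1", "intra")
    assert cls.partners("g1", "inter") == ("g3",)
    assert cls.sar_pairs("any") == [("tf1", "g1")]

    empty = make_interactions([("s1", "chr1", 1, 1000), ("s3", "chr2", 1, 1000)], [])
    gmap2 = map_genes_to_segments(genes, empty, 2500)
    cls2 = classify_sar(reg, gmap2, empty)
    assert cls2.sar_genes("any") == ()
    assert cls2.nonsar_genes("any") == ("g1",)


def test_classify_sar_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(2024)
    for _ in range(20):
        genes, inter, reg = random_instance(rng)
        gmap = map_genes_to_segments(genes, inter, 2500)
        cls = classify_sar(reg, gmap, inter)
        oracle = classify_bruteforce(reg, gmap, inter)
        got = {
            "inter": {k: set(v) for k, v in cls.partners_inter.items()},
            "intra": {k: set(v) for k, v in cls.partners_intra.items()},
        }
        assert got == oracle


def test_index_agrees_with_classification(strong_classified):
    ds, inter, gmap, classifications = strong_classified
    index = ColocalizationIndex(ds.genes, inter, gmap)
    for cls, reg in zip(classifications, ds.regulons):
        ko_idx = ds.genes.index_of(cls.ko_genes)
        bd_idx = ds.genes.index_of(cls.bound_genes)
        for mode in ("inter", "intra"):
            flags = index.colocalized_any(ko_idx, bd_idx, mode)
            expected = np.array([cls.is_sar(g, mode) for g in cls.ko_genes])
            assert np.array_equal(flags, expected)


# ---------------------------------------------------------------------------
# pooled frequency / partner counts
# ---------------------------------------------------------------------------

def test_pooled_frequency_toy_half():
    genes = make_genes(
        [("k1", "chr1", "+", 500), ("k2", "chr1", "+", 90500), ("b1", "chr2", "+", 500)]
    )
    inter = make_interactions(
        [("s1", "chr1", 1, 1000), ("s2", "chr1", 90001, 91000), ("s3", "chr2", 1, 1000)],
        [("s1", "s3")],
    )
    gmap = map_genes_to_segments(genes, inter, 2500)
    cls = classify_sar(make_regulon("tf", ["b1"], ["k1", "k2"]), gmap, inter)
    freq = pooled_frequency([cls], "ko_vs_bound", "inter")
    assert (freq.numerator, freq.denominator, freq.frequency) == (1, 2, 0.5)
    rev = pooled_frequency([cls], "bound_vs_ko", "inter")
    assert (rev.numerator, rev.denominator) == (1, 1)


def test_frequency_result_validation():
    with pytest.raises(ZeroDivisionError):
        FrequencyResult(numerator=0, denominator=0)
    with pytest.raises(ValueError):
        FrequencyResult(numerator=5, denominator=3)
    assert 0.0 <= FrequencyResult(numerator=2, denominator=7).frequency <= 1.0


def test_partner_count_summary_toy():
    genes = make_genes(
        [("k1", "chr1", "+", 500), ("k2", "chr1", "+", 90500), ("b1", "chr2", "+", 500)]
    )
    inter = make_interactions(
        [("s1", "chr1", 1, 1000), ("s2", "chr1", 90001, 91000), ("s3", "chr2", 1, 1000)],
        [("s1", "s3"), ("s2", "s3")],
    )
    gmap = map_genes_to_segments(genes, inter, 2500)
    cls = classify_sar(make_regulon("tf", ["b1"], ["k1", "k2"]), gmap, inter)
    ko_side = partner_count_summary([cls], "ko_vs_bound", "any")
    bd_side = partner_count_summary([cls], "bound_vs_ko", "any")
    assert ko_side.counts == {("tf", "k1"): 1, ("tf", "k2"): 1}
    assert bd_side.counts == {("tf", "b1"): 2}
    assert ko_side.total_pairs == bd_side.total_pairs == 2


def test_no_colocalization_gives_zero_counts():
    genes = make_genes([("k1", "chr1", "+", 500), ("b1", "chr2", "+", 500)])
    inter = make_interactions([("s1", "chr1", 1, 1000), ("s3", "chr2", 1, 1000)], [])
    gmap = map_genes_to_segments(genes, inter, 2500)
    cls = classify_sar(make_regulon("tf", ["b1"], ["k1"]), gmap, inter)
    summ = partner_count_summary([cls], "ko_vs_bound", "any")
    assert summ.total_pairs == 0 and set(summ.counts.values()) == {0}


def test_adding_interactions_never_decreases_frequency():
    rng = np.random.default_rng(7)
    genes, inter, reg = random_instance(rng)
    gmap = map_genes_to_segments(genes, inter, 2500)
    base = {
        (d, m): pooled_frequency([classify_sar(reg, gmap, inter)], d, m).frequency
        for d in ("ko_vs_bound", "bound_vs_ko")
        for m in ("inter", "intra")
    }
    # add every remaining segment pair
    seg_ids = list(inter.segments["segment_id"])
    extra = [
        (a, b)
        for i, a in enumerate(seg_ids)
        for b in seg_ids[i + 1 :]
    ]
    full_pairs = pd.DataFrame(extra, columns=["seg_a", "seg_b"])
    full_pairs["kind"] = pd.NA
    full_pairs["fdr"] = 1e-5
    from sarloc.core_io import InteractionSet

    # full_pairs enumerates every unordered segment pair: a superset
    dense = InteractionSet(segments=inter.segments, pairs=full_pairs)
    gmap2 = map_genes_to_segments(genes, dense, 2500)
    cls2 = classify_sar(reg, gmap2, dense)
    for key, v in base.items():
        assert pooled_frequency([cls2], *key).frequency >= v


def test_pair_total_symmetry_per_tf(strong_classified):
    ds, inter, gmap, classifications = strong_classified
    for cls in classifications:
        for mode in ("inter", "intra", "any"):
            ko_total = sum(len(cls.partners(g, mode)) for g in cls.ko_genes)
            bd_total = sum(len(v) for v in cls.bound_side_partners(mode).values())
            assert ko_total == bd_total
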