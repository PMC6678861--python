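"""Rank tests, bootstrap, GO co-membership frequencies and co-expression
contrasts, with an enumeration oracle for the Mann-Whitney U test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sarloc.core_io import AnnotationSet, ExpressionMatrix
from sarloc.functional import (
    bootstrap_median_ci,
    bp_coprocess_frequency,
    cc_cocomponent_frequency,
    coexpression_contrast,
    expression_variability,
    expression_variability_contrast,
    make_contrast,
    mann_whitney_u,
    pairwise_bound_coexpression,
    pearson_pairwise_complete,
)

from conftest import make_genes, make_regulon
from oracles import mwu_exact_enumeration


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def test_mwu_symmetric_identical_samples():
    assert mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0


def test_mwu_extreme_separation():
    a = np.arange(20, dtype=float) + 100.0
    b = np.arange(20, dtype=float)
    assert mann_whitney_u(a, b) < 1e-6


def test_mwu_empty_sample_raises():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.data())
def test_mwu_matches_exact_enumeration(data):
    n = data.draw(st.integers(1, 6))
    m = data.draw(st.integers(1, 8))
    vals = data.draw(
        st.lists(
            st.floats(-100, 100, allow_nan=False, allow_infinity=False),
            min_size=n + m,
            max_size=n + m,
            unique=True,
        )
    )
    a, b = vals[:n], vals[n:]
    assert mann_whitney_u(a, b) == pytest.approx(mwu_exact_enumeration(a, b), abs=1e-12)


# ---------------------------------------------------------------------------
# bootstrap / contrast container
# ---------------------------------------------------------------------------

def test_bootstrap_ci_contains_sample_median_usually():
    rng = np.random.default_rng(3)
    hits = 0
    for _ in range(200):
        x = rng.normal(size=25)
        lo, hi = bootstrap_median_ci(x, n_boot=200, seed=int(rng.integers(2**31)))
        med = np.median(x)
        hits += lo <= med <= hi
    assert hits / 200 >= 0.90  # nominal 95% minus 5-point slack


def test_make_contrast_degenerate_sentinel():
    c = make_contrast("x", [1.0, 1.0], [1.0, 1.0, 1.0], n_boot=50)
    assert c.degenerate and np.isnan(c.mw_u_p)
    c2 = make_contrast("y", [], [1.0], n_boot=50)
    assert c2.degenerate


# ---------------------------------------------------------------------------
# cellular co-component
# ---------------------------------------------------------------------------

def _cc_setup():
    genes = make_genes([("x1", "chr1", "+", 1000), ("x2", "chr1", "+", 200000)])
    regulons = [
        make_regulon("tfA", bound=[], ko=["x1"]),
        make_regulon("tfB", bound=["x1"], ko=[]),
        make_regulon("tfC", bound=["x2"], ko=[]),
    ]
    cc = AnnotationSet(category="CC", terms={"complex1": frozenset({"tfA", "tfB"})})
    return genes, regulons, cc


def test_cc_cocomponent_counts_shared_complex():
    genes, regulons, cc = _cc_setup()
    # x1 is bound by tfB, which shares a CC term with tfA -> counted
    freq = cc_cocomponent_frequency([("tfA", "x1")], regulons, cc, genes)
    assert (freq.numerator, freq.denominator) == (1, 1)
    # x2 is bound only by tfC, which shares no CC term with tfA -> not counted
    freq2 = cc_cocomponent_frequency([("tfA", "x2")], regulons, cc, genes)
    assert (freq2.numerator, freq2.denominator) == (0, 1)


def test_cc_cocomponent_requires_another_binding_tf():
    genes, regulons, cc = _cc_setup()
    # even though tfA shares a term with tfB, a gene bound by nobody fails
    regulons2 = [make_regulon("tfA", bound=[], ko=["x1"]), make_regulon("tfB", bound=[], ko=[])]
    freq = cc_cocomponent_frequency([("tfA", "x1")], regulons2, cc, genes)
    assert freq.numerator == 0
    # the binding TF must be ANOTHER TF: self-binding does not count
    regulons3 = [make_regulon("tfA", bound=["x1"], ko=[])]
    cc_self = AnnotationSet(category="CC", terms={"c": frozenset({"tfA"})})
    freq3 = cc_cocomponent_frequency([("tfA", "x1")], regulons3, cc_self, genes)
    assert freq3.numerator == 0


# ---------------------------------------------------------------------------
# biological co-process
# ---------------------------------------------------------------------------

def test_bp_coprocess_planted_term_and_monotonicity():
    regulons = [make_regulon("tfA", bound=["b1", "b2"], ko=["k1", "k2"])]
    bp0 = AnnotationSet(category="BP", terms={"p1": frozenset({"b1", "k1"})})
    f0 = bp_coprocess_frequency([("tfA", "k1"), ("tfA", "k2")], regulons, bp0)
    assert (f0.numerator, f0.denominator) == (1, 2)  # k2 has no BP annotation
    # adding a term can only increase the frequency
    bp1 = AnnotationSet(
        category="BP", terms={"p1": frozenset({"b1", "k1"}), "p2": frozenset({"b2", "k2"})}
    )
    f1 = bp_coprocess_frequency([("tfA", "k1"), ("tfA", "k2")], regulons, bp1)
    assert f1.frequency >= f0.frequency
    assert f1.numerator == 2
    # sharing a term with itself only does not count
    bp_self = AnnotationSet(category="BP", terms={"p": frozenset({"k1"})})
    assert bp_coprocess_frequency([("tfA", "k1")], regulons, bp_self).numerator == 0


# ---------------------------------------------------------------------------
# co-expression
# ---------------------------------------------------------------------------

def _expr(rows: dict, n=10) -> ExpressionMatrix:
    return ExpressionMatrix(frame=pd.DataFrame(rows, index=[f"c{i}" for i in range(n)]).T)


def test_pearson_identity_and_affine_invariance():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    assert pearson_pairwise_complete(x, x) == pytest.approx(1.0)
    assert pearson_pairwise_complete(x, 3.0 * x + 2.0) == pytest.approx(1.0)
    assert pearson_pairwise_complete(x, -x) == pytest.approx(-1.0)
    assert pearson_pairwise_complete(x[:2], x[:2]) is None  # < 3 shared obs


def test_pearson_pairwise_complete_with_missing():
    x = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
    y = np.array([2.0, 4.0, 6.0, np.nan, 10.0])
    assert pearson_pairwise_complete(x, y) == pytest.approx(1.0)


def test_coexpression_contrast_recovers_planted_blocks(strong_classified):
    ds, inter, gmap, classifications = strong_classified
    gt = ds.ground_truth
    sar_pairs, nonsar_pairs = [], []
    for reg in ds.regulons:
        for g in sorted(reg.ko_affected):
            (sar_pairs if g in gt.true_sar[reg.tf_id] else nonsar_pairs).append((reg.tf_id, g))
    c = coexpression_contrast(sar_pairs, nonsar_pairs, ds.regulons, ds.expression, n_boot=100, seed=0)
    assert c.median_a > c.median_b
    assert c.mw_u_p < 0.05


def test_pairwise_bound_coexpression_counts_and_sentinel(strong_classified):
    ds, inter, gmap, classifications = strong_classified
    c = pairwise_bound_coexpression(ds.regulons, classifications, ds.expression, n_boot=50, seed=0)
    # C(k,2) pooled counts: groups together cover all within-class pairs
    expected = 0
    for cls in classifications:
        k = len(cls.colocalized_bound_genes("any"))
        nk = len(cls.bound_genes) - k
        expected += k * (k - 1) // 2 + nk * (nk - 1) // 2
    assert c.group_a.size + c.group_b.size == expected

    # all-identical expression -> degenerate sentinel
    const = ExpressionMatrix(
        frame=pd.DataFrame(np.ones((4, 5)), index=["b1", "b2", "b3", "b4"]),
        min_observations=3,
    )
    from sarloc.colocalization import SARClassification

    cls = SARClassification(
        tf_id="tf",
        ko_genes=("k1",),
        bound_genes=("b1", "b2", "b3", "b4"),
        partners_inter={"k1": ("b1", "b2")},
        partners_intra={},
    )
    reg = make_regulon("tf", ["b1", "b2", "b3", "b4"], ["k1"])
    out = pairwise_bound_coexpression([reg], [cls], const, n_boot=20)
    assert out.degenerate


# ---------------------------------------------------------------------------
# expression variability
# ---------------------------------------------------------------------------

def test_variability_constant_row_is_zero():
    expr = _expr({"g1": np.ones(10), "g2": np.arange(10.0)})
    v = expression_variability(expr, ["g1"])
    assert v[0] == 0.0


def test_variability_scaling_doubles_sd_but_not_p():
    rng = np.random.default_rng(1)
    rows = {f"g{i}": rng.normal(size=12) for i in range(40)}
    expr1 = ExpressionMatrix(frame=pd.DataFrame(rows).T)
    expr2 = ExpressionMatrix(frame=pd.DataFrame({k: 2 * v for k, v in rows.items()}).T)
    a = [f"g{i}" for i in range(20)]
    b = [f"g{i}" for i in range(20, 40)]
    v1 = expression_variability(expr1, a)
    v2 = expression_variability(expr2, a)
    assert np.allclose(v2, 2 * v1)
    c1 = expression_variability_contrast(a, b, expr1, n_boot=20, seed=0)
    c2 = expression_variability_contrast(a, b, expr2, n_boot=20, seed=0)
    assert c1.mw_u_p == pytest.approx(c2.mw_u_p)


def test_variability_contrast_calibrated_under_null():
    rng = np.random.default_rng(8)
    rejections = 0
    for _ in range(30):
        rows = {f"g{i}": rng.normal(size=15) for i in range(120)}
        expr = ExpressionMatrix(frame=pd.DataFrame(rows).T)
        c = expression_variability_contrast(
            [f"g{i}" for i in range(60)], [f"g{i}" for i in range(60, 120)], expr, n_boot=10, seed=0
        )
        rejections += c.mw_u_p < 0.05
    assert rejections <= 6  # Binomial(30, 0.05) rarely exceeds this
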