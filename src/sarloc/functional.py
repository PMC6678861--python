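"""Downstream statistics on SAR vs non-SAR pairs.

Cellular co-component and biological co-process frequencies use flat GO
semantics: two genes (or TFs) are co-annotated iff they share at least one
term of the category; no ontology propagation. Co-expression is Pearson
correlation over the expression conditions (pairwise-complete when values
are missing). Group contrasts use the two-sided Mann-Whitney U rank test;
median error bars come from a seeded percentile bootstrap.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .colocalization import FrequencyResult, SARClassification
from .core_io import AnnotationSet, ExpressionMatrix, GeneTable, TFRegulon

logger = logging.getLogger("sarloc")


# ---------------------------------------------------------------------------
# Mann-Whitney U and contrast containers
# ---------------------------------------------------------------------------

def mann_whitney_u(sample_a, sample_b, alternative: str = "two-sided") -> float:
    """Two-sided (by default) Mann-Whitney U / rank-sum P value.

    Exact enumeration is used for tie-free inputs with min(n, m) <= 8;
    larger or tied inputs use the tie-corrected normal approximation with
    continuity correction. Completely degenerate input (every value in both
    samples identical) carries no rank information and returns P = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney_u requires two nonempty samples")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method, use_continuity=True)
    return float(res.pvalue)


@dataclass
class ContrastResult:
    """Two value groups, their medians with bootstrap CIs, and a rank-test P.

    ``degenerate`` marks contrasts in which a rank test carries no
    information (a group empty, or all values tied); ``mw_u_p`` is then NaN
    and the result is a no-contrast sentinel.
    """

    label: str
    group_a: np.ndarray
    group_b: np.ndarray
    mw_u_p: float
    ci_a: Tuple[float, float]
    ci_b: Tuple[float, float]
    n_boot: int
    degenerate: bool = False

    @property
    def median_a(self) -> float:
        return float(np.median(self.group_a)) if self.group_a.size else float("nan")

    @property
    def median_b(self) -> float:
        return float(np.median(self.group_b)) if self.group_b.size else float("nan")

    def summary(self) -> str:
        if self.degenerate:
            return f"{self.label}: no contrast (degenerate groups)"
        return (
            f"{self.label}: median A = {self.median_a:.4f} "
            f"[{self.ci_a[0]:.4f}, {self.ci_a[1]:.4f}] (n={self.group_a.size}), "
            f"median B = {self.median_b:.4f} "
            f"[{self.ci_b[0]:.4f}, {self.ci_b[1]:.4f}] (n={self.group_b.size}), "
            f"Mann-Whitney P = {self.mw_u_p:.3g}"
        )


def bootstrap_median_ci(
    values: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile bootstrap confidence interval for the median."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, values.size, size=(n_boot, values.size))
    medians = np.median(values[draws], axis=1)
    alpha = (1 - level) / 2
    return (float(np.quantile(medians, alpha)), float(np.quantile(medians, 1 - alpha)))


def make_contrast(
    label: str,
    group_a,
    group_b,
    n_boot: int = 1000,
    seed: int = 0,
) -> ContrastResult:
    """Assemble a :class:`ContrastResult`, handling degenerate groups."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    degenerate = a.size == 0 or b.size == 0 or np.ptp(np.concatenate([a, b])) == 0
    p = float("nan") if degenerate else mann_whitney_u(a, b)
    return ContrastResult(
        label=label,
        group_a=a,
        group_b=b,
        mw_u_p=p,
        ci_a=bootstrap_median_ci(a, n_boot=n_boot, seed=seed),
        ci_b=bootstrap_median_ci(b, n_boot=n_boot, seed=seed + 1),
        n_boot=n_boot,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Cellular co-component
# ---------------------------------------------------------------------------

class CoComponentIndex:
    """Fast evaluator of the cellular co-component frequency.

    Precomputes, for every gene, the set of TFs binding it (over *all*
    regulons supplied, at the load-time binding cutoff) and, for every
    query TF, which binding TFs share a CC term with it. A (tf, gene) pair
    satisfies the property iff some *other* TF both binds the gene and
    shares a CC term with tf.
    """

    def __init__(self, regulons: Sequence[TFRegulon], cc: AnnotationSet, genes: GeneTable):
        self.genes = genes
        self.tf_ids = [r.tf_id for r in regulons]
        tf_pos = {tf: i for i, tf in enumerate(self.tf_ids)}
        n_gene, n_tf = len(genes), len(self.tf_ids)
        B = np.zeros((n_gene, n_tf), dtype=bool)
        for j, reg in enumerate(regulons):
            for g in reg.bound:
                if g in genes:
                    B[genes.index_of([g])[0], j] = True
        self.binders = B
        # share[q, t]: query TF q shares >=1 CC term with binding TF t, t != q
        self._share: Dict[str, np.ndarray] = {}
        self._cc = cc
        self._tf_pos = tf_pos

    def _share_row(self, tf: str) -> np.ndarray:
        row = self._share.get(tf)
        if row is None:
            row = np.fromiter(
                (self._cc.share_term(tf, other) for other in self.tf_ids),
                dtype=bool,
                count=len(self.tf_ids),
            )
            j = self._tf_pos.get(tf)
            if j is not None:
                row[j] = False  # "another TF": t' != tf
            self._share[tf] = row
        return row

    def pair_flags(self, tf: str, gene_idx: np.ndarray) -> np.ndarray:
        """Flag per gene: bound by some other TF sharing a CC term with tf."""
        if len(gene_idx) == 0:
            return np.zeros(0, dtype=bool)
        return (self.binders[gene_idx] & self._share_row(tf)).any(axis=1)

    def frequency_idx(self, sets_by_tf: Mapping[str, np.ndarray]) -> float:
        num = den = 0
        for tf, idx in sets_by_tf.items():
            num += int(self.pair_flags(tf, idx).sum())
            den += len(idx)
        if den == 0:
            raise ZeroDivisionError("empty pair set")
        return num / den


def cc_cocomponent_statistic(index: CoComponentIndex):
    """Permutation statistic: CC co-component frequency of per-TF gene sets
    (only the gene side varies; the binder structure is fixed)."""

    def statistic(gene_sets: Mapping[str, np.ndarray], _unused) -> float:
        return index.frequency_idx(gene_sets)

    return statistic


def cc_cocomponent_frequency(
    sar_pairs: Iterable[Tuple[str, str]],
    regulons: Sequence[TFRegulon],
    cc: AnnotationSet,
    genes: GeneTable,
) -> FrequencyResult:
    """Fraction of (TF, SAR gene) pairs in which the TF shares a cellular
    component with another TF that directly binds the gene."""
    index = CoComponentIndex(regulons, cc, genes)
    num = den = 0
    for tf, gene in sar_pairs:
        den += 1
        if gene in genes and bool(index.pair_flags(tf, genes.index_of([gene]))[0]):
            num += 1
    return FrequencyResult(numerator=num, denominator=den, label="cc_cocomponent")


def sets_by_tf(pairs: Iterable[Tuple[str, str]]) -> Dict[str, List[str]]:
    """Group (tf, gene) pairs into per-TF gene lists (stable order)."""
    out: Dict[str, List[str]] = {}
    for tf, gene in pairs:
        out.setdefault(tf, []).append(gene)
    return out


# ---------------------------------------------------------------------------
# Biological co-process
# ---------------------------------------------------------------------------

def bp_coprocess_frequency(
    pair_set: Iterable[Tuple[str, str]],
    regulons: Sequence[TFRegulon],
    bp: AnnotationSet,
    label: str = "bp_coprocess",
) -> FrequencyResult:
    """Fraction of (TF, gene) pairs in which the gene shares a biological
    process term with at least one gene bound by that TF.

    Computed for SAR and non-SAR pair sets separately by the caller; genes
    without BP annotation never count in the numerator but stay in the
    denominator.
    """
    reg_by_tf = {r.tf_id: r for r in regulons}
    bound_terms: Dict[str, Set[str]] = {}
    num = den = 0
    for tf, gene in pair_set:
        den += 1
        terms = bp.terms_of(gene)
        if not terms:
            continue
        if tf not in bound_terms:
            reg = reg_by_tf.get(tf)
            acc: Set[str] = set()
            if reg is not None:
                for b in reg.bound:
                    acc |= bp.terms_of(b)
            bound_terms[tf] = acc
        shared = terms & bound_terms[tf]
        # the shared term must contain a bound gene other than the gene itself
        if shared and any(bp.terms[t] & (set(reg_by_tf[tf].bound) - {gene}) for t in shared):
            num += 1
    return FrequencyResult(numerator=num, denominator=den, label=label)


# ---------------------------------------------------------------------------
# Co-expression
# ---------------------------------------------------------------------------

def _zscore_rows(expr: ExpressionMatrix, gene_ids: Sequence[str]) -> Tuple[np.ndarray, Dict[str, int], int]:
    """Standardized expression rows for the requested genes (NaN-free fast
    path); genes missing from the matrix or with zero variance are omitted."""
    present = [g for g in gene_ids if g in expr]
    if len(present) < len(list(gene_ids)):
        logger.info("coexpression: %d genes lack expression rows", len(list(gene_ids)) - len(present))
    X = expr.frame.loc[present].to_numpy(dtype=float)
    sd = X.std(axis=1)
    ok = np.isfinite(sd) & (sd > 0) & np.isfinite(X).all(axis=1)
    X = X[ok]
    kept = [g for g, flag in zip(present, ok) if flag]
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    return Z, {g: i for i, g in enumerate(kept)}, expr.n_conditions


def pearson_pairwise_complete(x: np.ndarray, y: np.ndarray, min_obs: int = 3) -> Optional[float]:
    """Pearson r over conditions where both values are present; None if
    fewer than ``min_obs`` shared observations or zero variance."""
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < min_obs:
        return None
    xv, yv = x[mask], y[mask]
    if xv.std() == 0 or yv.std() == 0:
        return None
    return float(np.corrcoef(xv, yv)[0, 1])


def _cross_correlations(
    pairs_by_tf: Mapping[str, Sequence[str]],
    regulons_by_tf: Mapping[str, TFRegulon],
    expr: ExpressionMatrix,
) -> List[float]:
    """r for every (gene, bound gene of same TF) combination, pooled."""
    has_nan = bool(expr.frame.isna().to_numpy().any())
    values: List[float] = []
    if not has_nan:
        all_genes = sorted({g for gl in pairs_by_tf.values() for g in gl} | {b for tf in pairs_by_tf for b in regulons_by_tf[tf].bound})
        Z, pos, C = _zscore_rows(expr, all_genes)
        for tf, gene_list in pairs_by_tf.items():
            bidx = [pos[b] for b in sorted(regulons_by_tf[tf].bound) if b in pos]
            gidx = [pos[g] for g in gene_list if g in pos]
            if not bidx or not gidx:
                continue
            R = Z[gidx] @ Z[bidx].T / C
            values.extend(R.ravel().tolist())
    else:
        n_skipped = 0
        for tf, gene_list in pairs_by_tf.items():
            bound = sorted(regulons_by_tf[tf].bound)
            for g in gene_list:
                if g not in expr:
                    continue
                xg = expr.row(g)
                for b in bound:
                    if b not in expr:
                        continue
                    r = pearson_pairwise_complete(xg, expr.row(b))
                    if r is None:
                        n_skipped += 1
                    else:
                        values.append(r)
        if n_skipped:
            logger.info("coexpression: skipped %d pairs with < 3 shared observations", n_skipped)
    return values


def coexpression_contrast(
    sar_pairs: Iterable[Tuple[str, str]],
    nonsar_pairs: Iterable[Tuple[str, str]],
    regulons: Sequence[TFRegulon],
    expr: ExpressionMatrix,
    n_boot: int = 1000,
    seed: int = 0,
) -> ContrastResult:
    """Pearson co-expression of SAR genes vs non-SAR genes with the bound
    genes of the same TF (r pooled over all combinations), contrasted by a
    Mann-Whitney U test with bootstrap CIs on the medians."""
    reg_by_tf = {r.tf_id: r for r in regulons}
    a = _cross_correlations(sets_by_tf(sar_pairs), reg_by_tf, expr)
    b = _cross_correlations(sets_by_tf(nonsar_pairs), reg_by_tf, expr)
    return make_contrast("coexpression sar_vs_nonsar", a, b, n_boot=n_boot, seed=seed)


def _within_group_correlations(gene_ids: Sequence[str], expr: ExpressionMatrix) -> List[float]:
    genes = sorted(set(gene_ids))
    if len(genes) < 2:
        return []
    has_nan = bool(expr.frame.isna().to_numpy().any())
    if not has_nan:
        Z, pos, C = _zscore_rows(expr, genes)
        if len(pos) < 2:
            return []
        R = Z @ Z.T / C
        iu = np.triu_indices(len(pos), k=1)
        return R[iu].tolist()
    out: List[float] = []
    for g1, g2 in itertools.combinations([g for g in genes if g in expr], 2):
        r = pearson_pairwise_complete(expr.row(g1), expr.row(g2))
        if r is not None:
            out.append(r)
    return out


def pairwise_bound_coexpression(
    regulons: Sequence[TFRegulon],
    classifications: Sequence[SARClassification],
    expr: ExpressionMatrix,
    n_boot: int = 1000,
    seed: int = 0,
) -> ContrastResult:
    """Within-TF pairwise co-expression among bound genes that colocalize
    with KO genes vs among those that do not, pooled across TFs."""
    cls_by_tf = {c.tf_id: c for c in classifications}
    a: List[float] = []
    b: List[float] = []
    for reg in regulons:
        cls = cls_by_tf.get(reg.tf_id)
        if cls is None:
            continue
        coloc = set(cls.colocalized_bound_genes("any"))
        noncoloc = set(cls.bound_genes) - coloc
        a.extend(_within_group_correlations(sorted(coloc), expr))
        b.extend(_within_group_correlations(sorted(noncoloc), expr))
    return make_contrast("pairwise_bound_coexpression coloc_vs_noncoloc", a, b, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# Expression variability
# ---------------------------------------------------------------------------

def expression_variability(expr: ExpressionMatrix, gene_ids: Iterable[str], metric: str = "sd") -> np.ndarray:
    """Per-gene expression variability across conditions (sample SD by
    default; ``metric='cv'`` for coefficient of variation)."""
    vals: List[float] = []
    for g in gene_ids:
        if g not in expr:
            continue
        x = expr.row(g)
        x = x[np.isfinite(x)]
        if x.size < 2:
            continue
        sd = float(np.std(x, ddof=1))
        if metric == "sd":
            vals.append(sd)
        elif metric == "cv":
            m = float(np.mean(x))
            vals.append(sd / abs(m) if m != 0 else float("nan"))
        else:
            raise ValueError(f"metric must be 'sd' or 'cv', got {metric!r}")
    return np.asarray(vals, dtype=float)


def expression_variability_contrast(
    sar_genes: Iterable[str],
    other_genes: Iterable[str],
    expr: ExpressionMatrix,
    metric: str = "sd",
    n_boot: int = 1000,
    seed: int = 0,
) -> ContrastResult:
    """Mann-Whitney contrast of per-gene expression variability."""
    a = expression_variability(expr, sar_genes, metric)
    b = expression_variability(expr, other_genes, metric)
    return make_contrast(f"expression_variability ({metric})", a, b, n_boot=n_boot, seed=seed)
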