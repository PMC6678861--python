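"""Motif presence, promoter nucleosome occupancy, TF-count and
binding-affinity contrasts between SAR genes and comparison gene sets.

All group comparisons are rank-based (Mann-Whitney U), hence invariant
under strictly monotone transforms of the underlying scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .colocalization import FrequencyResult, SARClassification
from .core_io import MotifTable, OccupancyTrackSet, TFRegulon
from .functional import ContrastResult, make_contrast, mann_whitney_u

logger = logging.getLogger("sarloc")


def motif_presence_frequency(
    pair_set: Iterable[Tuple[str, str]],
    motifs: MotifTable,
    label: str = "motif_presence",
) -> FrequencyResult:
    """Fraction of (TF, gene) pairs whose promoter carries an (unbound)
    motif of that TF."""
    num = den = 0
    for tf, gene in pair_set:
        den += 1
        if motifs.has_motif(tf, gene):
            num += 1
    return FrequencyResult(numerator=num, denominator=den, label=label)


@dataclass
class OccupancyProfile:
    """Mean promoter occupancy profile of a gene set.

    ``profile`` is the position-wise mean over genes at strand-oriented
    positions [-500, -1] (last entry abuts the TSS); ``per_gene_mean`` maps
    each contributing gene to its scalar mean occupancy over the window.
    """

    profile: np.ndarray
    per_gene_mean: Dict[str, float]
    n_genes: int

    @property
    def gene_means(self) -> np.ndarray:
        return np.asarray(list(self.per_gene_mean.values()), dtype=float)


def promoter_occupancy_profile(
    gene_set: Iterable[str],
    occ: OccupancyTrackSet,
) -> OccupancyProfile:
    """Average the [-500, -1] promoter occupancy tracks of a gene set.

    Genes without a track are skipped with a logged count. Strand
    orientation is a property of the track set (tracks are stored already
    oriented, position -1 TSS-proximal).
    """
    genes = list(dict.fromkeys(gene_set))
    present = [g for g in genes if g in occ]
    missing = len(genes) - len(present)
    if missing:
        logger.info("promoter_occupancy_profile: %d genes lack occupancy tracks", missing)
    if not present:
        raise ValueError("no occupancy track available for any gene in the set")
    X = occ.frame.loc[present].to_numpy(dtype=float)
    return OccupancyProfile(
        profile=X.mean(axis=0),
        per_gene_mean={g: float(m) for g, m in zip(present, X.mean(axis=1))},
        n_genes=len(present),
    )


def occupancy_contrast(
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    occ: OccupancyTrackSet,
    label: str = "promoter_occupancy",
    n_boot: int = 1000,
    seed: int = 0,
) -> ContrastResult:
    """Mann-Whitney contrast of per-gene mean promoter occupancy.

    Callers comparing SAR genes with bound genes should exclude genes that
    belong to both sets beforehand.
    """
    pa = promoter_occupancy_profile(genes_a, occ)
    pb = promoter_occupancy_profile(genes_b, occ)
    return make_contrast(label, pa.gene_means, pb.gene_means, n_boot=n_boot, seed=seed)


def tf_binding_counts(gene_ids: Iterable[str], regulons: Sequence[TFRegulon]) -> Dict[str, int]:
    """Number of distinct TFs binding each gene (at the load-time binding
    cutoff), over the supplied regulon collection."""
    bound_by: Dict[str, int] = {g: 0 for g in gene_ids}
    for reg in regulons:
        for g in reg.bound:
            if g in bound_by:
                bound_by[g] += 1
    return bound_by


def tf_count_contrast(
    sar_genes: Iterable[str],
    other_genes: Iterable[str],
    regulons: Sequence[TFRegulon],
    n_boot: int = 1000,
    seed: int = 0,
) -> ContrastResult:
    """Contrast of per-gene binding-TF counts (SAR vs other genes)."""
    a = np.asarray(list(tf_binding_counts(sorted(set(sar_genes)), regulons).values()), dtype=float)
    b = np.asarray(list(tf_binding_counts(sorted(set(other_genes)), regulons).values()), dtype=float)
    return make_contrast("tf_count sar_vs_other", a, b, n_boot=n_boot, seed=seed)


def affinity_contrast(
    regulons: Sequence[TFRegulon],
    classifications: Sequence[SARClassification],
    n_boot: int = 1000,
    seed: int = 0,
) -> ContrastResult:
    """Binding-score contrast between bound events whose gene colocalizes
    with >= 1 KO gene of the same TF (group A) and the remaining bound
    events (group B).

    Scores are -log10 binding P-values by default, so larger means stronger
    binding; the rank test is invariant to any monotone rescaling.
    """
    cls_by_tf = {c.tf_id: c for c in classifications}
    a: List[float] = []
    b: List[float] = []
    for reg in regulons:
        cls = cls_by_tf.get(reg.tf_id)
        if cls is None:
            continue
        coloc = set(cls.colocalized_bound_genes("any"))
        for gene, score in reg.bound.items():
            (a if gene in coloc else b).append(score)
    return make_contrast("binding_affinity coloc_vs_noncoloc", a, b, n_boot=n_boot, seed=seed)
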