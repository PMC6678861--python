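"""Mutual-exclusion and linear-proximity filters on TF regulons.

For each TF the knockout-affected set and the bound set are made disjoint
and linearly separated: a knockout-affected gene is removed if it is bound
by the same TF or if its TSS lies within ``proximity_bp`` of any bound
gene's TSS on the same chromosome, and symmetrically for bound genes.
Only TFs whose two filtered sets are both large enough are analyzed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

from .core_io import GeneTable, TFRegulon

logger = logging.getLogger("sarloc")


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the regulon filters.

    proximity_bp
        TSS-to-TSS distance (same chromosome) below which a gene counts as
        "close to" a gene of the opposite set. Default 3000.
    min_set_size
        Size threshold for analyzable TFs. With ``strict_min`` (default)
        a TF is kept iff both sets are strictly larger than this.
    """

    proximity_bp: int = 3000
    min_set_size: int = 20
    strict_min: bool = True

    def __post_init__(self) -> None:
        if self.proximity_bp < 0:
            raise ValueError("proximity_bp must be >= 0")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")


def _tss_by_chrom(genes: GeneTable, gene_ids: Iterable[str]) -> Dict[str, np.ndarray]:
    """Sorted TSS arrays per chromosome for the given genes."""
    out: Dict[str, List[int]] = {}
    for g in gene_ids:
        out.setdefault(genes.chrom_of(g), []).append(genes.tss_of(g))
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in out.items()}


def _is_proximal(genes: GeneTable, gene_id: str, tss_index: Dict[str, np.ndarray], cutoff: int) -> bool:
    """True iff the gene's TSS is < cutoff bp from any indexed same-chromosome TSS."""
    arr = tss_index.get(genes.chrom_of(gene_id))
    if arr is None or len(arr) == 0:
        return False
    tss = genes.tss_of(gene_id)
    pos = int(np.searchsorted(arr, tss))
    for j in (pos - 1, pos):
        if 0 <= j < len(arr) and abs(int(arr[j]) - tss) < cutoff:
            return True
    return False


def exclude_mutual_and_proximal(
    regulon: TFRegulon,
    genes: GeneTable,
    cfg: FilterConfig = FilterConfig(),
) -> TFRegulon:
    """Remove overlapping and linearly proximal genes from both regulon sides.

    Exclusion is computed against the ORIGINAL (pre-filter) sets on both
    sides simultaneously, so the operation is symmetric, order-independent
    and idempotent. Genes absent from the gene table cannot be placed and
    are dropped with a logged count.
    """
    bound0 = {g: s for g, s in regulon.bound.items() if g in genes}
    ko0 = {g for g in regulon.ko_affected if g in genes}
    n_unknown = (len(regulon.bound) - len(bound0)) + (len(regulon.ko_affected) - len(ko0))
    if n_unknown:
        logger.warning("exclude_mutual_and_proximal[%s]: dropped %d genes absent from gene table", regulon.tf_id, n_unknown)

    bound_tss = _tss_by_chrom(genes, bound0)
    ko_tss = _tss_by_chrom(genes, ko0)

    new_ko = {
        g
        for g in ko0
        if g not in bound0 and not _is_proximal(genes, g, bound_tss, cfg.proximity_bp)
    }
    new_bound = {
        g: s
        for g, s in bound0.items()
        if g not in ko0 and not _is_proximal(genes, g, ko_tss, cfg.proximity_bp)
    }
    return TFRegulon(
        tf_id=regulon.tf_id,
        bound=new_bound,
        ko_affected=new_ko,
        in_binding_data=regulon.in_binding_data,
        in_ko_data=regulon.in_ko_data,
    )


def select_analyzable(
    regulons: Sequence[TFRegulon],
    cfg: FilterConfig = FilterConfig(),
) -> List[TFRegulon]:
    """Keep TFs whose (filtered) bound and knockout sets both exceed the
    size threshold (strictly greater under ``strict_min``)."""
    kept: List[TFRegulon] = []
    for reg in regulons:
        nb, nk = len(reg.bound), len(reg.ko_affected)
        if cfg.strict_min:
            ok = nb > cfg.min_set_size and nk > cfg.min_set_size
        else:
            ok = nb >= cfg.min_set_size and nk >= cfg.min_set_size
        if ok:
            kept.append(reg)
    logger.info("select_analyzable: %d/%d TFs retained", len(kept), len(regulons))
    return kept


def filter_regulons(
    regulons: Sequence[TFRegulon],
    genes: GeneTable,
    cfg: FilterConfig = FilterConfig(),
) -> Tuple[List[TFRegulon], Dict[str, Dict[str, int]]]:
    """Apply both filters to a regulon collection.

    Returns the analyzable regulons and per-TF exclusion counts
    ``{tf: {bound_removed, ko_removed}}`` (all TFs, including dropped ones).
    """
    filtered: List[TFRegulon] = []
    counts: Dict[str, Dict[str, int]] = {}
    for reg in regulons:
        new = exclude_mutual_and_proximal(reg, genes, cfg)
        counts[reg.tf_id] = {
            "bound_removed": len(reg.bound) - len(new.bound),
            "ko_removed": len(reg.ko_affected) - len(new.ko_affected),
        }
        filtered.append(new)
    return select_analyzable(filtered, cfg), counts


def assert_filtered(regulons: Sequence[TFRegulon], genes: GeneTable, cfg: FilterConfig = FilterConfig()) -> None:
    """Assert the post-filter invariant on every TF: disjoint sets and no
    same-chromosome bound/KO TSS pair closer than ``proximity_bp``."""
    for reg in regulons:
        overlap = set(reg.bound) & reg.ko_affected
        if overlap:
            raise AssertionError(f"TF {reg.tf_id}: bound and KO sets overlap: {sorted(overlap)[:5]}")
        ko_tss = _tss_by_chrom(genes, (g for g in reg.ko_affected if g in genes))
        for g in reg.bound:
            if g in genes and _is_proximal(genes, g, ko_tss, cfg.proximity_bp):
                raise AssertionError(f"TF {reg.tf_id}: bound gene {g} within {cfg.proximity_bp} bp of a KO gene")
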