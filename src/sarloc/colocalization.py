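"""Gene-segment mapping, interaction filtering and SAR classification.

A gene is attached to every kilobase segment whose interval lies within
``tss_window_bp`` (default 2500) of its TSS on the same chromosome. Two
genes are colocalized in the nucleus iff two *distinct* segments, one from
each gene's segment set, form a retained chromosomal interaction of the
requested kind. A TF's knockout-affected gene colocalized with any bound
gene of the same TF is a spatially adjacent regulated (SAR) gene.

Intra-chromosomal interactions closer than ``min_sep_bp`` (default 60 kb,
midpoint-to-midpoint) are removed beforehand to control for linear
proximity in the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core_io import GeneTable, InteractionSet, TFRegulon

logger = logging.getLogger("sarloc")

MODES = ("inter", "intra")


# ---------------------------------------------------------------------------
# Gene -> segment mapping
# ---------------------------------------------------------------------------

@dataclass
class GeneSegmentMap:
    """Mapping gene_id -> set of segment ids within the TSS window."""

    tss_window_bp: int
    mapping: Dict[str, FrozenSet[str]]

    def segments_of(self, gene_id: str) -> FrozenSet[str]:
        return self.mapping.get(gene_id, frozenset())

    @property
    def n_mapped(self) -> int:
        return sum(1 for s in self.mapping.values() if s)


def map_genes_to_segments(
    genes: GeneTable,
    interactions: InteractionSet,
    tss_window_bp: int = 2500,
) -> GeneSegmentMap:
    """Attach each gene to the same-chromosome segments whose interval is
    within ``tss_window_bp`` of the TSS (0 if the TSS falls inside).

    Genes with no eligible segment map to the empty set and are retained:
    they stay in every denominator as never-colocalized genes.
    """
    if tss_window_bp < 0:
        raise ValueError("tss_window_bp must be >= 0")
    seg = interactions.segments
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in seg.groupby("chrom", sort=False):
        by_chrom[str(chrom)] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["segment_id"].to_numpy(),
        )
    mapping: Dict[str, FrozenSet[str]] = {}
    for gene_id, chrom, tss in zip(genes.ids, genes.chroms, genes.tss):
        entry = by_chrom.get(chrom)
        if entry is None:
            mapping[gene_id] = frozenset()
            continue
        starts, ends, ids = entry
        dist = np.maximum.reduce([starts - tss, tss - ends, np.zeros_like(starts)])
        mapping[gene_id] = frozenset(ids[dist <= tss_window_bp])
    n_unmapped = sum(1 for s in mapping.values() if not s)
    if n_unmapped:
        logger.info("map_genes_to_segments: %d/%d genes have no segment", n_unmapped, len(mapping))
    return GeneSegmentMap(tss_window_bp=tss_window_bp, mapping=mapping)


def filter_intra_by_separation(
    interactions: InteractionSet,
    min_sep_bp: int = 60000,
    anchor: str = "midpoint",
) -> InteractionSet:
    """Drop intra-chromosomal pairs separated by less than ``min_sep_bp``.

    Separation is midpoint-to-midpoint by default (``anchor='edge'`` uses
    the gap between the closest interval edges). Inter pairs pass through
    untouched.
    """
    pairs = interactions.pairs
    intra = pairs["kind"] == "intra"
    if anchor == "midpoint":
        mid = interactions.midpoints()
        sep = (mid[pairs["seg_a"]].to_numpy() - mid[pairs["seg_b"]].to_numpy()).__abs__()
    elif anchor == "edge":
        seg = interactions.segments.set_index("segment_id")
        sa, sb = pairs["seg_a"], pairs["seg_b"]
        gap1 = seg.loc[sb, "start"].to_numpy() - seg.loc[sa, "end"].to_numpy()
        gap2 = seg.loc[sa, "start"].to_numpy() - seg.loc[sb, "end"].to_numpy()
        sep = np.maximum(np.maximum(gap1, gap2), 0)
    else:
        raise ValueError(f"anchor must be 'midpoint' or 'edge', got {anchor!r}")
    keep = (~intra) | (sep >= min_sep_bp)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_intra_by_separation: removed %d intra pairs < %d bp apart", n_dropped, min_sep_bp)
    return InteractionSet(
        segments=interactions.segments,
        pairs=pairs[keep],
        fdr_cutoff=interactions.fdr_cutoff,
    )


# ---------------------------------------------------------------------------
# Pairwise colocalization
# ---------------------------------------------------------------------------

def _neighbor_segments(
    gene_id: str, gmap: GeneSegmentMap, adjacency: Mapping[str, Set[str]]
) -> Set[str]:
    out: Set[str] = set()
    for s in gmap.segments_of(gene_id):
        out |= adjacency.get(s, set())
    return out


def genes_colocalized(
    gene_a: str,
    gene_b: str,
    gmap: GeneSegmentMap,
    interactions: InteractionSet,
    mode: str,
) -> bool:
    """True iff some segment of ``gene_a`` interacts (kind ``mode``) with a
    *different* segment of ``gene_b``. Sharing a segment alone never counts:
    the interaction list, not co-mapping, defines nuclear proximity."""
    adjacency = interactions.adjacency(mode)
    return bool(_neighbor_segments(gene_a, gmap, adjacency) & gmap.segments_of(gene_b))


# ---------------------------------------------------------------------------
# SAR classification
# ---------------------------------------------------------------------------

@dataclass
class SARClassification:
    """Per-TF partition of knockout-affected genes into SAR / non-SAR.

    ``partners_inter`` / ``partners_intra`` map each KO gene to the bound
    genes of the same TF it colocalizes with in that mode (possibly empty).
    A KO gene is SAR iff either partner list is nonempty.
    """

    tf_id: str
    ko_genes: Tuple[str, ...]
    bound_genes: Tuple[str, ...]
    partners_inter: Dict[str, Tuple[str, ...]]
    partners_intra: Dict[str, Tuple[str, ...]]

    def partners(self, ko_gene: str, mode: str = "any") -> Tuple[str, ...]:
        if mode == "inter":
            return self.partners_inter.get(ko_gene, ())
        if mode == "intra":
            return self.partners_intra.get(ko_gene, ())
        if mode == "any":
            merged = dict.fromkeys(self.partners_inter.get(ko_gene, ()))
            merged.update(dict.fromkeys(self.partners_intra.get(ko_gene, ())))
            return tuple(merged)
        raise ValueError(f"mode must be 'inter', 'intra' or 'any', got {mode!r}")

    def is_sar(self, ko_gene: str, mode: str = "any") -> bool:
        return bool(self.partners(ko_gene, mode))

    def sar_genes(self, mode: str = "any") -> Tuple[str, ...]:
        return tuple(g for g in self.ko_genes if self.is_sar(g, mode))

    def nonsar_genes(self, mode: str = "any") -> Tuple[str, ...]:
        return tuple(g for g in self.ko_genes if not self.is_sar(g, mode))

    def sar_pairs(self, mode: str = "any") -> List[Tuple[str, str]]:
        return [(self.tf_id, g) for g in self.sar_genes(mode)]

    def nonsar_pairs(self, mode: str = "any") -> List[Tuple[str, str]]:
        return [(self.tf_id, g) for g in self.nonsar_genes(mode)]

    def bound_side_partners(self, mode: str = "any") -> Dict[str, Tuple[str, ...]]:
        """Invert the partner lists: bound gene -> colocalized KO genes.

        Every bound gene appears as a key (possibly with an empty tuple), so
        the result enumerates the bound side of the symmetric relation."""
        inv: Dict[str, List[str]] = {b: [] for b in self.bound_genes}
        for ko in self.ko_genes:
            for b in self.partners(ko, mode):
                inv[b].append(ko)
        return {b: tuple(v) for b, v in inv.items()}

    def colocalized_bound_genes(self, mode: str = "any") -> Tuple[str, ...]:
        inv = self.bound_side_partners(mode)
        return tuple(b for b in self.bound_genes if inv[b])


def classify_sar(
    regulon: TFRegulon,
    gmap: GeneSegmentMap,
    interactions: InteractionSet,
) -> SARClassification:
    """Classify every knockout-affected gene of one (filtered) TF.

    A KO gene is flagged per mode iff it is colocalized with at least one
    bound gene of the same TF; the bound partners are recorded.
    """
    adjacency = {mode: interactions.adjacency(mode) for mode in MODES}
    ko_genes = tuple(sorted(regulon.ko_affected))
    bound_genes = tuple(sorted(regulon.bound))
    bound_segs = {b: gmap.segments_of(b) for b in bound_genes}
    partners: Dict[str, Dict[str, Tuple[str, ...]]] = {m: {} for m in MODES}
    for ko in ko_genes:
        for mode in MODES:
            nbrs = _neighbor_segments(ko, gmap, adjacency[mode])
            if nbrs:
                hit = tuple(b for b in bound_genes if nbrs & bound_segs[b])
            else:
                hit = ()
            if hit:
                partners[mode][ko] = hit
    return SARClassification(
        tf_id=regulon.tf_id,
        ko_genes=ko_genes,
        bound_genes=bound_genes,
        partners_inter=partners["inter"],
        partners_intra=partners["intra"],
    )


# ---------------------------------------------------------------------------
# Pooled frequencies and partner counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyResult:
    """A numerator/denominator frequency with its provenance labels."""

    numerator: int
    denominator: int
    direction: Optional[str] = None
    mode: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ZeroDivisionError("frequency with zero denominator")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator must lie in [0, denominator]")

    @property
    def frequency(self) -> float:
        return self.numerator / self.denominator

    def __str__(self) -> str:
        tag = self.label or f"{self.direction}/{self.mode}"
        return f"{tag}: {self.numerator}/{self.denominator} = {100 * self.frequency:.2f}%"


def pooled_frequency(
    classifications: Sequence[SARClassification],
    direction: str = "ko_vs_bound",
    mode: str = "inter",
) -> FrequencyResult:
    """Pooled colocalization frequency over all analyzable TFs.

    ``ko_vs_bound``: fraction of (TF, KO gene) pairs in which the KO gene
    colocalizes with >= 1 bound gene of that TF. ``bound_vs_ko``: roles
    swapped (fraction of (TF, bound gene) pairs colocalized with >= 1 KO
    gene).
    """
    if direction not in ("ko_vs_bound", "bound_vs_ko"):
        raise ValueError(f"unknown direction {direction!r}")
    num = den = 0
    for cls in classifications:
        if direction == "ko_vs_bound":
            den += len(cls.ko_genes)
            num += sum(1 for g in cls.ko_genes if cls.is_sar(g, mode))
        else:
            inv = cls.bound_side_partners(mode)
            den += len(cls.bound_genes)
            num += sum(1 for b in cls.bound_genes if inv[b])
    return FrequencyResult(numerator=num, denominator=den, direction=direction, mode=mode)


@dataclass
class PartnerCountSummary:
    """Per-gene colocalized-partner counts for one side of the relation.

    ``counts`` maps (tf_id, gene_id) on the chosen side to the number of
    colocalized partner genes on the other side. ``total_pairs`` is the
    grand total of colocalized (bound, KO) gene pairs — identical whichever
    side it is computed from.
    """

    direction: str
    mode: str
    counts: Dict[Tuple[str, str], int]

    @property
    def total_pairs(self) -> int:
        return sum(self.counts.values())

    @property
    def mean_partners(self) -> float:
        return self.total_pairs / len(self.counts) if self.counts else 0.0


def partner_count_summary(
    classifications: Sequence[SARClassification],
    direction: str = "ko_vs_bound",
    mode: str = "any",
) -> PartnerCountSummary:
    """Distribution of colocalized partner counts on one side.

    Direction ``ko_vs_bound`` counts bound partners per KO gene;
    ``bound_vs_ko`` counts KO partners per bound gene.
    """
    counts: Dict[Tuple[str, str], int] = {}
    for cls in classifications:
        if direction == "ko_vs_bound":
            for g in cls.ko_genes:
                counts[(cls.tf_id, g)] = len(cls.partners(g, mode))
        elif direction == "bound_vs_ko":
            inv = cls.bound_side_partners(mode)
            for b in cls.bound_genes:
                counts[(cls.tf_id, b)] = len(inv[b])
        else:
            raise ValueError(f"unknown direction {direction!r}")
    return PartnerCountSummary(direction=direction, mode=mode, counts=counts)


# ---------------------------------------------------------------------------
# Dense index for fast repeated counting (permutation engine)
# ---------------------------------------------------------------------------

class ColocalizationIndex:
    """Dense boolean index over (gene, segment) incidence and segment
    adjacency, for fast repeated colocalization counting.

    ``S[g]`` flags the segments mapped to gene ``g``; ``N[mode][g]`` flags
    the segments interacting (in that mode) with any segment of ``g``. Gene
    ``a`` colocalizes with gene set ``B`` iff ``N[mode][a]`` intersects the
    union of ``S[b]`` for b in B. Self-pairs never arise because the pair
    list contains only distinct segments.
    """

    def __init__(self, genes: GeneTable, interactions: InteractionSet, gmap: GeneSegmentMap):
        self.genes = genes
        seg_index = interactions.segment_index()
        n_seg = len(seg_index)
        n_gene = len(genes)
        S = np.zeros((n_gene, n_seg), dtype=bool)
        for i, gene_id in enumerate(genes.ids):
            for s in gmap.segments_of(gene_id):
                S[i, seg_index[s]] = True
        self.S = S
        self.N: Dict[str, np.ndarray] = {}
        for mode in MODES:
            sub = interactions.pairs_of_kind(mode)
            A = np.zeros((n_seg, n_seg), dtype=bool)
            ia = [seg_index[s] for s in sub["seg_a"]]
            ib = [seg_index[s] for s in sub["seg_b"]]
            A[ia, ib] = True
            A[ib, ia] = True
            self.N[mode] = (S.astype(np.uint8) @ A.astype(np.uint8)) > 0

    def colocalized_any(self, gene_idx: np.ndarray, other_idx: np.ndarray, mode: str) -> np.ndarray:
        """Boolean flag per gene in ``gene_idx``: colocalized (mode) with at
        least one gene of ``other_idx``."""
        if len(other_idx) == 0 or len(gene_idx) == 0:
            return np.zeros(len(gene_idx), dtype=bool)
        bmask = self.S[other_idx].any(axis=0)
        return (self.N[mode][gene_idx] & bmask).any(axis=1)

    def pooled_frequency_idx(
        self,
        ko_sets: Mapping[str, np.ndarray],
        bound_sets: Mapping[str, np.ndarray],
        mode: str,
        direction: str = "ko_vs_bound",
    ) -> float:
        num = den = 0
        for tf, ko_idx in ko_sets.items():
            bd_idx = bound_sets[tf]
            if direction == "bound_vs_ko":
                ko_idx, bd_idx = bd_idx, ko_idx
            num += int(self.colocalized_any(ko_idx, bd_idx, mode).sum())
            den += len(ko_idx)
        if den == 0:
            raise ZeroDivisionError("no genes on the counted side")
        return num / den


def frequency_statistic(index: ColocalizationIndex, mode: str, direction: str = "ko_vs_bound"):
    """Pooled-frequency statistic over regulon index-sets, for the
    permutation engine. Operates on dicts tf -> gene row-index array."""

    def statistic(ko_sets: Mapping[str, np.ndarray], bound_sets: Mapping[str, np.ndarray]) -> float:
        return index.pooled_frequency_idx(ko_sets, bound_sets, mode, direction)

    return statistic


def regulon_index_sets(
    regulons: Sequence[TFRegulon], genes: GeneTable
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """(ko_sets, bound_sets) as gene row-index arrays keyed by TF id."""
    ko_sets = {r.tf_id: genes.index_of(sorted(r.ko_affected)) for r in regulons}
    bound_sets = {r.tf_id: genes.index_of(sorted(r.bound)) for r in regulons}
    return ko_sets, bound_sets
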