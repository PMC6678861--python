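"""Domain types and plain-text readers/writers for all pipeline inputs.

Every input is a tab-separated table. Readers validate invariants at load
time and apply the score cutoffs (ChIP binding P-value, interaction FDR)
so that downstream code never sees an unfiltered record. Coordinates are
1-based; intervals are closed; a TSS is a single base.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger("sarloc")

#: ChIP-chip binding P-value cutoff defining a bound gene.
DEFAULT_BINDING_P_CUTOFF = 0.005
#: FDR cutoff defining a chromosomal interaction.
DEFAULT_INTERACTION_FDR_CUTOFF = 1e-4
#: Promoter window, strand-oriented positions [-500, -1] relative to TSS.
PROMOTER_WINDOW = 500


class TableFormatError(ValueError):
    """A file violates the expected dialect or a type invariant."""


class DuplicateIdError(TableFormatError):
    """A primary identifier column contains a repeated value."""


class ConsistencyError(TableFormatError):
    """Records contradict each other (e.g. pair kind vs chromosomes)."""


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path: object) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}; found {list(frame.columns)}")


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            dtype={c: str for c in required if not c.endswith(("_p", "fdr"))},
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise TableFormatError(f"{path}: cannot parse: {exc}") from exc
    _require_columns(frame, required, path)
    return frame


# ---------------------------------------------------------------------------
# Gene table
# ---------------------------------------------------------------------------

@dataclass
class GeneTable:
    """Per-gene chromosome, strand and TSS — the coordinate backbone.

    ``frame`` has columns ``gene_id, chrom, strand, tss`` (tss 1-based).
    """

    frame: pd.DataFrame
    _id_index: Dict[str, int] = field(init=False, repr=False)
    _chrom_codes: np.ndarray = field(init=False, repr=False)
    _chrom_names: List[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        frame = self.frame.reset_index(drop=True)
        _require_columns(frame, ("gene_id", "chrom", "strand", "tss"), "GeneTable")
        ids = frame["gene_id"].astype(str)
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise DuplicateIdError(f"duplicate gene_id(s): {dups[:5]}")
        frame["gene_id"] = ids
        frame["chrom"] = frame["chrom"].astype(str)
        if (frame["chrom"].str.len() == 0).any():
            raise TableFormatError("empty chromosome name")
        bad_strand = ~frame["strand"].isin(["+", "-"])
        if bad_strand.any():
            row = int(np.flatnonzero(bad_strand.to_numpy())[0])
            raise TableFormatError(f"row {row + 2}: strand must be '+' or '-'")
        frame["tss"] = pd.to_numeric(frame["tss"], errors="raise").astype(np.int64)
        if (frame["tss"] < 1).any():
            raise TableFormatError("tss coordinates must be >= 1 (1-based)")
        self.frame = frame
        self._id_index = {g: i for i, g in enumerate(frame["gene_id"])}
        cat = pd.Categorical(frame["chrom"])
        self._chrom_codes = np.asarray(cat.codes, dtype=np.int64)
        self._chrom_names = list(cat.categories)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._id_index

    @property
    def ids(self) -> np.ndarray:
        return self.frame["gene_id"].to_numpy()

    @property
    def tss(self) -> np.ndarray:
        return self.frame["tss"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.frame["chrom"].to_numpy()

    @property
    def strands(self) -> np.ndarray:
        return self.frame["strand"].to_numpy()

    @property
    def chrom_names(self) -> List[str]:
        """Distinct chromosome names (stable order)."""
        return list(self._chrom_names)

    @property
    def chrom_codes(self) -> np.ndarray:
        """Integer chromosome code per gene, aligned with :attr:`chrom_names`."""
        return self._chrom_codes

    def index_of(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Row indices of the given gene ids (KeyError on unknown id)."""
        idx = self._id_index
        return np.fromiter((idx[g] for g in gene_ids), dtype=np.int64)

    def chrom_of(self, gene_id: str) -> str:
        return self.frame["chrom"].iat[self._id_index[gene_id]]

    def tss_of(self, gene_id: str) -> int:
        return int(self.frame["tss"].iat[self._id_index[gene_id]])

    def genes_on(self, chrom: str) -> np.ndarray:
        """Gene ids located on one chromosome."""
        return self.frame.loc[self.frame["chrom"] == chrom, "gene_id"].to_numpy()


def read_gene_table(path) -> GeneTable:
    """Read a ``gene_id  chrom  strand  tss`` TSV into a validated table."""
    frame = _read_tsv(path, ("gene_id", "chrom", "strand", "tss"))
    try:
        return GeneTable(frame)
    except TableFormatError as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_gene_table(genes: GeneTable, path) -> None:
    genes.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Segments and chromosomal interactions
# ---------------------------------------------------------------------------

@dataclass
class InteractionSet:
    """Filtered segment-pair contact list plus segment intervals.

    ``segments``: columns ``segment_id, chrom, start, end`` (1-based closed).
    ``pairs``: columns ``seg_a, seg_b, kind, fdr``; unordered pairs stored
    with ``seg_a < seg_b`` lexicographically; ``kind`` is ``inter`` iff the
    two segments sit on different chromosomes. All retained pairs satisfy
    ``fdr <= fdr_cutoff``.
    """

    segments: pd.DataFrame
    pairs: pd.DataFrame
    fdr_cutoff: float = DEFAULT_INTERACTION_FDR_CUTOFF
    _seg_index: Dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seg = self.segments.reset_index(drop=True).copy()
        _require_columns(seg, ("segment_id", "chrom", "start", "end"), "segments")
        seg["segment_id"] = seg["segment_id"].astype(str)
        if seg["segment_id"].duplicated().any():
            raise DuplicateIdError("duplicate segment_id")
        seg["chrom"] = seg["chrom"].astype(str)
        seg["start"] = pd.to_numeric(seg["start"]).astype(np.int64)
        seg["end"] = pd.to_numeric(seg["end"]).astype(np.int64)
        if (seg["start"] < 1).any() or (seg["end"] < seg["start"]).any():
            raise TableFormatError("segment intervals must satisfy 1 <= start <= end")
        self.segments = seg
        self._seg_index = {s: i for i, s in enumerate(seg["segment_id"])}
        chrom_of = dict(zip(seg["segment_id"], seg["chrom"]))

        pairs = self.pairs.reset_index(drop=True).copy()
        _require_columns(pairs, ("seg_a", "seg_b", "kind", "fdr"), "pairs")
        pairs["seg_a"] = pairs["seg_a"].astype(str)
        pairs["seg_b"] = pairs["seg_b"].astype(str)
        pairs["fdr"] = pd.to_numeric(pairs["fdr"]).astype(float)
        for col in ("seg_a", "seg_b"):
            unknown = ~pairs[col].isin(self._seg_index)
            if unknown.any():
                raise ConsistencyError(f"unknown segment id in pairs: {pairs.loc[unknown, col].iloc[0]!r}")
        if (pairs["seg_a"] == pairs["seg_b"]).any():
            raise ConsistencyError("self-pair (segment interacting with itself) is not allowed")
        if (pairs["fdr"] > self.fdr_cutoff).any():
            raise ConsistencyError(f"pair with fdr above cutoff {self.fdr_cutoff} in a loaded InteractionSet")
        expected = np.where(
            pairs["seg_a"].map(chrom_of).to_numpy() == pairs["seg_b"].map(chrom_of).to_numpy(),
            "intra",
            "inter",
        )
        if "kind" in pairs and pairs["kind"].notna().any():
            mismatch = pairs["kind"].to_numpy() != expected
            if mismatch.any():
                i = int(np.flatnonzero(mismatch)[0])
                raise ConsistencyError(
                    f"pair ({pairs['seg_a'].iat[i]}, {pairs['seg_b'].iat[i]}) labeled "
                    f"{pairs['kind'].iat[i]!r} but chromosomes imply {expected[i]!r}"
                )
        pairs["kind"] = expected
        # canonical unordered representation, deduplicated (keep smallest fdr)
        swap = pairs["seg_a"] > pairs["seg_b"]
        pairs.loc[swap, ["seg_a", "seg_b"]] = pairs.loc[swap, ["seg_b", "seg_a"]].to_numpy()
        pairs = pairs.sort_values(["seg_a", "seg_b", "fdr"], kind="stable")
        pairs = pairs.drop_duplicates(["seg_a", "seg_b"], keep="first").reset_index(drop=True)
        self.pairs = pairs[["seg_a", "seg_b", "kind", "fdr"]]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pairs_of_kind(self, kind: str) -> pd.DataFrame:
        if kind not in ("inter", "intra"):
            raise ValueError(f"kind must be 'inter' or 'intra', got {kind!r}")
        return self.pairs[self.pairs["kind"] == kind]

    def segment_index(self) -> Dict[str, int]:
        return dict(self._seg_index)

    def adjacency(self, kind: str) -> Dict[str, Set[str]]:
        """Segment -> set of interacting segments, restricted to one kind."""
        adj: Dict[str, Set[str]] = {}
        sub = self.pairs_of_kind(kind)
        for a, b in zip(sub["seg_a"], sub["seg_b"]):
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj

    def midpoints(self) -> pd.Series:
        seg = self.segments
        mid = ((seg["start"] + seg["end"]) / 2.0).to_numpy()
        return pd.Series(mid, index=seg["segment_id"].to_numpy())


def read_interactions(
    pairs_path,
    segments_path,
    fdr_cutoff: float = DEFAULT_INTERACTION_FDR_CUTOFF,
) -> InteractionSet:
    """Read segment intervals and a BEDPE-like pair list, keeping pairs with
    ``fdr <= fdr_cutoff``. A ``kind`` column, if present, must agree with the
    chromosomes of the two segments."""
    seg = _read_tsv(segments_path, ("segment_id", "chrom", "start", "end"))
    pairs = _read_tsv(pairs_path, ("seg_a", "seg_b", "fdr"))
    if "kind" not in pairs.columns:
        pairs["kind"] = pd.NA
    pairs["fdr"] = pd.to_numeric(pairs["fdr"])
    n_raw = len(pairs)
    pairs = pairs[pairs["fdr"] <= fdr_cutoff]
    if len(pairs) < n_raw:
        logger.info("read_interactions: dropped %d/%d pairs above FDR cutoff %g", n_raw - len(pairs), n_raw, fdr_cutoff)
    return InteractionSet(segments=seg, pairs=pairs, fdr_cutoff=fdr_cutoff)


def write_interactions(interactions: InteractionSet, pairs_path, segments_path) -> None:
    interactions.segments.to_csv(segments_path, sep="\t", index=False)
    interactions.pairs.to_csv(pairs_path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# TF regulons (bound genes + knockout-affected genes)
# ---------------------------------------------------------------------------

@dataclass
class TFRegulon:
    """One TF's bound-gene set (with binding scores) and knockout-affected set.

    ``bound`` maps gene_id -> binding score (by default -log10 of the ChIP
    binding P-value, so larger = stronger binding). After filtering
    (``regulon_filtering``) the two sets are disjoint.
    """

    tf_id: str
    bound: Dict[str, float]
    ko_affected: Set[str]
    in_binding_data: bool = True
    in_ko_data: bool = True

    @property
    def bound_genes(self) -> Set[str]:
        return set(self.bound)

    def __repr__(self) -> str:  # compact: the dicts can be large
        return f"TFRegulon({self.tf_id!r}, n_bound={len(self.bound)}, n_ko={len(self.ko_affected)})"


def read_regulons(
    binding_path,
    ko_path,
    binding_p_cutoff: float = DEFAULT_BINDING_P_CUTOFF,
    genes: Optional[GeneTable] = None,
    score_transform=None,
) -> List[TFRegulon]:
    """Read long-format binding (``tf, gene, binding_p``) and knockout
    (``tf, gene``) tables into one regulon per TF.

    Bound genes are rows with ``binding_p <= binding_p_cutoff`` (inclusive).
    The stored score is ``-log10(binding_p)`` unless ``score_transform``
    overrides it. Gene ids absent from ``genes`` (when given) are dropped
    with a logged count. TFs present in only one of the two files get an
    empty set on the other side and are flagged via ``in_binding_data`` /
    ``in_ko_data``.
    """
    if score_transform is None:
        score_transform = lambda p: -math.log10(max(p, 1e-300))
    binding = _read_tsv(binding_path, ("tf", "gene", "binding_p"))
    ko = _read_tsv(ko_path, ("tf", "gene"))
    binding["binding_p"] = pd.to_numeric(binding["binding_p"])
    if (binding["binding_p"] < 0).any() or (binding["binding_p"] > 1).any():
        raise TableFormatError(f"{binding_path}: binding_p outside [0, 1]")

    n_dropped = 0
    if genes is not None:
        for name, frame in (("binding", binding), ("knockout", ko)):
            known = frame["gene"].isin(genes._id_index)
            n_dropped += int((~known).sum())
            if (~known).any():
                logger.warning("read_regulons: dropped %d %s rows with unknown gene ids", int((~known).sum()), name)
            if name == "binding":
                binding = frame[known]
            else:
                ko = frame[known]

    bound_rows = binding[binding["binding_p"] <= binding_p_cutoff]
    bound_by_tf: Dict[str, Dict[str, float]] = {}
    for tf, gene, p in zip(bound_rows["tf"], bound_rows["gene"], bound_rows["binding_p"]):
        bound_by_tf.setdefault(str(tf), {})[str(gene)] = float(score_transform(float(p)))
    ko_by_tf: Dict[str, Set[str]] = {}
    for tf, gene in zip(ko["tf"], ko["gene"]):
        ko_by_tf.setdefault(str(tf), set()).add(str(gene))

    binding_tfs = set(map(str, binding["tf"].unique()))
    ko_tfs = set(ko_by_tf)
    regulons: List[TFRegulon] = []
    for tf in sorted(binding_tfs | ko_tfs):
        reg = TFRegulon(
            tf_id=tf,
            bound=bound_by_tf.get(tf, {}),
            ko_affected=ko_by_tf.get(tf, set()),
            in_binding_data=tf in binding_tfs,
            in_ko_data=tf in ko_tfs,
        )
        if not reg.in_binding_data or not reg.in_ko_data:
            logger.info("read_regulons: TF %s present in only one dataset", tf)
        regulons.append(reg)
    return regulons


def write_regulons(regulons: Sequence[TFRegulon], binding_path, ko_path) -> None:
    """Inverse of :func:`read_regulons` (scores written back as P-values)."""
    brec = []
    krec = []
    for reg in regulons:
        for gene in sorted(reg.bound):
            brec.append((reg.tf_id, gene, 10.0 ** (-reg.bound[gene])))
        for gene in sorted(reg.ko_affected):
            krec.append((reg.tf_id, gene))
    pd.DataFrame(brec, columns=["tf", "gene", "binding_p"]).to_csv(binding_path, sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(krec, columns=["tf", "gene"]).to_csv(ko_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Flat GO-style annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """Flat term -> gene-set mapping for one category (CC or BP).

    TFs are annotated as ordinary gene ids. No ontology structure: two genes
    are co-annotated iff they share at least one term.
    """

    category: str
    terms: Dict[str, FrozenSet[str]]
    _gene_terms: Dict[str, FrozenSet[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.category not in ("CC", "BP"):
            raise TableFormatError(f"annotation category must be 'CC' or 'BP', got {self.category!r}")
        clean: Dict[str, FrozenSet[str]] = {}
        rev: Dict[str, Set[str]] = {}
        for term, members in self.terms.items():
            members = frozenset(members)
            if not members:
                raise TableFormatError(f"empty annotation term {term!r}")
            clean[term] = members
            for g in members:
                rev.setdefault(g, set()).add(term)
        self.terms = clean
        self._gene_terms = {g: frozenset(t) for g, t in rev.items()}

    def terms_of(self, gene_id: str) -> FrozenSet[str]:
        return self._gene_terms.get(gene_id, frozenset())

    def share_term(self, a: str, b: str) -> bool:
        return bool(self.terms_of(a) & self.terms_of(b))

    @property
    def annotated_genes(self) -> Set[str]:
        return set(self._gene_terms)


def read_annotations(path, category: str) -> AnnotationSet:
    """Read a GAF-like ``term  category  gene`` TSV, keeping one category."""
    frame = _read_tsv(path, ("term", "category", "gene"))
    frame = frame[frame["category"] == category]
    terms: Dict[str, Set[str]] = {}
    for term, gene in zip(frame["term"], frame["gene"]):
        terms.setdefault(str(term), set()).add(str(gene))
    return AnnotationSet(category=category, terms={t: frozenset(g) for t, g in terms.items()})


def write_annotations(sets: Sequence[AnnotationSet], path) -> None:
    rec = []
    for ann in sets:
        for term in sorted(ann.terms):
            for gene in sorted(ann.terms[term]):
                rec.append((term, ann.category, gene))
    pd.DataFrame(rec, columns=["term", "category", "gene"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x conditions matrix of real values; missing values allowed.

    Rows with fewer than ``min_observations`` non-missing values are not
    representable (the reader drops them with a logged count).
    """

    frame: pd.DataFrame
    min_observations: int = 3

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            raise DuplicateIdError("duplicate gene ids in expression matrix")
        counts = self.frame.notna().sum(axis=1)
        if (counts < self.min_observations).any():
            raise TableFormatError(
                f"expression rows with < {self.min_observations} non-missing values; filter at read time"
            )

    @property
    def n_conditions(self) -> int:
        return self.frame.shape[1]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.frame.index

    def row(self, gene_id: str) -> np.ndarray:
        return self.frame.loc[gene_id].to_numpy(dtype=float)


def read_expression(path, min_observations: int = 3) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    counts = frame.notna().sum(axis=1)
    keep = counts >= min_observations
    if (~keep).any():
        logger.warning("read_expression: dropped %d rows with < %d observations", int((~keep).sum()), min_observations)
    return ExpressionMatrix(frame=frame[keep], min_observations=min_observations)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.frame.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# Promoter nucleosome occupancy
# ---------------------------------------------------------------------------

@dataclass
class OccupancyTrackSet:
    """Per-gene occupancy over strand-oriented promoter positions [-500, -1].

    Column j holds position -(500 - j); the last column abuts the TSS on the
    coding strand. Tracks are stored already oriented: for minus-strand genes
    the genomic window was reversed at construction time.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.shape[1] != PROMOTER_WINDOW:
            raise TableFormatError(
                f"occupancy tracks must have {PROMOTER_WINDOW} positions, got {self.frame.shape[1]}"
            )
        if self.frame.index.duplicated().any():
            raise DuplicateIdError("duplicate gene ids in occupancy tracks")

    @property
    def positions(self) -> np.ndarray:
        """Promoter positions relative to TSS: -500 .. -1."""
        return np.arange(-PROMOTER_WINDOW, 0)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.frame.index

    def track(self, gene_id: str) -> np.ndarray:
        return self.frame.loc[gene_id].to_numpy(dtype=float)


def read_occupancy(path) -> OccupancyTrackSet:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    return OccupancyTrackSet(frame=frame)


def write_occupancy(occ: OccupancyTrackSet, path) -> None:
    occ.frame.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def orient_promoter_window(track_5to3: np.ndarray, strand: str) -> np.ndarray:
    """Orient a genomic upstream window into [-500, -1] transcription order.

    ``track_5to3`` is the genomic-coordinate window adjacent to the TSS
    (ascending coordinates). For minus-strand genes the upstream region lies
    at higher coordinates, so the vector is reversed to put position -1 next
    to the TSS.
    """
    arr = np.asarray(track_5to3, dtype=float)
    if arr.shape[-1] != PROMOTER_WINDOW:
        raise ValueError(f"expected {PROMOTER_WINDOW} positions")
    if strand == "+":
        return arr
    if strand == "-":
        return arr[..., ::-1]
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


# ---------------------------------------------------------------------------
# Unbound-motif table
# ---------------------------------------------------------------------------

@dataclass
class MotifTable:
    """(tf, gene) pairs whose promoter carries the TF's motif without binding."""

    pairs: FrozenSet[Tuple[str, str]]

    def has_motif(self, tf_id: str, gene_id: str) -> bool:
        return (tf_id, gene_id) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def read_motifs(path) -> MotifTable:
    frame = _read_tsv(path, ("tf", "gene"))
    return MotifTable(pairs=frozenset(zip(frame["tf"].astype(str), frame["gene"].astype(str))))


def write_motifs(motifs: MotifTable, path) -> None:
    frame = pd.DataFrame(sorted(motifs.pairs), columns=["tf", "gene"])
    frame.to_csv(path, sep="\t", index=False)
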