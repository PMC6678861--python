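"""Shared fixtures: toy table builders and session-scoped synthetic datasets."""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
import pytest

from sarloc.core_io import GeneTable, InteractionSet, TFRegulon
from sarloc.colocalization import classify_sar, filter_intra_by_separation, map_genes_to_segments
from sarloc.simulate import SimConfig, simulate


def make_genes(rows: Sequence[Tuple[str, str, str, int]]) -> GeneTable:
    """rows of (gene_id, chrom, strand, tss)."""
    return GeneTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"]))


def make_interactions(
    segments: Sequence[Tuple[str, str, int, int]],
    pairs: Sequence[Tuple[str, str]],
    fdr: float = 1e-5,
) -> InteractionSet:
    """segments of (segment_id, chrom, start, end); pairs of (seg_a, seg_b)."""
    seg = pd.DataFrame(segments, columns=["segment_id", "chrom", "start", "end"])
    pr = pd.DataFrame(pairs, columns=["seg_a", "seg_b"])
    pr["kind"] = pd.NA
    pr["fdr"] = fdr
    return InteractionSet(segments=seg, pairs=pr)


def make_regulon(tf_id: str, bound: Iterable[str], ko: Iterable[str], score: float = 3.0) -> TFRegulon:
    return TFRegulon(tf_id=tf_id, bound={g: score for g in bound}, ko_affected=set(ko))


#: Compact configuration for fast end-to-end tests.
SMALL_SIM = SimConfig(
    n_chromosomes=6,
    genes_per_chromosome=25,
    n_tfs=6,
    bound_size=22,
    ko_size=22,
    seed=5,
)


@pytest.fixture(scope="session")
def null_dataset():
    return simulate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def strong_dataset():
    return simulate(dataclasses.replace(SimConfig(seed=11), planted_enrichment=5.0))


@pytest.fixture(scope="session")
def strong_classified(strong_dataset):
    """Strong dataset run through filtering-free classification."""
    ds = strong_dataset
    inter = filter_intra_by_separation(ds.interactions)
    gmap = map_genes_to_segments(ds.genes, inter)
    classifications = [classify_sar(reg, gmap, inter) for reg in ds.regulons]
    return ds, inter, gmap, classifications
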