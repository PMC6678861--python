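"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's indexed/vectorized code paths:
colocalization by a double loop over gene pairs and the raw pair list,
and the rank-sum P value by exhaustive enumeration of rank assignments.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from sarloc.core_io import GeneTable, InteractionSet, TFRegulon
from sarloc.colocalization import GeneSegmentMap


def colocalized_bruteforce(
    gene_a: str,
    gene_b: str,
    gmap: GeneSegmentMap,
    pair_rows: Sequence[Tuple[str, str, str]],
    mode: str,
) -> bool:
    """Scan the raw (seg_a, seg_b, kind) rows for a connecting pair."""
    segs_a = gmap.segments_of(gene_a)
    segs_b = gmap.segments_of(gene_b)
    for sa, sb, kind in pair_rows:
        if kind != mode:
            continue
        if (sa in segs_a and sb in segs_b) or (sb in segs_a and sa in segs_b):
            return True
    return False


def classify_bruteforce(
    regulon: TFRegulon,
    gmap: GeneSegmentMap,
    interactions: InteractionSet,
) -> Dict[str, Dict[str, Set[str]]]:
    """Per mode, KO gene -> set of colocalized bound partners, by a naive
    double loop over all (KO, bound) gene pairs and the raw pair list."""
    pair_rows = list(zip(interactions.pairs["seg_a"], interactions.pairs["seg_b"], interactions.pairs["kind"]))
    out: Dict[str, Dict[str, Set[str]]] = {"inter": {}, "intra": {}}
    for mode in ("inter", "intra"):
        for ko in sorted(regulon.ko_affected):
            partners = {
                b for b in sorted(regulon.bound) if colocalized_bruteforce(ko, b, gmap, pair_rows, mode)
            }
            if partners:
                out[mode][ko] = partners
    return out


def mwu_exact_enumeration(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney P by enumerating all rank assignments.

    Valid for tie-free samples. P = P(U at least as extreme as observed)
    under the uniform distribution over all C(n+m, n) group-A position
    subsets; two-sided as 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == n + m, "oracle requires tie-free input"
    order = np.argsort(pooled)
    ranks = np.empty(n + m, dtype=float)
    ranks[order] = np.arange(1, n + m + 1)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)

    total = comb(n + m, n)
    le = ge = 0
    for subset in combinations(range(n + m), n):
        u = sum(ranks[list(subset)]) - n * (n + 1) / 2
        if u <= u_obs:
            le += 1
        if u >= u_obs:
            ge += 1
    return min(1.0, 2.0 * min(le / total, ge / total))


def random_instance(rng: np.random.Generator):
    """A random small colocalization instance: genes, interactions and one
    regulon (<= 50 genes, <= 100 interaction pairs, 1-3 chromosomes)."""
    n_chrom = int(rng.integers(1, 4))
    chroms = [f"chr{c + 1}" for c in range(n_chrom)]
    n_genes = int(rng.integers(6, 51))
    genes = GeneTable(
        pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n_genes)],
                "chrom": rng.choice(chroms, size=n_genes),
                "strand": rng.choice(["+", "-"], size=n_genes),
                "tss": rng.integers(1, 100_000, size=n_genes),
            }
        )
    )
    n_seg = int(rng.integers(4, 31))
    starts = rng.integers(1, 100_000, size=n_seg)
    lengths = rng.integers(500, 5001, size=n_seg)
    segments = pd.DataFrame(
        {
            "segment_id": [f"s{i}" for i in range(n_seg)],
            "chrom": rng.choice(chroms, size=n_seg),
            "start": starts,
            "end": starts + lengths,
        }
    )
    n_pairs = int(rng.integers(0, 101))
    rows = []
    for _ in range(n_pairs):
        i, j = rng.choice(n_seg, size=2, replace=False)
        rows.append((f"s{i}", f"s{j}", 1e-5))
    pairs = pd.DataFrame(rows, columns=["seg_a", "seg_b", "fdr"])
    pairs["kind"] = pd.NA
    interactions = InteractionSet(segments=segments, pairs=pairs)

    ids = list(genes.ids)
    rng.shuffle(ids)
    nb = int(rng.integers(1, max(2, n_genes // 3)))
    nk = int(rng.integers(1, max(2, n_genes // 3)))
    regulon = TFRegulon(
        tf_id="tfX",
        bound={g: 3.0 for g in ids[:nb]},
        ko_affected=set(ids[nb : nb + nk]),
    )
    return genes, interactions, regulon
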