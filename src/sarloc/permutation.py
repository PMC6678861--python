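"""Chromosome-matched randomization engine and empirical P values.

The null model replaces every gene of a set by a gene drawn uniformly from
the same chromosome (without replacement within one drawn set), preserving
the per-chromosome composition of each TF's gene sets — chromosomal
preference of TF regulation is thereby kept out of the signal. A test
statistic (any function of the per-TF knockout and bound index-sets) is
recomputed on ``n_reps`` independent randomized replicates; the empirical
P value is the fraction of replicates whose statistic strictly exceeds the
observed one. Ties therefore count as not exceeding; a conservative
(count+1)/(n_reps+1) estimator is available alongside.

Replicate r draws from a substream derived deterministically from
``(seed, r)``, so results are bit-identical for a fixed seed and
independent of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .core_io import GeneTable

logger = logging.getLogger("sarloc")

Statistic = Callable[[Mapping[str, np.ndarray], Mapping[str, np.ndarray]], float]


@dataclass
class PermutationResult:
    """Observed statistic, null sample and empirical P value.

    ``p_empirical`` is the strict-exceedance fraction ``exceed_count /
    n_reps``; ``p_conservative`` is ``(exceed_count + 1) / (n_reps + 1)``,
    never exactly zero. When no replicate exceeds the observation,
    ``p_label`` reports the resolution bound ``"< 1/n_reps"``.
    """

    observed: float
    null_sample: np.ndarray
    n_reps: int
    exceed_count: int
    seed: int
    randomize: str

    def __post_init__(self) -> None:
        self.null_sample = np.asarray(self.null_sample, dtype=float)
        if len(self.null_sample) != self.n_reps:
            raise ValueError("null_sample length must equal n_reps")
        if not 0 <= self.exceed_count <= self.n_reps:
            raise ValueError("exceed_count out of range")

    @property
    def p_empirical(self) -> float:
        return self.exceed_count / self.n_reps

    @property
    def p_conservative(self) -> float:
        return (self.exceed_count + 1) / (self.n_reps + 1)

    @property
    def p_label(self) -> str:
        if self.exceed_count == 0:
            return f"< {1 / self.n_reps:g}"
        return f"{self.p_empirical:g}"

    def p_value(self, estimator: str = "strict") -> float:
        if estimator == "strict":
            return self.p_empirical
        if estimator == "conservative":
            return self.p_conservative
        raise ValueError(f"estimator must be 'strict' or 'conservative', got {estimator!r}")


def draw_matched_random_set(
    gene_set: Iterable[str],
    genes: GeneTable,
    rng: np.random.Generator,
) -> Set[str]:
    """Draw a chromosome-matched random gene set of equal size.

    Per chromosome, as many genes as the actual set has there are sampled
    uniformly *without replacement* from all genes on that chromosome; the
    actual genes themselves are eligible draws. Raises if a chromosome has
    fewer candidates than needed.
    """
    gene_set = list(gene_set)
    need: Dict[str, int] = {}
    for g in gene_set:
        chrom = genes.chrom_of(g)  # KeyError on unknown gene
        need[chrom] = need.get(chrom, 0) + 1
    out: Set[str] = set()
    for chrom in sorted(need):
        pool = genes.genes_on(chrom)
        k = need[chrom]
        if len(pool) < k:
            raise ValueError(f"chromosome {chrom}: {len(pool)} candidate genes < {k} needed")
        out.update(rng.choice(pool, size=k, replace=False))
    return out


class MatchedSampler:
    """Vectorized chromosome-matched sampler over many TF gene sets.

    Precomputes each TF set's per-chromosome composition; one call to
    :meth:`draw` returns an independent matched random set (as gene row
    indices) per TF, sampled without replacement within each set.
    """

    def __init__(self, genes: GeneTable, sets_by_tf: Mapping[str, np.ndarray]):
        self.tfs: List[str] = list(sets_by_tf)
        codes = genes.chrom_codes
        n_chrom = len(genes.chrom_names)
        self.pools: List[np.ndarray] = [
            np.flatnonzero(codes == c).astype(np.int64) for c in range(n_chrom)
        ]
        self.counts = np.zeros((len(self.tfs), n_chrom), dtype=np.int64)
        for i, tf in enumerate(self.tfs):
            idx = np.asarray(sets_by_tf[tf], dtype=np.int64)
            if len(np.unique(idx)) != len(idx):
                raise ValueError(f"TF {tf}: duplicate genes in set")
            self.counts[i] = np.bincount(codes[idx], minlength=n_chrom)
        for c, pool in enumerate(self.pools):
            over = self.counts[:, c] > len(pool)
            if over.any():
                tf = self.tfs[int(np.flatnonzero(over)[0])]
                raise ValueError(f"TF {tf}: needs more genes than available on chromosome index {c}")

    def draw(self, rng: np.random.Generator) -> Dict[str, np.ndarray]:
        parts: List[List[np.ndarray]] = [[] for _ in self.tfs]
        for c, pool in enumerate(self.pools):
            need = self.counts[:, c]
            active = np.flatnonzero(need)
            if len(active) == 0:
                continue
            keys = rng.random((len(active), len(pool)))
            order = np.argsort(keys, axis=1)
            for row, i in enumerate(active):
                parts[i].append(pool[order[row, : need[i]]])
        empty = np.empty(0, dtype=np.int64)
        return {
            tf: (np.concatenate(parts[i]) if parts[i] else empty)
            for i, tf in enumerate(self.tfs)
        }


def _as_index_sets(sets_by_tf: Mapping[str, object], genes: GeneTable) -> Dict[str, np.ndarray]:
    out: Dict[str, np.ndarray] = {}
    for tf, s in sets_by_tf.items():
        arr = np.asarray(s)
        if arr.dtype.kind in "iu":
            out[tf] = arr.astype(np.int64)
        else:
            out[tf] = genes.index_of(sorted(map(str, s)))
    return out


def permutation_test(
    statistic: Statistic,
    ko_sets: Mapping[str, object],
    bound_sets: Optional[Mapping[str, object]],
    genes: GeneTable,
    n_reps: int = 10000,
    seed: int = 0,
    randomize: str = "both",
) -> PermutationResult:
    """Empirical permutation test of a pooled statistic.

    Parameters
    ----------
    statistic
        Function of ``(ko_sets, bound_sets)`` where each is a dict
        tf -> array of gene row indices into ``genes``. For the
        colocalization test both sides are randomized every replicate
        (``randomize='both'``); for the cellular co-component test only the
        gene side is randomized (``randomize='ko_only'``) and ``bound_sets``
        is passed through unchanged (it may be ``None``).
    ko_sets, bound_sets
        Per-TF gene sets, given as gene-id iterables or index arrays.
    n_reps
        Number of randomized replicates (the study default is 10,000).

    Notes
    -----
    The empirical P value counts replicates whose statistic is *strictly*
    greater than the observed value, so it tests for enrichment above the
    null.
    """
    if randomize not in ("both", "ko_only"):
        raise ValueError(f"randomize must be 'both' or 'ko_only', got {randomize!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ko_idx = _as_index_sets(ko_sets, genes)
    bound_idx = _as_index_sets(bound_sets, genes) if bound_sets is not None else None
    observed = float(statistic(ko_idx, bound_idx))

    ko_sampler = MatchedSampler(genes, ko_idx)
    bd_sampler = MatchedSampler(genes, bound_idx) if (randomize == "both" and bound_idx is not None) else None

    null = np.empty(n_reps, dtype=float)
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), r)))
        rko = ko_sampler.draw(rng)
        rbd = bd_sampler.draw(rng) if bd_sampler is not None else bound_idx
        try:
            null[r] = statistic(rko, rbd)
        except Exception as exc:
            raise RuntimeError(f"statistic failed on replicate {r}: {exc}") from exc
    exceed = int((null > observed).sum())
    return PermutationResult(
        observed=observed,
        null_sample=null,
        n_reps=n_reps,
        exceed_count=exceed,
        seed=int(seed),
        randomize=randomize,
    )
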