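"""Synthetic-data generator with known ground truth.

Emits a complete, self-consistent set of pipeline inputs: genes laid out
at fixed spacing on multiple chromosomes, kilobase segments tiling each
chromosome, a chromosomal-interaction graph with Bernoulli background
contacts plus an optional planted excess of (bound gene, KO gene)
contacts per TF, overlapping flat GO-style annotations, a block-correlated
expression matrix, promoter occupancy tracks elevated at planted-SAR
promoters, and per-(TF, gene) motif presence.

With ``planted_enrichment = 1`` every (bound, KO) segment pair has exactly
the background contact probability, so the generator is an exact null for
the colocalization permutation test. With enrichment e > 1 the total
contact probability of eligible planted pairs is e times the background
rate (a Bernoulli top-up on top of the background draw), and every planted
contact is recorded in the ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import core_io
from .core_io import (
    AnnotationSet,
    ExpressionMatrix,
    GeneTable,
    InteractionSet,
    MotifTable,
    OccupancyTrackSet,
    TFRegulon,
)

logger = logging.getLogger("sarloc")


@dataclass
class SimConfig:
    """Parameters of the synthetic genome and planted signals.

    Sizes follow the scaled-down study design used throughout the test
    suite: 16 chromosomes, 20 TFs with 30 bound and 30 knockout-affected
    genes each, 112 expression conditions. ``background_contact_rate`` is
    the Bernoulli probability of a contact per eligible segment pair;
    ``planted_enrichment`` multiplies it on (bound, KO) segment pairs.
    """

    n_chromosomes: int = 16
    genes_per_chromosome: int = 40
    gene_spacing_bp: int = 5000
    segment_length_bp: int = 3000
    n_tfs: int = 20
    bound_size: int = 30
    ko_size: int = 30
    background_contact_rate: float = 1e-3
    planted_enrichment: float = 1.0
    intra_min_sep_bp: int = 60000  # used only to label planted SAR truth
    fdr_cutoff: float = core_io.DEFAULT_INTERACTION_FDR_CUTOFF
    cc_coplanting_prob: float = 0.5
    bp_coplanting_prob: float = 0.78
    bp_background_prob: float = 0.66
    n_conditions: int = 112
    expr_block_correlation: float = 0.5
    occupancy_offset_sar: float = 0.5
    occupancy_noise_sd: float = 0.1
    motif_rate_sar: float = 0.30
    motif_rate_other: float = 0.32
    affinity_shift_coloc: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        n_genes = self.n_chromosomes * self.genes_per_chromosome
        if min(self.n_chromosomes, self.genes_per_chromosome, self.n_tfs, self.bound_size, self.ko_size) < 1:
            raise ValueError("counts must be positive")
        if self.gene_spacing_bp < 1 or self.segment_length_bp < 1:
            raise ValueError("spacings must be positive")
        if self.bound_size + self.ko_size > n_genes:
            raise ValueError("bound_size + ko_size exceeds the number of genes")
        if n_genes < 2 * (self.bound_size + self.ko_size):
            raise ValueError("need genes_per_chromosome * n_chromosomes >= 2 * (bound_size + ko_size)")
        for name in ("cc_coplanting_prob", "bp_coplanting_prob", "bp_background_prob",
                     "motif_rate_sar", "motif_rate_other"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.background_contact_rate < 1.0:
            raise ValueError("background_contact_rate must be in (0, 1)")
        if self.planted_enrichment < 1.0:
            raise ValueError("planted_enrichment must be >= 1")
        if not 0.0 <= self.expr_block_correlation < 1.0:
            raise ValueError("expr_block_correlation must be in [0, 1)")
        if self.n_conditions < 3:
            raise ValueError("n_conditions must be >= 3")

    def to_dict(self) -> Dict[str, object]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "SimConfig":
        return cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks.

    ``planted_contacts``: per TF, the (bound gene, KO gene) pairs whose
    primary segments were additionally connected. ``true_sar``: per TF, the
    KO genes with at least one planted contact that survives the pipeline's
    interaction filters (inter, or intra separated by >= the configured
    minimum). ``true_coloc_bound``: the bound-side genes of those surviving
    contacts.
    """

    planted_contacts: Dict[str, Set[Tuple[str, str]]]
    planted_segment_pairs: Set[Tuple[str, str]]
    true_sar: Dict[str, Set[str]]
    true_coloc_bound: Dict[str, Set[str]]
    bp_planted_members: Dict[str, Set[str]]
    expression_block_of: Dict[str, str]

    def all_true_sar_genes(self) -> Set[str]:
        out: Set[str] = set()
        for s in self.true_sar.values():
            out |= s
        return out


@dataclass
class SimulatedDataset:
    """In-memory bundle of all generated inputs plus the ground truth."""

    config: SimConfig
    genes: GeneTable
    interactions: InteractionSet
    regulons: List[TFRegulon]
    cc: AnnotationSet
    bp: AnnotationSet
    expression: ExpressionMatrix
    occupancy: OccupancyTrackSet
    motifs: MotifTable
    ground_truth: GroundTruth

    def write(self, out_dir) -> Dict[str, str]:
        """Write every input table (and the ground truth / config as JSON)
        into ``out_dir``; returns a manifest of file paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest: Dict[str, str] = {}

        def _p(name: str) -> str:
            manifest[name.split(".")[0]] = str(out / name)
            return str(out / name)

        core_io.write_gene_table(self.genes, _p("genes.tsv"))
        core_io.write_interactions(self.interactions, _p("interactions.tsv"), _p("segments.tsv"))
        core_io.write_regulons(self.regulons, _p("binding.tsv"), _p("knockout.tsv"))
        core_io.write_annotations([self.cc, self.bp], _p("annotations.tsv"))
        core_io.write_expression(self.expression, _p("expression.tsv"))
        core_io.write_occupancy(self.occupancy, _p("occupancy.tsv"))
        core_io.write_motifs(self.motifs, _p("motifs.tsv"))
        gt = {
            "planted_contacts": {tf: sorted(map(list, s)) for tf, s in self.ground_truth.planted_contacts.items()},
            "planted_segment_pairs": sorted(map(list, self.ground_truth.planted_segment_pairs)),
            "true_sar": {tf: sorted(s) for tf, s in self.ground_truth.true_sar.items()},
            "true_coloc_bound": {tf: sorted(s) for tf, s in self.ground_truth.true_coloc_bound.items()},
        }
        with open(_p("ground_truth.json"), "w") as fh:
            json.dump(gt, fh, sort_keys=True, indent=1)
        with open(_p("sim_config.json"), "w") as fh:
            json.dump(self.config.to_dict(), fh, sort_keys=True, indent=1)
        return manifest


def simulate(config: SimConfig) -> SimulatedDataset:
    """Generate one complete synthetic dataset (deterministic in the seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_chrom = config.n_chromosomes
    gpc = config.genes_per_chromosome
    n_genes = n_chrom * gpc
    seg_len = config.segment_length_bp

    # --- genes at fixed spacing -------------------------------------------
    chrom_names = [f"chr{c + 1:02d}" for c in range(n_chrom)]
    chrom_len = gpc * config.gene_spacing_bp + 2000
    gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    gene_chrom = np.repeat(np.arange(n_chrom), gpc)
    gene_tss = np.tile(1500 + np.arange(gpc, dtype=np.int64) * config.gene_spacing_bp, n_chrom)
    strands = rng.choice(np.array(["+", "-"]), size=n_genes)
    genes = GeneTable(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "chrom": [chrom_names[c] for c in gene_chrom],
                "strand": strands,
                "tss": gene_tss,
            }
        )
    )

    # --- segments tiling each chromosome ----------------------------------
    segs_per_chrom = -(-chrom_len // seg_len)  # ceil
    n_seg = n_chrom * segs_per_chrom
    seg_ids = [f"seg{i + 1:05d}" for i in range(n_seg)]
    seg_chrom = np.repeat(np.arange(n_chrom), segs_per_chrom)
    seg_start = np.tile(1 + np.arange(segs_per_chrom, dtype=np.int64) * seg_len, n_chrom)
    seg_end = np.minimum(seg_start + seg_len - 1, chrom_len)
    seg_mid = (seg_start + seg_end) / 2.0
    segments = pd.DataFrame(
        {
            "segment_id": seg_ids,
            "chrom": [chrom_names[c] for c in seg_chrom],
            "start": seg_start,
            "end": seg_end,
        }
    )
    # primary segment of each gene: the tile containing its TSS
    gene_primary_seg = gene_chrom * segs_per_chrom + (gene_tss - 1) // seg_len

    # --- TF gene sets -------------------------------------------------------
    tf_ids = [f"tf{t + 1:02d}" for t in range(config.n_tfs)]
    bound_idx: Dict[str, np.ndarray] = {}
    ko_idx: Dict[str, np.ndarray] = {}
    for tf in tf_ids:
        perm = rng.permutation(n_genes)
        bound_idx[tf] = np.sort(perm[: config.bound_size])
        ko_idx[tf] = np.sort(perm[config.bound_size : config.bound_size + config.ko_size])

    # --- background contacts (Bernoulli per eligible segment pair) ---------
    iu_a, iu_b = np.triu_indices(n_seg, k=1)
    contact = np.zeros((n_seg, n_seg), dtype=bool)
    bg = rng.random(len(iu_a)) < config.background_contact_rate
    contact[iu_a[bg], iu_b[bg]] = True

    # --- planted excess on (bound, KO) primary-segment pairs ---------------
    e, r = config.planted_enrichment, config.background_contact_rate
    p_add = 0.0 if e <= 1.0 else min(1.0, (min(e * r, 1.0) - r) / (1.0 - r))
    planted_contacts: Dict[str, Set[Tuple[str, str]]] = {tf: set() for tf in tf_ids}
    planted_segment_pairs: Set[Tuple[str, str]] = set()
    true_sar: Dict[str, Set[str]] = {tf: set() for tf in tf_ids}
    true_coloc_bound: Dict[str, Set[str]] = {tf: set() for tf in tf_ids}
    if p_add > 0.0:
        for tf in tf_ids:
            draws = rng.random((len(bound_idx[tf]), len(ko_idx[tf]))) < p_add
            for bi, ki in zip(*np.nonzero(draws)):
                gb, gk = int(bound_idx[tf][bi]), int(ko_idx[tf][ki])
                sb, sk = int(gene_primary_seg[gb]), int(gene_primary_seg[gk])
                if sb == sk:
                    continue
                lo, hi = min(sb, sk), max(sb, sk)
                contact[lo, hi] = True
                planted_contacts[tf].add((gene_ids[gb], gene_ids[gk]))
                planted_segment_pairs.add((seg_ids[lo], seg_ids[hi]))
                survives = seg_chrom[sb] != seg_chrom[sk] or abs(seg_mid[sb] - seg_mid[sk]) >= config.intra_min_sep_bp
                if survives:
                    true_sar[tf].add(gene_ids[gk])
                    true_coloc_bound[tf].add(gene_ids[gb])

    ci, cj = np.nonzero(contact)
    fdr = rng.uniform(0.0, config.fdr_cutoff, size=len(ci))
    pairs = pd.DataFrame(
        {
            "seg_a": [seg_ids[i] for i in ci],
            "seg_b": [seg_ids[j] for j in cj],
            "kind": np.where(seg_chrom[ci] == seg_chrom[cj], "intra", "inter"),
            "fdr": fdr,
        }
    )
    interactions = InteractionSet(segments=segments, pairs=pairs, fdr_cutoff=config.fdr_cutoff)

    all_true_sar: Set[str] = set()
    for s in true_sar.values():
        all_true_sar |= s

    # --- binding scores (stronger on colocalized bound events) -------------
    regulons: List[TFRegulon] = []
    for tf in tf_ids:
        scores = rng.uniform(2.31, 6.0, size=len(bound_idx[tf]))  # -log10 p, p <= 0.0049
        bound: Dict[str, float] = {}
        for gi, s in zip(bound_idx[tf], scores):
            g = gene_ids[int(gi)]
            if g in true_coloc_bound[tf]:
                s = s + config.affinity_shift_coloc
            bound[g] = float(s)
        regulons.append(
            TFRegulon(tf_id=tf, bound=bound, ko_affected={gene_ids[int(i)] for i in ko_idx[tf]})
        )

    # --- flat annotations ---------------------------------------------------
    cc_terms: Dict[str, Set[str]] = {}
    for i in range(config.n_tfs):
        for j in range(i + 1, config.n_tfs):
            if rng.random() < config.cc_coplanting_prob:
                cc_terms[f"cc_complex_{tf_ids[i]}_{tf_ids[j]}"] = {tf_ids[i], tf_ids[j]}
    # a broad gene-only compartment term (no TFs, so TF sharing is unaffected)
    broad = rng.random(n_genes) < 0.3
    if broad.any():
        cc_terms["cc_cytoplasm"] = {gene_ids[i] for i in np.flatnonzero(broad)}
    cc = AnnotationSet(category="CC", terms={t: frozenset(m) for t, m in cc_terms.items()})

    bp_terms: Dict[str, Set[str]] = {}
    bp_planted_members: Dict[str, Set[str]] = {tf: set() for tf in tf_ids}
    for tf in tf_ids:
        members = {gene_ids[int(i)] for i in bound_idx[tf]}
        for ki in ko_idx[tf]:
            g = gene_ids[int(ki)]
            p = config.bp_coplanting_prob if g in true_sar[tf] else config.bp_background_prob
            if rng.random() < p:
                members.add(g)
                bp_planted_members[tf].add(g)
        bp_terms[f"bp_process_{tf}"] = members
    misc = rng.random(n_genes) < 0.2
    if misc.any():
        bp_terms["bp_misc"] = {gene_ids[i] for i in np.flatnonzero(misc)}
    bp = AnnotationSet(category="BP", terms={t: frozenset(m) for t, m in bp_terms.items()})

    # --- block-correlated expression ---------------------------------------
    C = config.n_conditions
    loading = float(np.sqrt(config.expr_block_correlation))
    factors = rng.standard_normal((config.n_tfs, C))
    block_of: Dict[str, str] = {}
    block_row = np.full(n_genes, -1, dtype=np.int64)
    for t, tf in enumerate(tf_ids):
        for gi in np.concatenate([bound_idx[tf], ko_idx[tf]]):
            g = gene_ids[int(gi)]
            in_block = g in {gene_ids[int(i)] for i in bound_idx[tf]} or g in true_sar[tf]
            if in_block and block_row[gi] < 0:
                block_row[gi] = t
                block_of[g] = tf
    noise = rng.standard_normal((n_genes, C))
    X = noise.copy()
    has_block = block_row >= 0
    # unit marginal variance for every gene; within-block pairwise r = loading^2
    X[has_block] = np.sqrt(1.0 - loading**2) * noise[has_block] + loading * factors[block_row[has_block]]
    expression = ExpressionMatrix(
        frame=pd.DataFrame(X, index=pd.Index(gene_ids, name="gene_id"), columns=[f"c{j + 1:03d}" for j in range(C)])
    )

    # --- promoter occupancy -------------------------------------------------
    occ = rng.normal(1.0, config.occupancy_noise_sd, size=(n_genes, core_io.PROMOTER_WINDOW))
    for g in all_true_sar:
        occ[genes.index_of([g])[0]] += config.occupancy_offset_sar
    occupancy = OccupancyTrackSet(
        frame=pd.DataFrame(
            occ,
            index=pd.Index(gene_ids, name="gene_id"),
            columns=[str(p) for p in range(-core_io.PROMOTER_WINDOW, 0)],
        )
    )

    # --- unbound-motif presence --------------------------------------------
    motif_pairs: Set[Tuple[str, str]] = set()
    for tf in tf_ids:
        for ki in ko_idx[tf]:
            g = gene_ids[int(ki)]
            rate = config.motif_rate_sar if g in true_sar[tf] else config.motif_rate_other
            if rng.random() < rate:
                motif_pairs.add((tf, g))
    motifs = MotifTable(pairs=frozenset(motif_pairs))

    ground_truth = GroundTruth(
        planted_contacts=planted_contacts,
        planted_segment_pairs=planted_segment_pairs,
        true_sar=true_sar,
        true_coloc_bound=true_coloc_bound,
        bp_planted_members=bp_planted_members,
        expression_block_of=block_of,
    )
    return SimulatedDataset(
        config=config,
        genes=genes,
        interactions=interactions,
        regulons=regulons,
        cc=cc,
        bp=bp,
        expression=expression,
        occupancy=occupancy,
        motifs=motifs,
        ground_truth=ground_truth,
    )


FIXTURE_LEVELS: Dict[str, float] = {"null": 1.0, "weak": 2.0, "strong": 5.0}


def write_fixture_suite(out_dir, base_config: Optional[SimConfig] = None, seed: int = 0) -> Dict[str, object]:
    """Write the three canonical fixtures (null / weak / strong planted
    enrichment) plus a manifest of seeds and configs. Deterministic: the
    same call produces byte-identical files."""
    base = base_config or SimConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {"fixtures": {}}
    for k, (name, enrichment) in enumerate(sorted(FIXTURE_LEVELS.items())):
        cfg = dataclasses.replace(base, planted_enrichment=enrichment, seed=(seed * 3 + k) % (2**31))
        dataset = simulate(cfg)
        files = dataset.write(out / name)
        manifest["fixtures"][name] = {
            "config": cfg.to_dict(),
            "seed": cfg.seed,
            "files": files,
            "sha256": {n: _file_sha256(p) for n, p in sorted(files.items())},
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    manifest["path"] = str(out / "manifest.json")
    return manifest


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
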