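"""End-to-end pipeline: load or simulate inputs, filter regulons, classify
SAR genes, run the permutation tests and the functional/chromatin
contrasts, and emit a machine-readable summary.

One global seed drives every stochastic stage through deterministically
derived per-stage substreams, so re-running a configuration reproduces the
summary byte for byte, and disabling one analysis does not perturb the
random draws of another.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from . import core_io
from .colocalization import (
    ColocalizationIndex,
    SARClassification,
    classify_sar,
    filter_intra_by_separation,
    frequency_statistic,
    map_genes_to_segments,
    partner_count_summary,
    pooled_frequency,
    regulon_index_sets,
)
from .core_io import (
    AnnotationSet,
    ExpressionMatrix,
    GeneTable,
    InteractionSet,
    MotifTable,
    OccupancyTrackSet,
    TFRegulon,
)
from .filtering import FilterConfig, assert_filtered, filter_regulons
from .functional import (
    CoComponentIndex,
    bp_coprocess_frequency,
    cc_cocomponent_frequency,
    cc_cocomponent_statistic,
    coexpression_contrast,
    expression_variability_contrast,
    pairwise_bound_coexpression,
)
from .chromatin import (
    affinity_contrast,
    motif_presence_frequency,
    occupancy_contrast,
    tf_count_contrast,
)
from .permutation import PermutationResult, permutation_test
from .simulate import SimConfig, SimulatedDataset, simulate

logger = logging.getLogger("sarloc")

SUMMARY_SCHEMA_VERSION = "1"

#: Fixed per-stage seed offsets (derived from the global seed); keeping the
#: offsets stable means toggling one analysis never shifts another's draws.
STAGE_SEED_OFFSETS = {
    "perm_inter_ko_vs_bound": 11,
    "perm_intra_ko_vs_bound": 12,
    "perm_inter_bound_vs_ko": 13,
    "perm_intra_bound_vs_ko": 14,
    "perm_cc_cocomponent": 15,
    "bootstrap": 16,
}


@dataclass
class RunConfig:
    """All pipeline parameters with the study defaults.

    Exactly one of ``input_dir`` (a directory of input tables, in the
    dialect ``SimulatedDataset.write`` emits) or ``sim`` (a synthetic-data
    configuration) must be provided.
    """

    input_dir: Optional[str] = None
    sim: Optional[SimConfig] = None
    binding_p_cutoff: float = 0.005
    interaction_fdr_cutoff: float = 1e-4
    proximity_bp: int = 3000
    min_set_size: int = 20
    tss_window_bp: int = 2500
    min_intra_sep_bp: int = 60000
    n_reps: int = 10000
    n_boot: int = 1000
    seed: int = 17
    estimator: str = "strict"
    directions: Tuple[str, ...] = ("ko_vs_bound", "bound_vs_ko")
    out_dir: Optional[str] = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.sim is None):
            raise ValueError("provide exactly one of input_dir or sim")

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 131 + STAGE_SEED_OFFSETS[stage]) % (2**31)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        if sim is not None:
            sim = SimConfig.from_dict(sim)
        if "directions" in raw:
            raw["directions"] = tuple(raw["directions"])
        return cls(sim=sim, **raw)


@dataclass
class InputBundle:
    """All loaded inputs, plus ground truth when simulated."""

    genes: GeneTable
    interactions: InteractionSet
    regulons: List[TFRegulon]
    cc: AnnotationSet
    bp: AnnotationSet
    expression: ExpressionMatrix
    occupancy: OccupancyTrackSet
    motifs: MotifTable
    ground_truth: Optional[object] = None


def load_inputs(config: RunConfig) -> InputBundle:
    if config.sim is not None:
        ds = simulate(config.sim)
        return InputBundle(
            genes=ds.genes,
            interactions=ds.interactions,
            regulons=ds.regulons,
            cc=ds.cc,
            bp=ds.bp,
            expression=ds.expression,
            occupancy=ds.occupancy,
            motifs=ds.motifs,
            ground_truth=ds.ground_truth,
        )
    d = Path(config.input_dir)
    genes = core_io.read_gene_table(d / "genes.tsv")
    return InputBundle(
        genes=genes,
        interactions=core_io.read_interactions(
            d / "interactions.tsv", d / "segments.tsv", fdr_cutoff=config.interaction_fdr_cutoff
        ),
        regulons=core_io.read_regulons(
            d / "binding.tsv", d / "knockout.tsv", binding_p_cutoff=config.binding_p_cutoff, genes=genes
        ),
        cc=core_io.read_annotations(d / "annotations.tsv", "CC"),
        bp=core_io.read_annotations(d / "annotations.tsv", "BP"),
        expression=core_io.read_expression(d / "expression.tsv"),
        occupancy=core_io.read_occupancy(d / "occupancy.tsv"),
        motifs=core_io.read_motifs(d / "motifs.tsv"),
    )


def _freq_dict(freq) -> Dict[str, object]:
    return {
        "numerator": int(freq.numerator),
        "denominator": int(freq.denominator),
        "frequency": freq.frequency,
    }


def _perm_dict(res: PermutationResult) -> Dict[str, object]:
    return {
        "observed": res.observed,
        "null_mean": float(res.null_sample.mean()),
        "exceed_count": res.exceed_count,
        "n_reps": res.n_reps,
        "p_empirical": res.p_empirical,
        "p_conservative": res.p_conservative,
        "p_label": res.p_label,
    }


def _contrast_dict(c) -> Dict[str, object]:
    return {
        "n_a": int(c.group_a.size),
        "n_b": int(c.group_b.size),
        "median_a": None if c.group_a.size == 0 else c.median_a,
        "median_b": None if c.group_b.size == 0 else c.median_b,
        "ci_a": list(c.ci_a),
        "ci_b": list(c.ci_b),
        "mw_u_p": None if c.degenerate else c.mw_u_p,
        "degenerate": bool(c.degenerate),
    }


@dataclass
class PipelineReport:
    """Summary dictionary plus the heavier per-stage objects."""

    summary: Dict[str, object]
    bundle: InputBundle
    analyzable: List[TFRegulon]
    classifications: List[SARClassification]
    permutations: Dict[str, PermutationResult]
    out_dir: Optional[str] = None

    def summary_json(self) -> str:
        return json.dumps(self.summary, sort_keys=True, indent=1)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute every stage in order and return the structured report."""
    stage = "load"
    try:
        bundle = load_inputs(config)
        genes = bundle.genes

        stage = "filter_regulons"
        fcfg = FilterConfig(proximity_bp=config.proximity_bp, min_set_size=config.min_set_size)
        analyzable, exclusion_counts = filter_regulons(bundle.regulons, genes, fcfg)
        assert_filtered(analyzable, genes, fcfg)

        stage = "filter_interactions"
        interactions = filter_intra_by_separation(bundle.interactions, config.min_intra_sep_bp)

        stage = "colocalize"
        gmap = map_genes_to_segments(genes, interactions, config.tss_window_bp)
        classifications = [classify_sar(reg, gmap, interactions) for reg in analyzable]
        index = ColocalizationIndex(genes, interactions, gmap)
        ko_sets, bound_sets = regulon_index_sets(analyzable, genes)

        frequencies: Dict[str, object] = {}
        for direction in config.directions:
            for mode in ("inter", "intra"):
                freq = pooled_frequency(classifications, direction, mode)
                frequencies[f"{direction}_{mode}"] = _freq_dict(freq)

        sar_pairs = [p for cls in classifications for p in cls.sar_pairs("any")]
        nonsar_pairs = [p for cls in classifications for p in cls.nonsar_pairs("any")]
        partner_ko = partner_count_summary(classifications, "ko_vs_bound", "any")
        partner_bound = partner_count_summary(classifications, "bound_vs_ko", "any")
        if partner_ko.total_pairs != partner_bound.total_pairs:
            raise AssertionError("pair-total symmetry violated between KO and bound sides")

        stage = "permutation"
        permutations: Dict[str, PermutationResult] = {}
        if analyzable:
            for direction in config.directions:
                for mode in ("inter", "intra"):
                    name = f"perm_{mode}_{direction}"
                    permutations[name] = permutation_test(
                        frequency_statistic(index, mode, direction),
                        ko_sets,
                        bound_sets,
                        genes,
                        n_reps=config.n_reps,
                        seed=config.stage_seed(name),
                        randomize="both",
                    )

        stage = "functional"
        functional: Dict[str, object] = {}
        boot_seed = config.stage_seed("bootstrap")
        if sar_pairs:
            cc_freq = cc_cocomponent_frequency(sar_pairs, bundle.regulons, bundle.cc, genes)
            functional["cc_cocomponent"] = _freq_dict(cc_freq)
            cc_index = CoComponentIndex(bundle.regulons, bundle.cc, genes)
            sar_sets = {
                cls.tf_id: list(cls.sar_genes("any")) for cls in classifications if cls.sar_genes("any")
            }
            permutations["perm_cc_cocomponent"] = permutation_test(
                cc_cocomponent_statistic(cc_index),
                sar_sets,
                None,
                genes,
                n_reps=config.n_reps,
                seed=config.stage_seed("perm_cc_cocomponent"),
                randomize="ko_only",
            )
            functional["bp_coprocess_sar"] = _freq_dict(
                bp_coprocess_frequency(sar_pairs, analyzable, bundle.bp, "bp_sar")
            )
            if nonsar_pairs:
                functional["bp_coprocess_nonsar"] = _freq_dict(
                    bp_coprocess_frequency(nonsar_pairs, analyzable, bundle.bp, "bp_nonsar")
                )
            functional["coexpression"] = _contrast_dict(
                coexpression_contrast(
                    sar_pairs, nonsar_pairs, analyzable, bundle.expression, n_boot=config.n_boot, seed=boot_seed
                )
            )
            functional["pairwise_bound_coexpression"] = _contrast_dict(
                pairwise_bound_coexpression(
                    analyzable, classifications, bundle.expression, n_boot=config.n_boot, seed=boot_seed + 2
                )
            )
            sar_genes = sorted({g for _, g in sar_pairs})
            other_genes = sorted(set(genes.ids) - set(sar_genes))
            functional["expression_variability"] = _contrast_dict(
                expression_variability_contrast(
                    sar_genes, other_genes, bundle.expression, n_boot=config.n_boot, seed=boot_seed + 4
                )
            )

        stage = "chromatin"
        chromatin: Dict[str, object] = {}
        if sar_pairs:
            chromatin["motif_sar"] = _freq_dict(motif_presence_frequency(sar_pairs, bundle.motifs, "motif_sar"))
            if nonsar_pairs:
                chromatin["motif_nonsar"] = _freq_dict(
                    motif_presence_frequency(nonsar_pairs, bundle.motifs, "motif_nonsar")
                )
            sar_genes = {g for _, g in sar_pairs}
            bound_all = {g for reg in analyzable for g in reg.bound}
            # occupancy contrast excludes genes that are both bound and SAR
            occ_a = sorted(sar_genes - bound_all)
            occ_b = sorted(bound_all - sar_genes)
            if occ_a and occ_b:
                chromatin["occupancy_sar_vs_bound"] = _contrast_dict(
                    occupancy_contrast(occ_a, occ_b, bundle.occupancy, n_boot=config.n_boot, seed=boot_seed + 6)
                )
            other = sorted(set(genes.ids) - sar_genes)
            if other:
                chromatin["occupancy_sar_vs_other"] = _contrast_dict(
                    occupancy_contrast(sorted(sar_genes), other, bundle.occupancy, n_boot=config.n_boot, seed=boot_seed + 8)
                )
                chromatin["tf_count"] = _contrast_dict(
                    tf_count_contrast(sorted(sar_genes), other, bundle.regulons, n_boot=config.n_boot, seed=boot_seed + 10)
                )
            chromatin["affinity"] = _contrast_dict(
                affinity_contrast(analyzable, classifications, n_boot=config.n_boot, seed=boot_seed + 12)
            )

        stage = "summarize"
        summary: Dict[str, object] = {
            "schema_version": SUMMARY_SCHEMA_VERSION,
            "seed": int(config.seed),
            "parameters": {
                "binding_p_cutoff": config.binding_p_cutoff,
                "interaction_fdr_cutoff": config.interaction_fdr_cutoff,
                "proximity_bp": config.proximity_bp,
                "min_set_size": config.min_set_size,
                "tss_window_bp": config.tss_window_bp,
                "min_intra_sep_bp": config.min_intra_sep_bp,
                "n_reps": config.n_reps,
                "n_boot": config.n_boot,
            },
            "counts": {
                "n_genes": len(genes),
                "n_tfs_input": len(bundle.regulons),
                "n_tfs_analyzable": len(analyzable),
                "n_interactions": int(interactions.n_pairs),
                "n_interactions_prefilter": int(bundle.interactions.n_pairs),
                "n_sar_pairs": len(sar_pairs),
                "n_nonsar_pairs": len(nonsar_pairs),
                "total_colocalized_gene_pairs": partner_ko.total_pairs,
                "exclusions": exclusion_counts,
            },
            "frequencies": frequencies,
            "permutation": {name: _perm_dict(res) for name, res in sorted(permutations.items())},
            "functional": functional,
            "chromatin": chromatin,
        }
        _validate_summary(summary)
        report = PipelineReport(
            summary=summary,
            bundle=bundle,
            analyzable=analyzable,
            classifications=classifications,
            permutations=permutations,
            out_dir=config.out_dir,
        )
        if config.out_dir is not None:
            stage = "write_outputs"
            _write_outputs(report, config)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _validate_summary(summary: Mapping[str, object]) -> None:
    """Minimal schema check on emit."""
    for key in ("schema_version", "seed", "parameters", "counts", "frequencies", "permutation"):
        if key not in summary:
            raise AssertionError(f"summary missing required key {key!r}")
    if summary["schema_version"] != SUMMARY_SCHEMA_VERSION:
        raise AssertionError("unexpected summary schema version")
    json.dumps(summary)  # must be serializable


def _write_outputs(report: PipelineReport, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(report.summary_json() + "\n")

    per_tf = []
    for cls in report.classifications:
        for mode in ("inter", "intra"):
            n = sum(1 for g in cls.ko_genes if cls.is_sar(g, mode))
            per_tf.append((cls.tf_id, mode, n, len(cls.ko_genes), n / len(cls.ko_genes) if cls.ko_genes else 0.0))
    pd.DataFrame(per_tf, columns=["tf", "mode", "n_sar", "n_ko", "frequency"]).to_csv(
        out / "per_tf_frequencies.tsv", sep="\t", index=False
    )
    rows = []
    for cls in report.classifications:
        for g in cls.ko_genes:
            rows.append(
                (
                    cls.tf_id,
                    g,
                    cls.is_sar(g, "inter"),
                    cls.is_sar(g, "intra"),
                    ",".join(cls.partners(g, "inter")),
                    ",".join(cls.partners(g, "intra")),
                )
            )
    pd.DataFrame(
        rows, columns=["tf", "ko_gene", "sar_inter", "sar_intra", "partners_inter", "partners_intra"]
    ).to_csv(out / "sar_pairs.tsv", sep="\t", index=False)
    for direction in ("ko_vs_bound", "bound_vs_ko"):
        summ = partner_count_summary(report.classifications, direction, "any")
        pd.DataFrame(
            [(tf, g, n) for (tf, g), n in sorted(summ.counts.items())], columns=["tf", "gene", "n_partners"]
        ).to_csv(out / f"partner_counts_{direction}.tsv", sep="\t", index=False)
    if config.make_plots:
        _write_plots(report, out)


def _write_plots(report: PipelineReport, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    names, samples = [], []
    for name, res in sorted(report.permutations.items()):
        names.append(name.replace("perm_", ""))
        samples.append(res.null_sample)
    if samples:
        ax.boxplot(samples, tick_labels=names)
        for i, (_, res) in enumerate(sorted(report.permutations.items()), start=1):
            ax.plot(i, res.observed, "ro")
        ax.set_ylabel("pooled frequency")
        plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
        fig.tight_layout()
        fig.savefig(out / "permutation_null_distributions.png", dpi=120)
    plt.close(fig)
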