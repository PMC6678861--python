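"""Readers/writers: round trips, cutoff filtering, invariant enforcement."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from sarloc import core_io
from sarloc.core_io import (
    ConsistencyError,
    DuplicateIdError,
    GeneTable,
    InteractionSet,
    TableFormatError,
    orient_promoter_window,
)

from conftest import make_genes, make_interactions


@pytest.fixture(scope="module")
def dataset():
    from sarloc.simulate import SimConfig, simulate

    return simulate(SimConfig(n_chromosomes=4, genes_per_chromosome=12, n_tfs=3,
                              bound_size=8, ko_size=8, n_conditions=12, seed=3,
                              planted_enrichment=2.0))


def test_round_trip_all_table_kinds(dataset, tmp_path):
    """Writer -> reader is the identity on every table kind."""
    manifest = dataset.write(tmp_path)

    genes2 = core_io.read_gene_table(manifest["genes"])
    assert_frame_equal(genes2.frame, dataset.genes.frame)

    inter2 = core_io.read_interactions(manifest["interactions"], manifest["segments"])
    assert_frame_equal(inter2.segments, dataset.interactions.segments)
    assert_frame_equal(inter2.pairs, dataset.interactions.pairs)

    regs2 = core_io.read_regulons(manifest["binding"], manifest["knockout"])
    by_tf = {r.tf_id: r for r in regs2}
    for reg in dataset.regulons:
        other = by_tf[reg.tf_id]
        assert other.ko_affected == reg.ko_affected
        assert set(other.bound) == set(reg.bound)
        for g, s in reg.bound.items():
            assert other.bound[g] == pytest.approx(s, rel=1e-12)

    for category, original in (("CC", dataset.cc), ("BP", dataset.bp)):
        ann2 = core_io.read_annotations(manifest["annotations"], category)
        assert ann2.terms == original.terms

    expr2 = core_io.read_expression(manifest["expression"])
    assert_frame_equal(expr2.frame, dataset.expression.frame, check_names=False)

    occ2 = core_io.read_occupancy(manifest["occupancy"])
    assert np.array_equal(occ2.frame.to_numpy(), dataset.occupancy.frame.to_numpy())
    assert list(occ2.frame.index) == list(dataset.occupancy.frame.index)

    motifs2 = core_io.read_motifs(manifest["motifs"])
    assert motifs2.pairs == dataset.motifs.pairs


def test_gene_table_toy_and_errors(tmp_path):
    path = tmp_path / "genes.tsv"
    path.write_text("gene_id\tchrom\tstrand\ttss\ng1\tchr1\t+\t100\ng2\tchr1\t-\t200\ng3\tchr2\t+\t1\n")
    gt = core_io.read_gene_table(path)
    assert len(gt) == 3
    assert gt.chrom_of("g3") == "chr2"

    path.write_text("gene_id\tchrom\tstrand\ttss\ng1\tchr1\t+\t100\ng1\tchr1\t+\t200\n")
    with pytest.raises(DuplicateIdError):
        core_io.read_gene_table(path)

    path.write_text("gene_id\tchrom\tstrand\ttss\n")
    assert len(core_io.read_gene_table(path)) == 0

    with pytest.raises(TableFormatError):
        make_genes([("g1", "chr1", "+", 0)])  # 1-based coordinates
    with pytest.raises(TableFormatError):
        make_genes([("g1", "chr1", "?", 10)])


def test_read_interactions_fdr_filter(tmp_path):
    seg = tmp_path / "segments.tsv"
    seg.write_text(
        "segment_id\tchrom\tstart\tend\ns1\tchr1\t1\t1000\ns2\tchr1\t5001\t6000\ns3\tchr2\t1\t1000\n"
    )
    pr = tmp_path / "pairs.tsv"
    pr.write_text(
        "seg_a\tseg_b\tfdr\n"
        "s1\ts2\t1e-5\ns1\ts3\t5e-5\ns2\ts3\t1e-4\ns1\ts3\t0.01\ns2\ts3\t0.01\n"
    )
    inter = core_io.read_interactions(pr, seg, fdr_cutoff=1e-4)
    assert inter.n_pairs == 3  # two rows above the cutoff dropped
    assert set(inter.pairs["kind"]) == {"inter", "intra"}


def test_interaction_kind_consistency_and_unknown_segment():
    seg = pd.DataFrame(
        [("s1", "chr1", 1, 1000), ("s2", "chr2", 1, 1000)],
        columns=["segment_id", "chrom", "start", "end"],
    )
    bad_kind = pd.DataFrame([("s1", "s2", "intra", 1e-5)], columns=["seg_a", "seg_b", "kind", "fdr"])
    with pytest.raises(ConsistencyError):
        InteractionSet(segments=seg, pairs=bad_kind)
    unknown = pd.DataFrame([("s1", "sX", "inter", 1e-5)], columns=["seg_a", "seg_b", "kind", "fdr"])
    with pytest.raises(ConsistencyError):
        InteractionSet(segments=seg, pairs=unknown)
    self_pair = pd.DataFrame([("s1", "s1", "intra", 1e-5)], columns=["seg_a", "seg_b", "kind", "fdr"])
    with pytest.raises(ConsistencyError):
        InteractionSet(segments=seg, pairs=self_pair)


def test_loaded_interactions_satisfy_cutoff_and_consistency(dataset):
    inter = dataset.interactions
    assert (inter.pairs["fdr"] <= inter.fdr_cutoff).all()
    chrom_of = dict(zip(inter.segments["segment_id"], inter.segments["chrom"]))
    expected = np.where(
        inter.pairs["seg_a"].map(chrom_of) == inter.pairs["seg_b"].map(chrom_of), "intra", "inter"
    )
    assert (inter.pairs["kind"].to_numpy() == expected).all()


def test_read_regulons_boundary_and_flags(tmp_path):
    binding = tmp_path / "binding.tsv"
    binding.write_text(
        "tf\tgene\tbinding_p\ntfA\tg1\t0.001\ntfA\tg2\t0.005\ntfA\tg3\t0.01\n"
    )
    ko = tmp_path / "ko.tsv"
    ko.write_text("tf\tgene\ntfA\tg9\ntfB\tg1\n")
    regs = {r.tf_id: r for r in core_io.read_regulons(binding, ko, binding_p_cutoff=0.005)}
    # cutoff is inclusive: p = 0.005 is bound, p = 0.01 is not
    assert set(regs["tfA"].bound) == {"g1", "g2"}
    assert regs["tfA"].bound["g1"] == pytest.approx(3.0)  # -log10(0.001)
    # TF only in the knockout file: empty bound set, flagged
    assert regs["tfB"].bound == {} and not regs["tfB"].in_binding_data


def test_read_regulons_drops_unknown_genes(tmp_path, caplog):
    genes = make_genes([("g1", "chr1", "+", 100)])
    binding = tmp_path / "b.tsv"
    binding.write_text("tf\tgene\tbinding_p\ntfA\tg1\t0.001\ntfA\tgX\t0.001\n")
    ko = tmp_path / "k.tsv"
    ko.write_text("tf\tgene\ntfA\tg1\n")
    with caplog.at_level("WARNING", logger="sarloc"):
        regs = core_io.read_regulons(binding, ko, genes=genes)
    assert set(regs[0].bound) == {"g1"}
    assert any("unknown gene" in r.message for r in caplog.records)


def test_expression_reader_drops_sparse_rows(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene_id\tc1\tc2\tc3\tc4\n"
        "g1\t1.0\t2.0\t3.0\t4.0\n"
        "g2\t1.0\t\t\t\n"
    )
    expr = core_io.read_expression(path, min_observations=3)
    assert "g1" in expr and "g2" not in expr


def test_occupancy_width_and_orientation():
    with pytest.raises(TableFormatError):
        core_io.OccupancyTrackSet(frame=pd.DataFrame(np.ones((2, 10))))
    window = np.arange(500, dtype=float)
    assert np.array_equal(orient_promoter_window(window, "+"), window)
    assert np.array_equal(orient_promoter_window(window, "-"), window[::-1])
    with pytest.raises(ValueError):
        orient_promoter_window(window, "x")
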