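import numpy as np
import pandas as pd
import pytest

from dmrkit.errors import ValidationError
from dmrkit.scrna import (
    DegRecord,
    DegThresholds,
    ExpressionMatrix,
    QcParams,
    cluster_composition_test,
    cluster_deg_test,
    cross_species_deg_concordance,
    expressing_fraction_test,
    knn_lineage_annotate,
    link_degs_to_dmrs,
    normalize_cells,
    qc_filter_cells,
    recurrent_degs,
)
from dmrkit.simulate import SimulationConfig, simulate_scrna


def make_matrix(counts, clusters=None, groups=None, samples=None, mito_first_n=1):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = [f"MT-{i + 1}" for i in range(mito_first_n)] + [
        f"G{i + 1}" for i in range(n_genes - mito_first_n)
    ]
    meta = pd.DataFrame(
        {
            "sample": samples or ["s1"] * n_cells,
            "group": groups or ["a"] * n_cells,
            "cluster": clusters or ["c1"] * n_cells,
        }
    )
    mito = np.array([g.startswith("MT-") for g in genes])
    return ExpressionMatrix(
        counts=counts,
        genes=genes,
        barcodes=[f"b{i}" for i in range(n_cells)],
        cell_meta=meta,
        mito=mito,
    )


# ---------------------------------------------------------------------------
# QC


def cell_with(n_genes_expressed, total_reads, mito_reads, n_genes=400):
    row = np.zeros(n_genes)
    non_mito = max(0, n_genes_expressed - (1 if mito_reads else 0))
    body = total_reads - mito_reads
    if non_mito:
        per = body // non_mito
        row[1 : 1 + non_mito] = per
        row[1] += body - per * non_mito
    row[0] = mito_reads
    return row


def test_qc_removes_low_gene_cell():
    # 200 expressed genes, 5000 reads, 1% mito -> removed by the gene rule
    m = make_matrix([cell_with(200, 5000, 50)])
    kept, report = qc_filter_cells(m)
    assert kept.n_cells == 0 and report["failed_min_genes"] == 1


def test_qc_removes_low_read_cell():
    m = make_matrix([cell_with(300, 499, 0)])
    kept, report = qc_filter_cells(m)
    assert kept.n_cells == 0 and report["failed_min_reads"] == 1


def test_qc_boundary_cell_kept():
    # exactly 250 genes, 500 reads, 10% mito survives strict inequalities
    m = make_matrix([cell_with(250, 500, 50)])
    row = m.counts[0]
    assert (row > 0).sum() == 250 and row.sum() == 500 and row[0] / row.sum() == 0.10
    kept, _ = qc_filter_cells(m)
    assert kept.n_cells == 1


def test_qc_removes_high_mito():
    m = make_matrix([cell_with(300, 1000, 101)])
    kept, report = qc_filter_cells(m)
    assert kept.n_cells == 0 and report["failed_max_mito"] == 1


def test_qc_requires_mito_flags():
    m = make_matrix([cell_with(300, 1000, 0)])
    m.mito[:] = False
    with pytest.raises(ValidationError):
        qc_filter_cells(m)


def test_qc_monotone_in_thresholds():
    rng = np.random.default_rng(0)
    counts = rng.poisson(2.0, size=(100, 400))
    m = make_matrix(counts)
    _, strict = qc_filter_cells(m, QcParams(min_genes=250, min_reads=600, max_mito_fraction=0.05))
    _, loose = qc_filter_cells(m, QcParams(min_genes=200, min_reads=500, max_mito_fraction=0.10))
    assert loose["n_removed"] <= strict["n_removed"]


# ---------------------------------------------------------------------------
# normalization


def test_normalize_scales_to_target():
    m = make_matrix([[1, 2, 7] + [0] * 397])
    scaled = normalize_cells(m, 10_000.0, log_transform=False)
    assert scaled[0, :3] == pytest.approx([1000, 2000, 7000])
    assert scaled.sum() == pytest.approx(10_000.0)


def test_normalize_scale_invariance():
    base = np.array([[3, 5, 12] + [1] * 397])
    m1 = make_matrix(base)
    m2 = make_matrix(base * 2)
    assert np.allclose(normalize_cells(m1), normalize_cells(m2))


def test_normalize_zero_gene_stays_zero():
    m = make_matrix([[5, 0, 5] + [0] * 397])
    assert normalize_cells(m)[0, 1] == 0.0


def test_normalize_zero_cell_errors():
    m = make_matrix([[0] * 400])
    with pytest.raises(ValidationError):
        normalize_cells(m)


# ---------------------------------------------------------------------------
# composition


def test_composition_identical():
    clusters = ["c1"] * 30 + ["c2"] * 20 + ["c1"] * 30 + ["c2"] * 20
    samples = ["s1"] * 50 + ["s2"] * 50
    m = make_matrix(np.ones((100, 400)), clusters=clusters, samples=samples)
    out = cluster_composition_test(m)
    assert out["statistic"] == pytest.approx(0.0, abs=1e-9)
    assert out["p"] == pytest.approx(1.0)


def test_composition_shifted():
    clusters = ["c1"] * 50 + ["c2"] * 10 + ["c1"] * 10 + ["c2"] * 50
    samples = ["s1"] * 60 + ["s2"] * 60
    m = make_matrix(np.ones((120, 400)), clusters=clusters, samples=samples)
    out = cluster_composition_test(m)
    assert out["statistic"] == pytest.approx(53.33, abs=0.01)
    assert out["p"] < 1e-12


def test_composition_shift_at_paper_scale():
    # one cluster moves from 14% to 5% of 3000 cells/sample
    rng = np.random.default_rng(12)
    fr = [0.14] + [0.86 / 5] * 5
    ft = [0.05] + [0.95 / 5] * 5
    cfg = SimulationConfig(
        seed=12, n_clusters=6, cells_per_cluster=500, n_genes=60,
        n_markers_per_cluster=3, n_planted_degs_per_cluster=0,
        cluster_fractions_ref=fr, cluster_fractions_test=ft,
        qc_violation_fraction=0.0,
    )
    bundle = simulate_scrna(cfg, rng)
    out = cluster_composition_test(bundle.matrix)
    assert out["p"] < 0.0001


# ---------------------------------------------------------------------------
# DEG calling


def deg_cohort(fold=4.0, n_cells=200, seed=0, n_genes=80):
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(3), 0.6, n_genes)
    disp = 2.0
    counts = []
    groups = []
    for g, f in (("ref", 1.0), ("test", fold)):
        m = mu.copy()
        m[5] *= f  # planted gene index 5
        p = disp / (disp + m)
        counts.append(rng.negative_binomial(disp, p, size=(n_cells, n_genes)))
        groups += [g] * n_cells
    counts = np.vstack(counts)
    return make_matrix(counts, groups=groups, mito_first_n=1), "G5"  # gene index 5 name


def test_deg_identical_distributions_not_emitted():
    m, _ = deg_cohort(fold=1.0, seed=1)
    recs = cluster_deg_test(m, "test", "ref")
    assert all(r.gene != "G5" for r in recs)


def test_deg_planted_fold_recovered():
    hits = 0
    for seed in range(20):
        m, gene = deg_cohort(fold=4.0, n_cells=200, seed=seed)
        recs = cluster_deg_test(m, "test", "ref")
        match = [r for r in recs if r.gene == gene]
        if match and 1.5 <= match[0].log2_ratio <= 2.5:
            hits += 1
    assert hits >= 18


def test_deg_dual_gate_conjunctive():
    m, _ = deg_cohort(fold=1.6, n_cells=400, seed=3)  # significant p, weak fold
    recs = cluster_deg_test(m, "test", "ref")
    for r in recs:
        assert r.p <= 0.05 and abs(r.log2_ratio) >= 1.0


def test_deg_small_cluster_skipped():
    m, _ = deg_cohort(n_cells=5, seed=2)
    assert cluster_deg_test(m, "test", "ref") == []


def test_deg_missing_group_errors():
    m, _ = deg_cohort(seed=2)
    with pytest.raises(ValidationError):
        cluster_deg_test(m, "nosuch", "ref")


# ---------------------------------------------------------------------------
# recurrent DEGs


def rec(cluster, gene, direction):
    return DegRecord(
        cluster=cluster, gene=gene, log2_ratio=1.5 if direction == "up" else -1.5,
        p=0.01, direction=direction, frac_expressing_test=0.5,
        frac_expressing_ref=0.1, expressing_fisher_p=0.001,
    )


def test_recurrent_concordant():
    records = [rec(f"c{i}", "RASIP1", "up") for i in range(7)]
    records += [rec("c8", "OTHER", "down")]
    out = recurrent_degs(records)
    assert list(out["gene"]) == ["RASIP1"]
    assert out.iloc[0]["n_clusters"] == 7 and out.iloc[0]["concordant"]


def test_recurrent_discordant():
    out = recurrent_degs([rec("c1", "X", "up"), rec("c2", "X", "down")])
    assert len(out) == 1 and not out.iloc[0]["concordant"]


def test_recurrent_empty():
    assert recurrent_degs([rec("c1", "A", "up"), rec("c2", "B", "up")]).empty


# ---------------------------------------------------------------------------
# expressing fractions


def test_expressing_fraction_paper_like():
    counts = np.zeros((200, 400))
    counts[:, 1] = 1  # keep cells non-degenerate
    counts[0, 5] = 3  # 1/100 control cells express
    counts[100:115, 5] = 2  # 15/100 case cells express
    groups = ["ctrl"] * 100 + ["case"] * 100
    m = make_matrix(counts, groups=groups)
    out = expressing_fraction_test(m, "G5", ("ctrl", "case"))
    assert out["fractions"]["ctrl"] == pytest.approx(0.01)
    assert out["fractions"]["case"] == pytest.approx(0.15)
    assert out["p"] < 0.001


def test_expressing_fraction_equal_p_one():
    counts = np.ones((40, 400))
    m = make_matrix(counts, groups=["a"] * 20 + ["b"] * 20)
    assert expressing_fraction_test(m, "G5", ("a", "b"))["p"] == 1.0


def test_expressing_fraction_zero_both_p_one():
    counts = np.ones((40, 400))
    counts[:, 5] = 0
    m = make_matrix(counts, groups=["a"] * 20 + ["b"] * 20)
    assert expressing_fraction_test(m, "G5", ("a", "b"))["p"] == 1.0


# ---------------------------------------------------------------------------
# DEG <-> DMR linking


class FakeDmr:
    def __init__(self, chrom, start, end):
        self.chrom, self.start, self.end = chrom, start, end


def test_link_within_k():
    out = link_degs_to_dmrs(
        [rec("c1", "G1", "up")],
        {"G1": ("chr1", 1000, 5000)},
        [FakeDmr("chr1", 5500, 6000)],
    )
    assert out.iloc[0]["distance"] == 500 and out.iloc[0]["linked"]


def test_link_beyond_k():
    out = link_degs_to_dmrs(
        [rec("c1", "G1", "up")],
        {"G1": ("chr1", 1000, 5000)},
        [FakeDmr("chr1", 25_000, 26_000)],
    )
    assert not out.iloc[0]["linked"]


def test_link_missing_interval_flagged():
    out = link_degs_to_dmrs([rec("c1", "G1", "up")], {}, [FakeDmr("chr1", 0, 10)])
    assert out.iloc[0]["no_interval"] and not out.iloc[0]["linked"]


def test_link_matches_bruteforce():
    rng = np.random.default_rng(30)
    dmrs = [FakeDmr("chr1", s, s + 200) for s in rng.integers(0, 100_000, 30)]
    intervals = {
        f"G{i}": ("chr1", int(s), int(s) + 1500)
        for i, s in enumerate(rng.integers(0, 100_000, 30))
    }
    records = [rec("c1", g, "up") for g in intervals]
    out = link_degs_to_dmrs(records, intervals, dmrs).set_index("gene")
    for g, (c, s, e) in intervals.items():
        brute = min(
            0 if min(e, d.end) - max(s, d.start) > 0
            else (d.start - e if d.start >= e else s - d.end)
            for d in dmrs
        )
        assert out.loc[g, "distance"] == brute


# ---------------------------------------------------------------------------
# lineage annotation


def test_knn_identity_profile():
    rng = np.random.default_rng(4)
    ref = pd.DataFrame(
        rng.random((3, 100)), index=["linA", "linB", "linC"],
        columns=[f"G{i + 1}" for i in range(100)],
    )
    counts = np.zeros((1, 100))
    counts[0] = np.round(ref.loc["linB"].to_numpy() * 50)
    m = make_matrix(counts, mito_first_n=0)
    m.genes[:] = list(ref.columns)
    labels = knn_lineage_annotate(m, ref)
    assert labels.iloc[0] == "linB"


def test_knn_all_zero_cell_unassigned():
    ref = pd.DataFrame(
        np.random.default_rng(1).random((2, 100)), index=["a", "b"],
        columns=[f"G{i + 1}" for i in range(100)],
    )
    counts = np.zeros((1, 100))
    m = make_matrix(counts, mito_first_n=0)
    m.genes[:] = list(ref.columns)
    assert knn_lineage_annotate(m, ref).iloc[0] == "unassigned"


def test_knn_too_few_shared_genes():
    ref = pd.DataFrame(np.ones((2, 10)), index=["a", "b"], columns=[f"X{i}" for i in range(10)])
    m = make_matrix(np.ones((1, 400)))
    with pytest.raises(ValidationError):
        knn_lineage_annotate(m, ref)


def test_knn_recovers_simulated_clusters():
    cfg = SimulationConfig(seed=6, n_clusters=4, cells_per_cluster=50, n_genes=200,
                           qc_violation_fraction=0.0)
    bundle = simulate_scrna(cfg)
    labels = knn_lineage_annotate(bundle.matrix, bundle.reference)
    expected = "lin_" + bundle.matrix.cell_meta["cluster"]
    agreement = (labels.to_numpy() == expected.to_numpy()).mean()
    assert agreement >= 0.99


# ---------------------------------------------------------------------------
# cross-species concordance


def test_concordance_case_insensitive():
    human = [rec("c1", "RASIP1", "up")]
    mouse = [rec("c3", "Rasip1", "up")]
    out = cross_species_deg_concordance(human, mouse)
    assert out.iloc[0]["concordant"]
    assert out.attrs["percent_concordant"] == 100.0


def test_concordance_disjoint_sets():
    out = cross_species_deg_concordance(
        [rec("c1", "A", "up")], [rec("c1", "B", "up")]
    )
    assert out.attrs["n_concordant"] == 0


def test_concordance_direction_mismatch():
    out = cross_species_deg_concordance(
        [rec("c1", "A", "up")], [rec("c1", "a", "down")]
    )
    assert out.iloc[0]["in_both"] and not out.iloc[0]["concordant"]
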