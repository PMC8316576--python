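import math

import numpy as np
import pytest

from conftest import build_matrix, build_metadata
from dmrkit.caller import (
    DmrParams,
    DmrRecord,
    call_dmrs,
    canonicality_filter,
    covariate_regression,
    dmr_summary,
    merge_adjacent,
    replicate_correlation,
    score_and_filter,
    segment_candidates,
)
from dmrkit.core import IntervalIndex
from dmrkit.errors import ValidationError
from dmrkit.simulate import GroupSpec, SimulationConfig, simulate_cohort


def cohort_matrix(positions, test_level, ref_level, n_test=3, n_ref=3, sd=0.01, seed=0):
    rng = np.random.default_rng(seed)
    n = len(positions)
    test = np.clip(rng.normal(test_level, sd, (n, n_test)), 0, 1)
    ref = np.clip(rng.normal(ref_level, sd, (n, n_ref)), 0, 1)
    samples = [f"t{i}" for i in range(n_test)] + [f"r{i}" for i in range(n_ref)]
    matrix = build_matrix(positions, np.hstack([test, ref]), samples=samples)
    meta = build_metadata(samples, ["case"] * n_test + ["control"] * n_ref)
    return matrix, meta


# ---------------------------------------------------------------------------
# segmentation


def test_segment_single_run_of_12():
    positions = 1000 + 50 * np.arange(12)
    matrix, meta = cohort_matrix(positions, 0.5, 0.8)
    cands = segment_candidates(matrix, meta, "case", "control")
    assert len(cands) == 1
    c = cands[0]
    assert c.start == 1000 and c.end == positions[-1] + 1
    assert len(c.site_idx) == 12


def test_segment_nine_cpgs_below_minimum():
    positions = 1000 + 50 * np.arange(9)
    matrix, meta = cohort_matrix(positions, 0.5, 0.8)
    assert segment_candidates(matrix, meta, "case", "control") == []


def test_segment_large_gap_splits_run():
    # 500 bp gap after the 6th CpG -> two 6-CpG runs, both below min_cpgs
    positions = np.concatenate([1000 + 50 * np.arange(6), 1800 + 50 * np.arange(6)])
    matrix, meta = cohort_matrix(positions, 0.5, 0.8)
    assert segment_candidates(matrix, meta, "case", "control") == []


def test_segment_sign_flip_breaks_run():
    positions = 1000 + 50 * np.arange(20)
    rng = np.random.default_rng(1)
    test = np.clip(rng.normal(0.5, 0.005, (20, 3)), 0, 1)
    test[8] = 0.995  # hyper at one CpG inside a hypo run
    ref = np.clip(rng.normal(0.8, 0.005, (20, 3)), 0, 1)
    samples = ["t0", "t1", "t2", "r0", "r1", "r2"]
    matrix = build_matrix(positions, np.hstack([test, ref]), samples=samples)
    meta = build_metadata(samples, ["case"] * 3 + ["control"] * 3)
    cands = segment_candidates(matrix, meta, "case", "control")
    assert len(cands) == 1 and len(cands[0].site_idx) == 11  # CpGs 9..19


def test_segment_insufficient_coverage_breaks_run():
    positions = 1000 + 50 * np.arange(12)
    matrix, meta = cohort_matrix(positions, 0.5, 0.8)
    matrix.coverage[5, :3] = 0
    matrix.ratio[5, :3] = np.nan
    assert segment_candidates(matrix, meta, "case", "control") == []


def test_segment_absent_group_errors():
    positions = 1000 + 50 * np.arange(12)
    matrix, meta = cohort_matrix(positions, 0.5, 0.8)
    with pytest.raises(ValidationError):
        segment_candidates(matrix, meta, "nosuch", "control")


# ---------------------------------------------------------------------------
# scoring + filtering


def test_score_keeps_separated_groups():
    # p = 0.1 is the floor for an exact 3v3 test, so relax the FDR gate to
    # observe the record itself
    positions = 1000 + 50 * np.arange(12)
    matrix, meta = cohort_matrix(positions, 0.3, 0.8)
    params = DmrParams(max_fdr=0.1)
    cands = segment_candidates(matrix, meta, "case", "control", params)
    recs = score_and_filter(cands, matrix, meta, "case", "control", params)
    assert len(recs) == 1
    r = recs[0]
    assert r.p == pytest.approx(0.1)  # exact MWU, complete separation 3v3
    assert r.q == pytest.approx(0.1)
    assert r.direction == "hypo"
    assert r.mean_diff == pytest.approx(-0.5, abs=0.02)


def test_score_rejects_identical_groups():
    positions = 1000 + 50 * np.arange(12)
    vals = np.full((12, 6), 0.5)
    samples = ["t0", "t1", "t2", "r0", "r1", "r2"]
    matrix = build_matrix(positions, vals, samples=samples)
    meta = build_metadata(samples, ["case"] * 3 + ["control"] * 3)
    cands = segment_candidates(matrix, meta, "case", "control")
    assert cands == []  # zero difference never seeds a run
    assert score_and_filter(cands, matrix, meta, "case", "control") == []


def test_score_fdr_gate():
    # p = 0.1 from a 3v3 exact test never beats max_fdr = 0.05
    positions = 1000 + 50 * np.arange(12)
    matrix, meta = cohort_matrix(positions, 0.3, 0.8)
    params = DmrParams(max_fdr=0.05)
    cands = segment_candidates(matrix, meta, "case", "control", params)
    assert score_and_filter(cands, matrix, meta, "case", "control", params) == []


# ---------------------------------------------------------------------------
# merging


def make_record(start, end, chrom="chr1", p=0.01, n_cpgs=10, **kw):
    defaults = dict(
        id="x", chrom=chrom, start=start, end=end, n_cpgs=n_cpgs,
        sample_means={"a": 0.3, "b": 0.8}, mean_test=0.3, mean_ref=0.8,
        mean_diff=-0.5, sd_test=0.01, sd_ref=0.01, p=p, q=p,
    )
    defaults.update(kw)
    return DmrRecord(**defaults)


def test_merge_gap_below_threshold():
    out = merge_adjacent([make_record(100, 200), make_record(240, 300)])
    assert len(out) == 1
    assert (out[0].start, out[0].end) == (100, 300)


def test_merge_gap_at_threshold_not_merged():
    out = merge_adjacent([make_record(100, 200), make_record(260, 300)])
    assert len(out) == 2


def test_merge_exact_boundary_gap_50():
    # gap of exactly 50 is NOT < 50
    out = merge_adjacent([make_record(100, 200), make_record(250, 300)])
    assert len(out) == 2


def test_merge_transitive():
    out = merge_adjacent(
        [make_record(100, 200), make_record(240, 300), make_record(340, 400)]
    )
    assert len(out) == 1
    assert (out[0].start, out[0].end) == (100, 400)
    assert out[0].n_cpgs == 30  # CpG count conserved


def test_merge_idempotent():
    once = merge_adjacent([make_record(100, 200), make_record(240, 300)])
    twice = merge_adjacent(once)
    assert [(r.start, r.end) for r in twice] == [(r.start, r.end) for r in once]


def test_merge_recomputes_from_matrix():
    # 25 CpGs 20 bp apart; the middle CpG loses test-group coverage, which
    # splits the run into two 12-CpG records 39 bp apart -> merged (<50)
    positions = 1000 + 20 * np.arange(25)
    matrix, meta = cohort_matrix(positions, 0.3, 0.8, n_test=4, n_ref=4)
    matrix.coverage[12, :4] = 0
    matrix.ratio[12, :4] = np.nan
    params = DmrParams()
    cands = segment_candidates(matrix, meta, "case", "control", params)
    assert [len(c.site_idx) for c in cands] == [12, 12]
    recs = score_and_filter(cands, matrix, meta, "case", "control", params)
    assert len(recs) == 2
    merged = merge_adjacent(recs, params, matrix, meta, "case", "control")
    assert len(merged) == 1
    assert merged[0].n_cpgs == 24  # union of member CpGs, not the span
    assert (merged[0].start, merged[0].end) == (1000, 1000 + 20 * 24 + 1)


def test_merge_different_chromosomes_never():
    out = merge_adjacent(
        [make_record(100, 200, chrom="chr1"), make_record(210, 300, chrom="chr2")]
    )
    assert len(out) == 2


# ---------------------------------------------------------------------------
# canonicality


def test_canonicality_keeps_tight_groups():
    r = make_record(100, 200, sd_test=0.010, sd_ref=0.008)
    assert canonicality_filter([r]) == [r]


def test_canonicality_removes_dispersed_test_group():
    r = make_record(100, 200, sd_test=0.30, sd_ref=0.01)
    assert canonicality_filter([r]) == []


def test_canonicality_boundary_inclusive():
    r = make_record(100, 200, sd_test=0.1, sd_ref=0.1)
    assert canonicality_filter([r]) == [r]


def test_canonicality_undefined_sd_kept_flagged():
    r = make_record(100, 200, sd_test=float("nan"), sd_ref=0.01)
    out = canonicality_filter([r])
    assert out == [r] and out[0].sd_undefined


def test_canonicality_test_group_only_switch():
    r = make_record(100, 200, sd_test=0.05, sd_ref=0.5)
    params = DmrParams(sd_filter_both_groups=False)
    assert canonicality_filter([r], params=params) == [r]
    assert canonicality_filter([r]) == []


# ---------------------------------------------------------------------------
# full cascade on simulations


@pytest.fixture(scope="module")
def severe_cohort():
    cfg = SimulationConfig(seed=11, n_chroms=2, chrom_length=1_000_000, n_regions=30)
    return simulate_cohort(cfg)


def test_call_dmrs_recovers_planted(severe_cohort):
    genome, matrix, meta = severe_cohort
    recs = call_dmrs(matrix, meta, "mutant", "control")
    idx = IntervalIndex((r.chrom, r.start, r.end) for r in recs)
    planted = genome.regions[~genome.regions["ko_only"]]
    recovered = sum(
        idx.overlaps_any(r.chrom, r.start, r.end) for r in planted.itertuples()
    )
    assert recovered >= 0.8 * len(planted)


def test_call_dmrs_all_hypo(severe_cohort):
    _, matrix, meta = severe_cohort
    recs = call_dmrs(matrix, meta, "mutant", "control")
    assert recs and all(r.direction == "hypo" for r in recs)


def test_call_dmrs_stable_ids_and_order(severe_cohort):
    _, matrix, meta = severe_cohort
    recs = call_dmrs(matrix, meta, "mutant", "control")
    assert [r.id for r in recs] == [f"dmr_{i + 1}" for i in range(len(recs))]
    keys = [(r.chrom, r.start) for r in recs]
    assert keys == sorted(keys)


def test_call_dmrs_deterministic(severe_cohort):
    _, matrix, meta = severe_cohort
    a = call_dmrs(matrix, meta, "mutant", "control")
    b = call_dmrs(matrix, meta, "mutant", "control")
    assert a == b


def test_call_dmrs_hyper_mode():
    # hyper effects need headroom below 1.0, so lower the background baseline
    cfg = SimulationConfig(
        seed=3, n_chroms=1, chrom_length=800_000, n_regions=15, hyper_mode=True,
        baseline_background=0.45,
    )
    _, matrix, meta = simulate_cohort(cfg)
    recs = call_dmrs(matrix, meta, "mutant", "control")
    assert recs and all(r.direction == "hyper" for r in recs)


# ---------------------------------------------------------------------------
# covariate regression


def _regression_cohort(seed, geno_effect=-0.3, age_effect=0.0, n_test=6, n_ref=10):
    rng = np.random.default_rng(seed)
    samples = [f"t{i}" for i in range(n_test)] + [f"r{i}" for i in range(n_ref)]
    groups = ["case"] * n_test + ["control"] * n_ref
    ages = list(rng.uniform(2, 40, n_test + n_ref))
    sexes = (["M", "F"] * ((n_test + n_ref) // 2 + 1))[: n_test + n_ref]
    meta = build_metadata(samples, groups, ages=ages, sexes=sexes)
    records = []
    for k in range(8):
        means = {}
        for s, g, a in zip(samples, groups, ages):
            mu = 0.8 + (geno_effect if g == "case" else 0.0) + age_effect * math.log(a)
            means[s] = float(np.clip(mu + rng.normal(0, 0.02), 0, 1))
        records.append(make_record(1000 * (k + 1), 1000 * (k + 1) + 500, sample_means=means))
    positions = [10]
    matrix = build_matrix(positions, np.full((1, len(samples)), 0.5), samples=samples)
    return records, matrix, meta


def test_covariate_regression_recovers_effect():
    records, matrix, meta = _regression_cohort(seed=0)
    out = covariate_regression(records, matrix, meta, "case", "control")
    assert (out["genotype_coef"].between(-0.33, -0.27)).all()
    assert (out["genotype_q"] < 0.05).all()


def test_covariate_regression_singular_design():
    records, matrix, meta = _regression_cohort(seed=0)
    meta["group"] = "case"  # genotype indicator constant
    out = covariate_regression(records, matrix, meta, "case", "case")
    assert out["singular"].all()
    assert out["genotype_coef"].isna().all()


def test_covariate_regression_age_only_null():
    hits = 0
    for seed in range(20):
        records, matrix, meta = _regression_cohort(
            seed=seed, geno_effect=0.0, age_effect=0.03
        )
        out = covariate_regression(records, matrix, meta, "case", "control")
        if (out["genotype_q"] >= 0.05).all():
            hits += 1
    assert hits >= 18


# ---------------------------------------------------------------------------
# summaries


def test_dmr_summary_published_width_ttest():
    # reconstruct two width samples with the printed moments is unnecessary:
    # the summary path exposes the pooled test directly via set statistics
    a = [make_record(0, 100), make_record(200, 320)]
    b = [make_record(0, 100), make_record(200, 320)]
    out = dmr_summary(a, b)
    assert out["width_ttest"]["t"] == pytest.approx(0.0, abs=1e-12)
    assert out["width_ttest"]["p"] == pytest.approx(1.0)


def test_dmr_summary_intersections_half_open():
    a = [make_record(100, 200)]
    b = [make_record(199, 300)]
    assert dmr_summary(a, b)["a_overlapping_b"] == 1
    c = [make_record(200, 300)]
    assert dmr_summary(a, c)["a_overlapping_b"] == 0


def test_dmr_summary_empty_set():
    out = dmr_summary([])
    assert out["set_a"]["count"] == 0
    assert math.isnan(out["set_a"]["width_mean"])


# ---------------------------------------------------------------------------
# replicate correlation


def test_replicate_correlation_duplicate_sample():
    rng = np.random.default_rng(2)
    vals = rng.random(200)
    matrix = build_matrix(
        np.arange(200) * 10, np.column_stack([vals, vals]), samples=["a", "b"]
    )
    meta = build_metadata(["a", "b"], ["g", "g"])
    out = replicate_correlation(matrix, meta)
    assert out["g"].loc["a", "b"] == pytest.approx(1.0)
    assert out["g"].attrs["qc_pass"]


def test_replicate_correlation_anticorrelated():
    rng = np.random.default_rng(2)
    vals = rng.random(200)
    matrix = build_matrix(
        np.arange(200) * 10, np.column_stack([vals, 1 - vals]), samples=["a", "b"]
    )
    meta = build_metadata(["a", "b"], ["g", "g"])
    out = replicate_correlation(matrix, meta)
    assert out["g"].loc["a", "b"] == pytest.approx(-1.0)
    assert not out["g"].attrs["qc_pass"]


def test_replicate_correlation_simulated_cohort(severe_cohort):
    _, matrix, meta = severe_cohort
    out = replicate_correlation(matrix, meta)
    for frame in out.values():
        assert frame.attrs["qc_pass"]
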