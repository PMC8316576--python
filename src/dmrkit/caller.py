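"""DMR detection: seed-and-extend segmentation over per-CpG group-mean
differences, a rank test on per-sample regional means, BH control, merging
of near-adjacent regions, and the within-group-SD canonicality filter.

The filter cascade applies the published criteria: regions must span at
least ``min_cpgs`` CpGs, show an absolute group-mean methylation difference
of at least ``min_mean_diff``, reach ``q <= max_fdr``, and (canonicality)
have a within-group SD of per-sample regional means <= ``max_within_group_sd``
in both groups.  Regions closer than ``merge_gap_bp`` are merged with full
recomputation of their statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import IntervalIndex, MethylationMatrix, group_samples, validate_metadata
from .errors import ValidationError
from .stats import bh_fdr, mann_whitney_u, pooled_ttest_from_stats

log = logging.getLogger(__name__)


@dataclass
class DmrParams:
    """Thresholds of the calling cascade (defaults match the published
    criteria; segmentation knobs are documented substitutes)."""

    min_cpgs: int = 10
    min_mean_diff: float = 0.2
    max_fdr: float = 0.05
    max_within_group_sd: float = 0.1
    merge_gap_bp: int = 50
    max_intersite_gap_bp: int = 300
    min_samples_per_group_at_cpg: int = 2
    region_test: str = "mannwhitney"
    sd_filter_both_groups: bool = True  # False: test group only
    coverage_weighted_means: bool = False

    def __post_init__(self) -> None:
        if self.min_cpgs <= 0 or self.merge_gap_bp <= 0 or self.max_intersite_gap_bp <= 0:
            raise ValidationError("all thresholds must be positive")
        if not 0 < self.min_mean_diff <= 1:
            raise ValidationError("min_mean_diff must lie in (0, 1]")
        if self.max_fdr <= 0 or self.max_within_group_sd <= 0:
            raise ValidationError("all thresholds must be positive")


@dataclass(eq=False)
class DmrRecord:
    """A called region with its per-sample and per-group statistics.

    Coordinates are 0-based half-open; ``mean_diff`` is test minus
    reference (signed); ``direction`` is 'hypo' iff the difference is
    negative.
    """

    id: str
    chrom: str
    start: int
    end: int
    n_cpgs: int
    sample_means: dict[str, float]
    mean_test: float
    mean_ref: float
    mean_diff: float
    sd_test: float
    sd_ref: float
    p: float
    q: float
    direction: str = ""
    sd_undefined: bool = False
    site_idx: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("DMR width must be positive")
        if not self.direction:
            self.direction = "hypo" if self.mean_diff < 0 else "hyper"

    @property
    def width_bp(self) -> int:
        return self.end - self.start

    def __eq__(self, other) -> bool:  # NaN-tolerant field equality
        if not isinstance(other, DmrRecord):
            return NotImplemented

        def same(a, b):
            if isinstance(a, float) and isinstance(b, float):
                return (math.isnan(a) and math.isnan(b)) or a == b
            return a == b

        scalars = (
            "id chrom start end n_cpgs mean_test mean_ref mean_diff "
            "sd_test sd_ref p q direction sd_undefined".split()
        )
        if not all(same(getattr(self, k), getattr(other, k)) for k in scalars):
            return False
        if set(self.sample_means) != set(other.sample_means):
            return False
        return all(same(self.sample_means[k], other.sample_means[k]) for k in self.sample_means)


@dataclass
class Candidate:
    """A maximal run of consecutive CpGs with a constant-sign difference."""

    chrom: str
    start: int
    end: int
    site_idx: np.ndarray  # global site indices of member CpGs


# ---------------------------------------------------------------------------
# segmentation


def segment_candidates(
    matrix: MethylationMatrix,
    metadata: pd.DataFrame,
    test_group: str,
    ref_group: str,
    params: DmrParams | None = None,
) -> list[Candidate]:
    """Find maximal runs of consecutive CpGs where each CpG is covered in
    >= ``min_samples_per_group_at_cpg`` samples of both groups, consecutive
    CpGs are <= ``max_intersite_gap_bp`` apart, the per-CpG group-mean
    difference keeps a constant sign, and every prefix of the run keeps a
    running mean |difference| >= ``min_mean_diff``.  Runs shorter than
    ``min_cpgs`` are discarded."""
    params = params or DmrParams()
    validate_metadata(metadata, matrix.samples)
    t_idx = [matrix.sample_index(s) for s in group_samples(metadata, test_group)]
    r_idx = [matrix.sample_index(s) for s in group_samples(metadata, ref_group)]

    cov_t = (matrix.coverage[:, t_idx] > 0).sum(axis=1)
    cov_r = (matrix.coverage[:, r_idx] > 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_t = np.nanmean(matrix.ratio[:, t_idx], axis=1)
        mean_r = np.nanmean(matrix.ratio[:, r_idx], axis=1)
    diff = mean_t - mean_r
    k = params.min_samples_per_group_at_cpg
    valid = (cov_t >= k) & (cov_r >= k) & ~np.isnan(diff)

    candidates: list[Candidate] = []

    def close(run: list[int], chrom: str) -> None:
        if len(run) >= params.min_cpgs:
            candidates.append(
                Candidate(
                    chrom=chrom,
                    start=int(matrix.starts[run[0]]),
                    end=int(matrix.starts[run[-1]]) + 1,
                    site_idx=np.asarray(run, dtype=np.int64),
                )
            )

    for chrom, sl in matrix.chrom_slices():
        run: list[int] = []
        run_sum = 0.0
        run_sign = 0
        for i in range(sl.start, sl.stop):
            if not valid[i]:
                close(run, chrom)
                run, run_sum, run_sign = [], 0.0, 0
                continue
            d = float(diff[i])
            sign = 1 if d > 0 else (-1 if d < 0 else 0)
            ok = bool(run)
            if ok:
                gap = int(matrix.starts[i]) - int(matrix.starts[run[-1]])
                ok = (
                    gap <= params.max_intersite_gap_bp
                    and sign == run_sign
                    and abs(run_sum + d) / (len(run) + 1) >= params.min_mean_diff
                )
            if ok:
                run.append(i)
                run_sum += d
            else:
                close(run, chrom)
                # try to seed a new run at this CpG
                if sign != 0 and abs(d) >= params.min_mean_diff:
                    run, run_sum, run_sign = [i], d, sign
                else:
                    run, run_sum, run_sign = [], 0.0, 0
        close(run, chrom)
    return candidates


# ---------------------------------------------------------------------------
# scoring


def _regional_stats(
    matrix: MethylationMatrix,
    site_idx: np.ndarray,
    t_idx: list[int],
    r_idx: list[int],
    coverage_weighted: bool = False,
):
    """Per-sample regional means over the member CpGs plus group summaries.

    Returns (sample_means_by_column, test_means, ref_means) where group
    arrays drop samples with no covered CpG in the region."""
    sub = matrix.ratio[site_idx]
    if coverage_weighted:
        w = matrix.coverage[site_idx].astype(float)
        w[np.isnan(sub)] = 0.0
        num = np.nansum(sub * w, axis=0)
        den = w.sum(axis=0)
        with np.errstate(invalid="ignore"):
            col_means = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    else:
        with np.errstate(invalid="ignore"):
            col_means = np.nanmean(sub, axis=0)
    t_means = col_means[t_idx]
    r_means = col_means[r_idx]
    return col_means, t_means[~np.isnan(t_means)], r_means[~np.isnan(r_means)]


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) >= 2 else float("nan")


def _build_record(
    matrix: MethylationMatrix,
    site_idx: np.ndarray,
    chrom: str,
    start: int,
    end: int,
    t_idx: list[int],
    r_idx: list[int],
    params: DmrParams,
) -> DmrRecord | None:
    col_means, t_means, r_means = _regional_stats(
        matrix, site_idx, t_idx, r_idx, params.coverage_weighted_means
    )
    if len(t_means) == 0 or len(r_means) == 0:
        return None
    _, p = mann_whitney_u(t_means, r_means)
    sample_means = {
        s: float(col_means[j])
        for j, s in enumerate(matrix.samples)
        if not np.isnan(col_means[j])
    }
    return DmrRecord(
        id="",
        chrom=chrom,
        start=start,
        end=end,
        n_cpgs=len(site_idx),
        sample_means=sample_means,
        mean_test=float(np.mean(t_means)),
        mean_ref=float(np.mean(r_means)),
        mean_diff=float(np.mean(t_means) - np.mean(r_means)),
        sd_test=_sd(t_means),
        sd_ref=_sd(r_means),
        p=float(p),
        q=float("nan"),
        site_idx=site_idx,
    )


def score_and_filter(
    candidates: list[Candidate],
    matrix: MethylationMatrix,
    metadata: pd.DataFrame,
    test_group: str,
    ref_group: str,
    params: DmrParams | None = None,
) -> list[DmrRecord]:
    """Score candidates (rank test on per-sample regional means), apply BH
    across ALL candidates genome-wide, and keep q <= max_fdr with
    |difference| >= min_mean_diff."""
    params = params or DmrParams()
    t_idx = [matrix.sample_index(s) for s in group_samples(metadata, test_group)]
    r_idx = [matrix.sample_index(s) for s in group_samples(metadata, ref_group)]
    records: list[DmrRecord] = []
    for c in candidates:
        rec = _build_record(
            matrix, c.site_idx, c.chrom, c.start, c.end, t_idx, r_idx, params
        )
        if rec is None:
            log.warning(
                "candidate %s:%d-%d dropped: a group has no covered sample",
                c.chrom,
                c.start,
                c.end,
            )
            continue
        records.append(rec)
    if not records:
        return []
    q = bh_fdr([r.p for r in records])
    kept = []
    for rec, qv in zip(records, q):
        rec.q = float(qv)
        if rec.q <= params.max_fdr and abs(rec.mean_diff) >= params.min_mean_diff:
            kept.append(rec)
    log.info("score_and_filter: %d/%d candidates kept", len(kept), len(records))
    return kept


# ---------------------------------------------------------------------------
# merging


def merge_adjacent(
    records: list[DmrRecord],
    params: DmrParams | None = None,
    matrix: MethylationMatrix | None = None,
    metadata: pd.DataFrame | None = None,
    test_group: str | None = None,
    ref_group: str | None = None,
) -> list[DmrRecord]:
    """Merge same-chromosome records whose gap is < ``merge_gap_bp``
    (transitively).  When the matrix is available, merged statistics are
    recomputed exactly over the union of member CpGs; otherwise per-sample
    means are combined weighted by member CpG counts and p is the member
    minimum (approximation, logged).  q is re-assigned by BH over the
    post-merge set."""
    params = params or DmrParams()
    if not records:
        return []
    recs = sorted(records, key=lambda r: (r.chrom, r.start, r.end))
    groups: list[list[DmrRecord]] = [[recs[0]]]
    for r in recs[1:]:
        prev = groups[-1][-1]
        if r.chrom == prev.chrom and r.start - prev.end < params.merge_gap_bp:
            groups[-1].append(r)
        else:
            groups.append([r])

    exact = matrix is not None and metadata is not None
    if exact:
        t_idx = [matrix.sample_index(s) for s in group_samples(metadata, test_group)]
        r_idx = [matrix.sample_index(s) for s in group_samples(metadata, ref_group)]

    merged: list[DmrRecord] = []
    for grp in groups:
        if len(grp) == 1:
            merged.append(grp[0])
            continue
        chrom = grp[0].chrom
        start = min(r.start for r in grp)
        end = max(r.end for r in grp)
        if exact and all(r.site_idx is not None for r in grp):
            union = np.unique(np.concatenate([r.site_idx for r in grp]))
            rec = _build_record(matrix, union, chrom, start, end, t_idx, r_idx, params)
            if rec is None:  # degenerate; keep widest member
                rec = max(grp, key=lambda r: r.width_bp)
            merged.append(rec)
        else:
            log.warning(
                "merge_adjacent: no matrix available; combining member statistics "
                "by CpG-count weighting (approximate)"
            )
            n_cpgs = sum(r.n_cpgs for r in grp)
            samples = sorted({s for r in grp for s in r.sample_means})
            sample_means = {}
            for s in samples:
                pairs = [(r.sample_means[s], r.n_cpgs) for r in grp if s in r.sample_means]
                sample_means[s] = sum(v * w for v, w in pairs) / sum(w for _, w in pairs)
            w = np.array([r.n_cpgs for r in grp], dtype=float)
            mean_test = float(np.average([r.mean_test for r in grp], weights=w))
            mean_ref = float(np.average([r.mean_ref for r in grp], weights=w))
            merged.append(
                DmrRecord(
                    id="",
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_cpgs=n_cpgs,
                    sample_means=sample_means,
                    mean_test=mean_test,
                    mean_ref=mean_ref,
                    mean_diff=mean_test - mean_ref,
                    sd_test=float(np.average([r.sd_test for r in grp], weights=w)),
                    sd_ref=float(np.average([r.sd_ref for r in grp], weights=w)),
                    p=min(r.p for r in grp),
                    q=float("nan"),
                )
            )
    q = bh_fdr([r.p for r in merged])
    for rec, qv in zip(merged, q):
        rec.q = float(qv)
    return merged


# ---------------------------------------------------------------------------
# canonicality


def canonicality_filter(
    records: list[DmrRecord],
    metadata: pd.DataFrame | None = None,
    params: DmrParams | None = None,
) -> list[DmrRecord]:
    """Keep records whose within-group SD of per-sample regional means is
    <= ``max_within_group_sd`` (inclusive boundary).  Applied to both groups
    by default; with ``sd_filter_both_groups=False``, the test group only.
    Records with an undefined SD (a group of < 2 samples) are kept with a
    warning flag."""
    params = params or DmrParams()
    kept: list[DmrRecord] = []
    removed = 0
    for r in records:
        sds = [r.sd_test] + ([r.sd_ref] if params.sd_filter_both_groups else [])
        if any(math.isnan(s) for s in sds):
            r.sd_undefined = True
            log.warning("DMR %s:%d-%d: SD undefined (group < 2 samples); kept", r.chrom, r.start, r.end)
            kept.append(r)
        elif all(s <= params.max_within_group_sd for s in sds):
            kept.append(r)
        else:
            removed += 1
    log.info("canonicality_filter removed %d of %d records", removed, len(records))
    return kept


# ---------------------------------------------------------------------------
# top level


def call_dmrs(
    matrix: MethylationMatrix,
    metadata: pd.DataFrame,
    test_group: str,
    ref_group: str,
    params: DmrParams | None = None,
) -> list[DmrRecord]:
    """Full cascade: segment -> score/FDR -> merge -> canonicality.  Final
    records get stable ids dmr_1..dmr_n in coordinate order.  Deterministic."""
    params = params or DmrParams()
    candidates = segment_candidates(matrix, metadata, test_group, ref_group, params)
    log.info("segmentation: %d candidates", len(candidates))
    provisional = score_and_filter(
        candidates, matrix, metadata, test_group, ref_group, params
    )
    merged = merge_adjacent(provisional, params, matrix, metadata, test_group, ref_group)
    final = canonicality_filter(merged, metadata, params)
    final.sort(key=lambda r: (r.chrom, r.start, r.end))
    for i, r in enumerate(final, start=1):
        r.id = f"dmr_{i}"
    log.info(
        "call_dmrs: candidates=%d post_fdr=%d post_merge=%d post_sd=%d",
        len(candidates),
        len(provisional),
        len(merged),
        len(final),
    )
    return final


# ---------------------------------------------------------------------------
# covariate sensitivity regression


def covariate_regression(
    records: list[DmrRecord],
    matrix: MethylationMatrix,
    metadata: pd.DataFrame,
    test_group: str,
    ref_group: str,
) -> pd.DataFrame:
    """Per DMR: OLS of per-sample regional mean on genotype indicator + sex
    indicator + log(age); two-sided t on the genotype coefficient; BH across
    DMRs.  A rank-deficient design is flagged with undefined coefficient."""
    validate_metadata(metadata)
    meta = metadata[metadata["group"].isin([test_group, ref_group])]
    if meta.empty:
        raise ValidationError("no samples in the requested groups")
    rows = []
    for r in records:
        y, geno, sexf, logage = [], [], [], []
        for m in meta.itertuples(index=False):
            if m.sample not in r.sample_means:
                continue
            y.append(r.sample_means[m.sample])
            geno.append(1.0 if m.group == test_group else 0.0)
            sexf.append(1.0 if m.sex == "F" else 0.0)
            logage.append(math.log(m.age))
        X = np.column_stack([np.ones(len(y)), geno, sexf, logage])
        singular = (
            len(y) <= X.shape[1] or np.linalg.matrix_rank(X) < X.shape[1]
        )
        if singular:
            rows.append((r.id, float("nan"), float("nan"), True))
            continue
        fit = sm.OLS(np.asarray(y), X).fit()
        rows.append((r.id, float(fit.params[1]), float(fit.pvalues[1]), False))
    out = pd.DataFrame(rows, columns=["dmr_id", "genotype_coef", "genotype_p", "singular"])
    ok = ~out["singular"] & ~out["genotype_p"].isna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[np.flatnonzero(ok)] = bh_fdr(out.loc[ok, "genotype_p"].to_numpy())
    out["genotype_q"] = q
    out["significant"] = out["genotype_q"] < 0.05
    return out


# ---------------------------------------------------------------------------
# summaries


def intersection_count(records_a: list[DmrRecord], records_b: list[DmrRecord]) -> int:
    """Number of records in A overlapping (>= 1 bp) any record in B."""
    idx = IntervalIndex((r.chrom, r.start, r.end) for r in records_b)
    return sum(1 for r in records_a if idx.overlaps_any(r.chrom, r.start, r.end))


def dmr_summary(
    records_a: list[DmrRecord],
    records_b: list[DmrRecord] | None = None,
) -> dict:
    """Count, width mean +/- SD and per-group mean methylation for each set;
    with two sets, a pooled-variance two-tailed t-test on widths plus
    1 bp-overlap intersection counts in both directions."""

    def one(records):
        if not records:
            return {
                "count": 0,
                "width_mean": float("nan"),
                "width_sd": float("nan"),
                "mean_test": float("nan"),
                "mean_ref": float("nan"),
            }
        widths = np.array([r.width_bp for r in records], dtype=float)
        return {
            "count": len(records),
            "width_mean": float(widths.mean()),
            "width_sd": _sd(widths),
            "mean_test": float(np.mean([r.mean_test for r in records])),
            "mean_ref": float(np.mean([r.mean_ref for r in records])),
        }

    out = {"set_a": one(records_a)}
    if records_b is not None:
        out["set_b"] = one(records_b)
        a, b = out["set_a"], out["set_b"]
        if a["count"] >= 2 and b["count"] >= 2:
            t, p = pooled_ttest_from_stats(
                a["width_mean"], a["width_sd"], a["count"],
                b["width_mean"], b["width_sd"], b["count"],
            )
            out["width_ttest"] = {"t": t, "p": p}
        out["a_overlapping_b"] = intersection_count(records_a, records_b)
        out["b_overlapping_a"] = intersection_count(records_b, records_a)
    return out


def replicate_correlation(
    matrix: MethylationMatrix, metadata: pd.DataFrame, qc_threshold: float = 0.8
) -> dict[str, pd.DataFrame]:
    """Per group, pairwise Pearson r over CpGs covered in both samples of
    each pair.  Pairs with < 2 shared covered CpGs get NaN.  Each frame
    carries a ``qc_pass`` attribute: True when all within-group pairs have
    r > ``qc_threshold``."""
    validate_metadata(metadata, matrix.samples)
    out: dict[str, pd.DataFrame] = {}
    for group, sub in metadata.groupby("group"):
        samples = sub["sample"].tolist()
        n = len(samples)
        mat = np.full((n, n), np.nan)
        for i in range(n):
            mat[i, i] = 1.0
            xi = matrix.ratio[:, matrix.sample_index(samples[i])]
            for j in range(i + 1, n):
                xj = matrix.ratio[:, matrix.sample_index(samples[j])]
                both = ~np.isnan(xi) & ~np.isnan(xj)
                if both.sum() < 2:
                    log.warning("pair %s/%s: <2 shared covered CpGs", samples[i], samples[j])
                    continue
                a, b = xi[both], xj[both]
                if np.std(a) == 0 or np.std(b) == 0:
                    continue
                mat[i, j] = mat[j, i] = float(np.corrcoef(a, b)[0, 1])
        frame = pd.DataFrame(mat, index=samples, columns=samples)
        off = mat[~np.eye(n, dtype=bool)]
        frame.attrs["qc_pass"] = bool(n < 2 or np.all(off[~np.isnan(off)] > qc_threshold))
        out[str(group)] = frame
    return out
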