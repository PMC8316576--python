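"""Single-cell expression integration: QC filtering, depth normalization,
cluster composition testing, per-cluster differential expression,
recurrent-DEG detection, expressing-fraction tests, lineage annotation
against reference profiles, and DEG-to-DMR proximity linking.

QC boundaries are strict inequalities: cells are removed when they have
fewer than ``min_genes`` expressed genes, less than ``min_reads`` total
reads, or more than ``max_mito_fraction`` mitochondrial transcripts.  DEG
gates are conjunctive: p <= 0.05 AND |log2 ratio| >= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps

from .core import IntervalIndex
from .errors import ValidationError
from .stats import bh_fdr, contingency_chi2, fisher_exact_2x2

log = logging.getLogger(__name__)


@dataclass
class QcParams:
    min_genes: int = 250
    min_reads: int = 500
    max_mito_fraction: float = 0.10
    target_depth: float = 10_000.0

    def __post_init__(self) -> None:
        if min(self.min_genes, self.min_reads, self.max_mito_fraction, self.target_depth) <= 0:
            raise ValidationError("all QC parameters must be positive")


@dataclass
class DegThresholds:
    max_p: float = 0.05
    min_abs_log2_ratio: float = 1.0
    min_cells_per_group: int = 10


@dataclass
class DegRecord:
    cluster: str
    gene: str
    log2_ratio: float
    p: float
    direction: str  # up | down (test relative to reference)
    frac_expressing_test: float
    frac_expressing_ref: float
    expressing_fisher_p: float
    q: float = float("nan")  # BH within cluster, informational only


@dataclass
class ExpressionMatrix:
    """Cells x genes counts with per-cell sample/group/cluster labels.

    ``cell_meta`` columns: sample, group, cluster (indexed like barcodes).
    """

    counts: np.ndarray
    genes: list[str]
    barcodes: list[str]
    cell_meta: pd.DataFrame
    mito: np.ndarray
    gene_intervals: dict[str, tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        if sparse.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        n_cells, n_genes = self.counts.shape
        if len(self.barcodes) != n_cells or len(self.genes) != n_genes:
            raise ValidationError("counts shape does not match barcodes x genes")
        self.mito = np.asarray(self.mito, dtype=bool)
        if len(self.mito) != n_genes:
            raise ValidationError("mito flag vector length mismatch")
        for col in ("sample", "group", "cluster"):
            if col not in self.cell_meta.columns:
                raise ValidationError(f"cell_meta missing column {col!r}")
        if len(self.cell_meta) != n_cells:
            raise ValidationError("cell_meta length mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts[mask],
            genes=self.genes,
            barcodes=[b for b, m in zip(self.barcodes, mask) if m],
            cell_meta=self.cell_meta.loc[np.asarray(mask)].reset_index(drop=True),
            mito=self.mito,
            gene_intervals=self.gene_intervals,
        )


# ---------------------------------------------------------------------------
# QC and normalization


def qc_filter_cells(
    matrix: ExpressionMatrix, params: QcParams | None = None
) -> tuple[ExpressionMatrix, dict]:
    """Remove cells failing ANY rule; a cell may fail several, and each
    failure is tallied per rule in the report."""
    params = params or QcParams()
    if not matrix.mito.any() and matrix.counts.shape[1] > 0:
        raise ValidationError("no mitochondrial gene flags set; cannot apply mito rule")
    genes_per_cell = (matrix.counts > 0).sum(axis=1)
    reads_per_cell = matrix.counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            reads_per_cell > 0,
            matrix.counts[:, matrix.mito].sum(axis=1) / np.maximum(reads_per_cell, 1),
            1.0,
        )
    fail_genes = genes_per_cell < params.min_genes
    fail_reads = reads_per_cell < params.min_reads
    fail_mito = mito_frac > params.max_mito_fraction
    keep = ~(fail_genes | fail_reads | fail_mito)
    report = {
        "n_input": matrix.n_cells,
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "failed_min_genes": int(fail_genes.sum()),
        "failed_min_reads": int(fail_reads.sum()),
        "failed_max_mito": int(fail_mito.sum()),
    }
    return matrix.subset_cells(keep), report


def normalize_cells(
    matrix: ExpressionMatrix, target_depth: float = 10_000.0, log_transform: bool = True
) -> np.ndarray:
    """Depth-normalize each cell to ``target_depth`` (pre-log values sum to
    the target exactly) and apply log(1 + x) by default."""
    totals = matrix.counts.sum(axis=1, dtype=float)
    if (totals == 0).any():
        raise ValidationError("zero-total cell encountered; run QC first")
    scaled = matrix.counts * (target_depth / totals)[:, None]
    return np.log1p(scaled) if log_transform else scaled


# ---------------------------------------------------------------------------
# composition


def cluster_composition_test(matrix: ExpressionMatrix) -> dict:
    """Pearson chi-squared on the clusters x sample contingency table plus
    per-cluster percent of total cells per sample."""
    table = pd.crosstab(matrix.cell_meta["cluster"], matrix.cell_meta["sample"])
    table = table.loc[table.sum(axis=1) > 0]
    stat, p = contingency_chi2(table.to_numpy())
    fractions = 100.0 * table / table.sum(axis=0)
    return {"statistic": stat, "p": p, "table": table, "percent": fractions}


# ---------------------------------------------------------------------------
# differential expression


def cluster_deg_test(
    matrix: ExpressionMatrix,
    test_group: str,
    ref_group: str,
    thresholds: DegThresholds | None = None,
    target_depth: float = 10_000.0,
) -> list[DegRecord]:
    """Per cluster, per gene: Welch two-sided t-test on log-normalized
    values between genotype groups; log2 ratio from depth-scaled (pre-log)
    group means with pseudo-count 1.  Emit genes passing BOTH gates."""
    thresholds = thresholds or DegThresholds()
    groups = set(matrix.cell_meta["group"])
    for g in (test_group, ref_group):
        if g not in groups:
            raise ValidationError(f"group {g!r} absent from cell metadata")
    norm = normalize_cells(matrix, target_depth)
    scaled = normalize_cells(matrix, target_depth, log_transform=False)
    records: list[DegRecord] = []
    grp = matrix.cell_meta["group"].to_numpy()
    clusters = matrix.cell_meta["cluster"].to_numpy()
    for cluster in sorted(pd.unique(clusters)):
        in_cl = clusters == cluster
        t_mask = in_cl & (grp == test_group)
        r_mask = in_cl & (grp == ref_group)
        nt, nr = int(t_mask.sum()), int(r_mask.sum())
        if nt < thresholds.min_cells_per_group or nr < thresholds.min_cells_per_group:
            log.warning(
                "cluster %s skipped: %d test / %d ref cells (< %d)",
                cluster, nt, nr, thresholds.min_cells_per_group,
            )
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            tt = sps.ttest_ind(norm[t_mask], norm[r_mask], equal_var=False, axis=0)
        pvals = np.asarray(tt.pvalue, dtype=float)
        pvals[np.isnan(pvals)] = 1.0  # zero variance and equal means
        mean_t = scaled[t_mask].mean(axis=0)
        mean_r = scaled[r_mask].mean(axis=0)
        l2r = np.log2((mean_t + 1.0) / (mean_r + 1.0))
        qvals = bh_fdr(pvals)
        hit = (pvals <= thresholds.max_p) & (np.abs(l2r) >= thresholds.min_abs_log2_ratio)
        for j in np.flatnonzero(hit):
            et = int((matrix.counts[t_mask, j] > 0).sum())
            er = int((matrix.counts[r_mask, j] > 0).sum())
            fisher_p = fisher_exact_2x2([[et, nt - et], [er, nr - er]])
            records.append(
                DegRecord(
                    cluster=str(cluster),
                    gene=matrix.genes[j],
                    log2_ratio=float(l2r[j]),
                    p=float(pvals[j]),
                    direction="up" if l2r[j] > 0 else "down",
                    frac_expressing_test=et / nt,
                    frac_expressing_ref=er / nr,
                    expressing_fisher_p=fisher_p,
                    q=float(qvals[j]),
                )
            )
    return records


def deg_frame(records: list[DegRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.cluster, r.gene, r.log2_ratio, r.p, r.q, r.direction,
                r.frac_expressing_test, r.frac_expressing_ref, r.expressing_fisher_p,
            )
            for r in records
        ],
        columns=[
            "cluster", "gene", "log2_ratio", "p", "q", "direction",
            "frac_expressing_test", "frac_expressing_ref", "expressing_fisher_p",
        ],
    )


def recurrent_degs(records: list[DegRecord]) -> pd.DataFrame:
    """Genes dysregulated in >= 2 clusters, with per-cluster directions and
    a concordance flag (all directions equal)."""
    by_gene: dict[str, list[DegRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    rows = []
    for gene, recs in sorted(by_gene.items()):
        clusters = sorted({r.cluster for r in recs})
        if len(clusters) < 2:
            continue
        directions = [r.direction for r in sorted(recs, key=lambda r: r.cluster)]
        rows.append(
            (gene, len(clusters), ",".join(clusters), ",".join(directions),
             len(set(directions)) == 1)
        )
    return pd.DataFrame(
        rows, columns=["gene", "n_clusters", "clusters", "directions", "concordant"]
    )


def expressing_fraction_test(
    matrix: ExpressionMatrix,
    gene: str,
    groups: tuple[str, str],
    cluster_subset: list | None = None,
) -> dict:
    """Two-sided Fisher exact test on expressing (count > 0) vs not, by
    group, optionally restricted to a cluster subset."""
    if gene not in matrix.genes:
        raise ValidationError(f"gene {gene!r} not present")
    j = matrix.genes.index(gene)
    mask = np.ones(matrix.n_cells, dtype=bool)
    if cluster_subset is not None:
        mask = matrix.cell_meta["cluster"].isin(cluster_subset).to_numpy()
    if not mask.any():
        raise ValidationError("empty cell subset")
    grp = matrix.cell_meta["group"].to_numpy()
    table = []
    fracs = {}
    for g in groups:
        sel = mask & (grp == g)
        n = int(sel.sum())
        if n == 0:
            raise ValidationError(f"no cells for group {g!r} in subset")
        e = int((matrix.counts[sel, j] > 0).sum())
        table.append([e, n - e])
        fracs[g] = e / n
    return {"p": fisher_exact_2x2(table), "fractions": fracs, "table": table}


# ---------------------------------------------------------------------------
# DEG <-> DMR proximity


def link_degs_to_dmrs(
    deg_records: list[DegRecord],
    gene_intervals: dict[str, tuple[str, int, int]],
    dmrs,
    k: int = 10_000,
) -> pd.DataFrame:
    """Per unique DEG gene, edge-to-edge distance from its gene body to the
    nearest DMR; linked iff <= k (overlap -> 0).  Genes without an interval
    are unlinked and flagged.  The frame carries linked/total summary attrs."""
    idx = IntervalIndex((r.chrom, r.start, r.end) for r in dmrs)
    genes = sorted({r.gene for r in deg_records})
    rows = []
    for gene in genes:
        iv = gene_intervals.get(gene)
        if iv is None:
            rows.append((gene, float("nan"), False, True))
            continue
        d = idx.nearest_distance(*iv)
        rows.append((gene, d, bool(d <= k), False))
    out = pd.DataFrame(rows, columns=["gene", "distance", "linked", "no_interval"])
    out.attrs["n_linked"] = int(out["linked"].sum())
    out.attrs["n_total"] = len(out)
    return out


# ---------------------------------------------------------------------------
# lineage annotation


def knn_lineage_annotate(
    matrix: ExpressionMatrix,
    reference_profiles: pd.DataFrame,
    k: int = 1,
    min_shared_genes: int = 50,
) -> pd.Series:
    """Label each cell by Spearman correlation of its normalized expression
    to reference lineage profiles over shared genes; the label is the
    majority among the k best-correlated lineages (ties broken by higher
    mean correlation).  All-zero cells become 'unassigned'."""
    shared = [g for g in matrix.genes if g in reference_profiles.columns]
    if len(shared) < min_shared_genes:
        raise ValidationError(
            f"only {len(shared)} genes shared with the reference (< {min_shared_genes})"
        )
    gidx = [matrix.genes.index(g) for g in shared]
    totals = matrix.counts.sum(axis=1, dtype=float)
    expr = np.log1p(
        matrix.counts[:, gidx] * (10_000.0 / np.maximum(totals, 1.0))[:, None]
    )
    ref = reference_profiles[shared].to_numpy(dtype=float)
    lineages = list(reference_profiles.index)

    cell_ranks = sps.rankdata(expr, axis=1)
    ref_ranks = sps.rankdata(ref, axis=1)
    cr = cell_ranks - cell_ranks.mean(axis=1, keepdims=True)
    rr = ref_ranks - ref_ranks.mean(axis=1, keepdims=True)
    cn = np.linalg.norm(cr, axis=1)
    rn = np.linalg.norm(rr, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (cr @ rr.T) / np.outer(np.where(cn > 0, cn, 1), np.where(rn > 0, rn, 1))
    degenerate = (cn == 0) | (totals == 0)

    labels = []
    for i in range(matrix.n_cells):
        if degenerate[i]:
            labels.append("unassigned")
            continue
        order = np.argsort(-corr[i], kind="mergesort")[: max(1, k)]
        votes: dict[str, list[float]] = {}
        for j in order:
            votes.setdefault(lineages[j], []).append(float(corr[i, j]))
        best = max(votes.items(), key=lambda kv: (len(kv[1]), float(np.mean(kv[1]))))
        labels.append(best[0])
    return pd.Series(labels, index=matrix.barcodes, name="lineage")


# ---------------------------------------------------------------------------
# cross-species concordance


def cross_species_deg_concordance(
    degs_a: list[DegRecord],
    degs_b: list[DegRecord],
    name_map=None,
) -> pd.DataFrame:
    """Genes present in both DEG sets under case-insensitive name matching
    (or a custom mapping); concordant iff any direction in A matches any
    direction in B for that gene.  Percent is over unique A genes and is
    stored in frame attrs."""
    if name_map is None:
        name_map = lambda g: g.lower()  # noqa: E731
    a_dirs: dict[str, set[str]] = {}
    a_names: dict[str, str] = {}
    for r in degs_a:
        key = name_map(r.gene)
        a_dirs.setdefault(key, set()).add(r.direction)
        a_names.setdefault(key, r.gene)
    b_dirs: dict[str, set[str]] = {}
    for r in degs_b:
        b_dirs.setdefault(name_map(r.gene), set()).add(r.direction)
    rows = []
    for key in sorted(a_dirs):
        shared = key in b_dirs
        concordant = shared and bool(a_dirs[key] & b_dirs[key])
        rows.append((a_names[key], shared, concordant))
    out = pd.DataFrame(rows, columns=["gene", "in_both", "concordant"])
    out.attrs["n_a_genes"] = len(a_dirs)
    out.attrs["n_concordant"] = int(out["concordant"].sum())
    out.attrs["percent_concordant"] = (
        100.0 * out.attrs["n_concordant"] / len(a_dirs) if a_dirs else None
    )
    return out


# ---------------------------------------------------------------------------
# readers


def read_expression_dense(
    counts_path, cells_path, mito_prefix: str = "mt-"
) -> ExpressionMatrix:
    """Dense TSV (cells x genes, first column barcode) + cell metadata TSV
    with columns barcode, sample, group, cluster."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(cells_path, sep="\t", dtype=str)
    meta = meta.set_index("barcode").loc[counts.index].reset_index()
    genes = list(counts.columns)
    mito = np.array([g.lower().startswith(mito_prefix.lower()) for g in genes])
    return ExpressionMatrix(
        counts=counts.to_numpy(),
        genes=genes,
        barcodes=list(counts.index),
        cell_meta=meta[["sample", "group", "cluster"]],
        mito=mito,
    )


def read_expression_mtx(
    mtx_path, features_path, barcodes_path, cells_path, mito_prefix: str = "mt-"
) -> ExpressionMatrix:
    """MatrixMarket triplet (genes x cells, CellRanger orientation) plus
    feature/barcode lists and a cell metadata TSV."""
    from scipy.io import mmread

    m = mmread(str(mtx_path)).tocsr()
    genes = [line.split("\t")[0] for line in _read_lines(features_path)]
    barcodes = _read_lines(barcodes_path)
    if m.shape != (len(genes), len(barcodes)):
        raise ValidationError("MTX dimensions do not match features x barcodes")
    meta = pd.read_csv(cells_path, sep="\t", dtype=str)
    meta = meta.set_index("barcode").loc[barcodes].reset_index()
    mito = np.array([g.lower().startswith(mito_prefix.lower()) for g in genes])
    return ExpressionMatrix(
        counts=np.asarray(m.T.todense()),
        genes=genes,
        barcodes=barcodes,
        cell_meta=meta[["sample", "group", "cluster"]],
        mito=mito,
    )


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]
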