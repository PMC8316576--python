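"""Intersection of DMRs with categorized annotations: per-category
containment fractions with pairwise enrichment tests, per-sample
per-category mean methylation, and nearest-feature distances.

Overlap semantics everywhere: half-open intervals sharing >= 1 bp.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnnotationSet, IntervalIndex, MethylationMatrix, positions_in_intervals
from .errors import ValidationError
from .stats import bh_fdr, chi2_2x2, fisher_exact_2x2

log = logging.getLogger(__name__)


@dataclass
class CategoryEnrichment:
    """Per-category feature-containment summary with pairwise tests."""

    fractions: pd.DataFrame  # category, n_features, n_features_with_dmr, fraction
    pairwise: pd.DataFrame  # category_a, category_b, test, p, q


def features_containing_dmrs(
    annotations: AnnotationSet, dmrs
) -> CategoryEnrichment:
    """For each category, the fraction of features containing (>= 1 bp
    overlap) at least one DMR, plus pairwise 2x2 tests between categories
    (chi-squared without correction, Fisher exact when any expected cell
    < 5) with BH adjustment."""
    dmr_idx = IntervalIndex((r.chrom, r.start, r.end) for r in dmrs)
    rows = []
    for category in annotations.categories:
        sub = annotations.category_frame(category)
        n = len(sub)
        if n == 0:
            continue
        with_dmr = sum(
            1
            for row in sub.itertuples(index=False)
            if dmr_idx.overlaps_any(row.chrom, row.start, row.end)
        )
        rows.append((category, n, with_dmr, with_dmr / n))
    fractions = pd.DataFrame(
        rows, columns=["category", "n_features", "n_features_with_dmr", "fraction"]
    )

    pair_rows = []
    by_cat = {r.category: r for r in fractions.itertuples(index=False)}
    for a, b in itertools.combinations(sorted(by_cat), 2):
        ra, rb = by_cat[a], by_cat[b]
        table = np.array(
            [
                [ra.n_features_with_dmr, ra.n_features - ra.n_features_with_dmr],
                [rb.n_features_with_dmr, rb.n_features - rb.n_features_with_dmr],
            ],
            dtype=float,
        )
        if table[:, 0].sum() == 0:  # no DMR-containing feature anywhere
            pair_rows.append((a, b, "chi2", 1.0))
            continue
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if (expected < 5).any():
            pair_rows.append((a, b, "fisher", fisher_exact_2x2(table.astype(int))))
        else:
            pair_rows.append((a, b, "chi2", chi2_2x2(table)[1]))
    pairwise = pd.DataFrame(pair_rows, columns=["category_a", "category_b", "test", "p"])
    pairwise["q"] = bh_fdr(pairwise["p"].to_numpy()) if len(pairwise) else []
    return CategoryEnrichment(fractions=fractions, pairwise=pairwise)


def region_mean_methylation(
    matrix: MethylationMatrix,
    annotations: AnnotationSet,
    cpg_subset: str = "all",
    dmrs=None,
) -> pd.DataFrame:
    """Per sample and category, the unweighted mean ratio over covered CpGs
    inside category intervals.  ``cpg_subset='dmr_only'`` additionally
    restricts to CpGs inside a DMR.  CpGs in several features of one
    category count once.  Returns a samples x categories frame (NaN where a
    category holds no covered CpG)."""
    if cpg_subset not in ("all", "dmr_only"):
        raise ValidationError("cpg_subset must be 'all' or 'dmr_only'")
    if cpg_subset == "dmr_only" and dmrs is None:
        raise ValidationError("cpg_subset='dmr_only' requires a DMR set")

    dmr_mask = np.ones(matrix.n_sites, dtype=bool)
    if cpg_subset == "dmr_only":
        dmr_mask = np.zeros(matrix.n_sites, dtype=bool)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in dmrs:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for chrom, sl in matrix.chrom_slices():
            if chrom in by_chrom:
                dmr_mask[sl] = positions_in_intervals(matrix.starts[sl], by_chrom[chrom])

    out = {}
    for category in annotations.categories:
        sub = annotations.category_frame(category)
        mask = np.zeros(matrix.n_sites, dtype=bool)
        by_chrom = {}
        for row in sub.itertuples(index=False):
            by_chrom.setdefault(row.chrom, []).append((row.start, row.end))
        for chrom, sl in matrix.chrom_slices():
            if chrom in by_chrom:
                mask[sl] = positions_in_intervals(matrix.starts[sl], by_chrom[chrom])
        mask &= dmr_mask
        if not mask.any():
            out[category] = np.full(len(matrix.samples), np.nan)
            continue
        with np.errstate(invalid="ignore"):
            out[category] = np.nanmean(matrix.ratio[mask], axis=0)
    return pd.DataFrame(out, index=matrix.samples)


def nearest_feature_distance(
    dmrs, annotations: AnnotationSet, category: str
) -> pd.DataFrame:
    """Edge-to-edge distance from each DMR to the nearest feature of the
    category on the same chromosome (0 on overlap, inf when the chromosome
    has no feature)."""
    idx = annotations.index_for(category)
    rows = []
    for r in dmrs:
        d = idx.nearest_distance(r.chrom, r.start, r.end)
        rows.append((r.id, r.chrom, r.start, r.end, d, not np.isfinite(d)))
    return pd.DataFrame(
        rows, columns=["dmr_id", "chrom", "start", "end", "distance", "no_feature_on_chrom"]
    )
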