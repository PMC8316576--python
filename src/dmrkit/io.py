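"""Readers and writers for the on-disk formats.

Formats handled: per-CpG methylation TSV (bedGraph-descended, 6 columns:
chrom, start, end, ratio, meth_count, unmeth_count), BED4/6 annotations
whose name field encodes "category:gene", UCSC chain files, sample-metadata
TSV, and DMR tables (TSV with header, or BED6).  All readers accept gzip
(by .gz suffix).
"""

from __future__ import annotations

import gzip
import logging
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .core import (
    ANNOTATION_CATEGORIES,
    AnnotationSet,
    ChainMap,
    ChainRecord,
    MethylationMatrix,
    validate_metadata,
)
from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

RATIO_TOLERANCE = 0.01  # absolute tolerance when cross-checking the ratio column


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# per-CpG methylation tables


def read_methylation_table(path, sample_id: str) -> MethylationMatrix:
    """Read one sample's per-CpG table into a single-column matrix.

    The ratio column is recomputed from the counts and cross-checked within
    ``RATIO_TOLERANCE``; coverage-0 rows become missing.  Unsorted input is
    sorted with a warning.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ratios: list[float] = []
    covs: list[int] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(
                    f"expected 6 tab-separated columns, got {len(parts)}",
                    path=str(path),
                    line=lineno,
                )
            try:
                chrom = parts[0]
                start = int(parts[1])
                end = int(parts[2])
                ratio = float(parts[3])
                meth = int(parts[4])
                unmeth = int(parts[5])
            except ValueError as exc:
                raise ParseError(f"malformed row ({exc})", path=str(path), line=lineno)
            if end != start + 1:
                raise ParseError(
                    f"CpG rows must be 1 bp intervals (got {start}-{end})",
                    path=str(path),
                    line=lineno,
                )
            if start < 0 or meth < 0 or unmeth < 0:
                raise ParseError("negative coordinate or count", path=str(path), line=lineno)
            cov = meth + unmeth
            if cov > 0:
                expected = meth / cov
                if abs(ratio - expected) > RATIO_TOLERANCE:
                    raise ParseError(
                        f"ratio column {ratio} disagrees with counts "
                        f"{meth}/{cov} = {expected:.4f}",
                        path=str(path),
                        line=lineno,
                    )
                ratios.append(expected)
            else:
                ratios.append(np.nan)
            chroms.append(chrom)
            starts.append(start)
            covs.append(cov)
    chrom_arr = np.asarray(chroms, dtype=object)
    start_arr = np.asarray(starts, dtype=np.int64)
    ratio_arr = np.asarray(ratios, dtype=float)
    cov_arr = np.asarray(covs, dtype=np.int64)
    order = np.lexsort((start_arr, chrom_arr.astype(str)))
    if not np.array_equal(order, np.arange(len(order))):
        log.warning("%s: sites were not sorted; sorting", path)
        chrom_arr, start_arr = chrom_arr[order], start_arr[order]
        ratio_arr, cov_arr = ratio_arr[order], cov_arr[order]
    key = list(zip(chrom_arr.tolist(), start_arr.tolist()))
    if len(set(key)) != len(key):
        raise ValidationError(f"{path}: duplicate CpG positions")
    return MethylationMatrix(
        chroms=chrom_arr,
        starts=start_arr,
        samples=[sample_id],
        ratio=ratio_arr.reshape(-1, 1),
        coverage=cov_arr.reshape(-1, 1),
    )


def merge_samples(matrices: Iterable[MethylationMatrix]) -> MethylationMatrix:
    """Union of sites across single-or-multi-sample matrices.

    Missing entries appear where a sample lacks a site.  Order-independent:
    the output is sorted by (chrom, start) and samples keep first-seen order.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValidationError("merge_samples needs at least one matrix")
    samples: list[str] = []
    for m in matrices:
        for s in m.samples:
            if s in samples:
                raise ValidationError(f"duplicate sample id {s!r}")
            samples.append(s)
    site_set: set[tuple[str, int]] = set()
    for m in matrices:
        site_set.update(zip((str(c) for c in m.chroms), m.starts.tolist()))
    sites = sorted(site_set)
    pos = {site: i for i, site in enumerate(sites)}
    n = len(sites)
    ratio = np.full((n, len(samples)), np.nan)
    coverage = np.zeros((n, len(samples)), dtype=np.int64)
    col = 0
    for m in matrices:
        rows = np.fromiter(
            (pos[(str(c), int(s))] for c, s in zip(m.chroms, m.starts)),
            dtype=np.int64,
            count=m.n_sites,
        )
        ncol = len(m.samples)
        ratio[rows, col : col + ncol] = m.ratio
        coverage[rows, col : col + ncol] = m.coverage
        col += ncol
    return MethylationMatrix(
        chroms=np.array([c for c, _ in sites], dtype=object),
        starts=np.array([s for _, s in sites], dtype=np.int64),
        samples=samples,
        ratio=ratio,
        coverage=coverage,
    )


def write_methylation_table(matrix: MethylationMatrix, sample: str, path) -> None:
    """Write one sample back out in the 6-column format, skipping
    zero-coverage sites (uncovered CpGs are simply absent, as in bedGraph)."""
    j = matrix.sample_index(sample)
    with _open_text(path, "wt") as fh:
        for i in range(matrix.n_sites):
            cov = int(matrix.coverage[i, j])
            if cov == 0:
                continue
            r = matrix.ratio[i, j]
            meth = int(round(r * cov))
            fh.write(
                f"{matrix.chroms[i]}\t{matrix.starts[i]}\t{matrix.starts[i] + 1}\t"
                f"{r:.6f}\t{meth}\t{cov - meth}\n"
            )


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str, "sex": str})
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path) -> AnnotationSet:
    """Read BED4+ annotations whose name field is "category:gene" (gene part
    optional).  Unknown categories map to 'other' with a warning."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError("BED4 requires 4 columns", path=str(path), line=lineno)
            try:
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            except ValueError as exc:
                raise ParseError(f"malformed row ({exc})", path=str(path), line=lineno)
            if start >= end:
                raise ParseError(
                    f"empty or inverted interval {start}-{end}", path=str(path), line=lineno
                )
            category, _, gene = name.partition(":")
            if category not in ANNOTATION_CATEGORIES:
                log.warning(
                    "%s line %d: unknown category %r mapped to 'other'",
                    path,
                    lineno,
                    category,
                )
                category = "other"
            rows.append((chrom, start, end, category, gene or None, name))
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "category", "gene", "name"]
    )
    return AnnotationSet(frame=frame)


def write_annotations(annotations: AnnotationSet, path) -> None:
    with _open_text(path, "wt") as fh:
        for row in annotations.frame.itertuples(index=False):
            gene = row.gene or ""
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.category}:{gene}\n")


# ---------------------------------------------------------------------------
# UCSC chain files


def read_chain(path) -> ChainMap:
    """Parse a UCSC chain file, validating block arithmetic per chain."""
    chains: list[ChainRecord] = []
    current: ChainRecord | None = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                if current is not None:
                    _finish_chain(current)
                    chains.append(current)
                parts = line.split()
                if len(parts) != 13:
                    raise ParseError(
                        "chain header must have 13 fields", path=str(path), line=lineno
                    )
                try:
                    current = ChainRecord(
                        score=float(parts[1]),
                        t_name=parts[2],
                        t_size=int(parts[3]),
                        t_strand=parts[4],
                        t_start=int(parts[5]),
                        t_end=int(parts[6]),
                        q_name=parts[7],
                        q_size=int(parts[8]),
                        q_strand=parts[9],
                        q_start=int(parts[10]),
                        q_end=int(parts[11]),
                        chain_id=parts[12],
                    )
                except ValueError as exc:
                    raise ParseError(f"malformed chain header ({exc})", path=str(path), line=lineno)
            else:
                if current is None:
                    raise ParseError("block line before any chain header", path=str(path), line=lineno)
                fields = line.split()
                try:
                    if len(fields) == 3:
                        current.blocks.append((int(fields[0]), int(fields[1]), int(fields[2])))
                    elif len(fields) == 1:
                        current.blocks.append((int(fields[0]), 0, 0))
                    else:
                        raise ValueError("expected 1 or 3 fields")
                except ValueError as exc:
                    raise ParseError(f"malformed block line ({exc})", path=str(path), line=lineno)
    if current is not None:
        _finish_chain(current)
        chains.append(current)
    return ChainMap(chains=chains)


def _finish_chain(chain: ChainRecord) -> None:
    if not chain.blocks:
        raise ValidationError(f"chain {chain.chain_id} has no alignment blocks")
    chain.validate()


def write_chain(chain_map: ChainMap, path) -> None:
    with _open_text(path, "wt") as fh:
        for c in chain_map.chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} {c.t_strand} {c.t_start} "
                f"{c.t_end} {c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} "
                f"{c.chain_id}\n"
            )
            for size, dt, dq in c.blocks[:-1]:
                fh.write(f"{size}\t{dt}\t{dq}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")


# ---------------------------------------------------------------------------
# DMR tables

# scalar DmrRecord fields serialized to TSV, in column order
_DMR_SCALARS = [
    ("id", str),
    ("chrom", str),
    ("start", int),
    ("end", int),
    ("n_cpgs", int),
    ("width_bp", int),
    ("mean_test", float),
    ("mean_ref", float),
    ("mean_diff", float),
    ("sd_test", float),
    ("sd_ref", float),
    ("p", float),
    ("q", float),
    ("direction", str),
    ("sd_undefined", lambda v: str(v).lower() == "true"),
]


def write_regions(records, path, format: str = "tsv") -> None:
    """Write DMR records as TSV (all fields; lossless round trip) or BED6
    (score = round(1000*|mean diff|) capped at 1000, strand '.')."""
    format = format.lower()
    if format not in ("tsv", "bed"):
        raise ValidationError(f"unknown region format {format!r}")
    records = list(records)
    if format == "bed":
        with _open_text(path, "wt") as fh:
            for r in records:
                score = min(1000, int(round(1000 * abs(r.mean_diff))))
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t{score}\t.\n")
        return
    sample_cols: list[str] = []
    for r in records:
        for s in r.sample_means:
            if s not in sample_cols:
                sample_cols.append(s)
    header = [name for name, _ in _DMR_SCALARS] + [f"mean.{s}" for s in sample_cols]
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            vals = [repr(getattr(r, name)) if typ is float else str(getattr(r, name))
                    for name, typ in _DMR_SCALARS]
            for s in sample_cols:
                v = r.sample_means.get(s, float("nan"))
                vals.append(repr(float(v)))
            fh.write("\t".join(vals) + "\n")


def read_regions(path):
    """Read a TSV written by :func:`write_regions` back into DmrRecord
    objects (lossless for every declared field)."""
    from .caller import DmrRecord  # local import to avoid a cycle

    with _open_text(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            return []
        header = header_line.split("\t")
        sample_cols = [h[len("mean."):] for h in header if h.startswith("mean.")]
        records = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            vals = dict(zip(header, line.split("\t")))
            try:
                kwargs = {}
                for name, typ in _DMR_SCALARS:
                    if name == "width_bp":
                        continue  # derived
                    kwargs[name] = typ(vals[name])
                sample_means = {}
                for s in sample_cols:
                    v = float(vals[f"mean.{s}"])
                    if not np.isnan(v):
                        sample_means[s] = v
                records.append(DmrRecord(sample_means=sample_means, **kwargs))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"malformed DMR row ({exc})", path=str(path), line=lineno)
    return records
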