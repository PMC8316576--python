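"""Core data model: per-CpG methylation matrices, genomic intervals and
interval indexes.

Coordinate convention is 0-based half-open throughout.  A CpG site is a
1 bp interval at the cytosine of the (strand-collapsed) CpG on the plus
strand.  A missing observation (coverage 0) is NaN in the ratio matrix,
never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

ANNOTATION_CATEGORIES = frozenset(
    {"gene_body", "promoter", "tss", "enhancer", "cpg_island", "other"}
)


# ---------------------------------------------------------------------------
# intervals


def overlap_length(s1: int, e1: int, s2: int, e2: int) -> int:
    """Length of the intersection of two half-open intervals (>= 0)."""
    return max(0, min(e1, e2) - max(s1, s2))


def edge_distance(s1: int, e1: int, s2: int, e2: int) -> int:
    """Edge-to-edge distance between two half-open intervals; 0 if they overlap."""
    if overlap_length(s1, e1, s2, e2) > 0:
        return 0
    if e1 <= s2:
        return s2 - e1
    return s1 - e2


class IntervalIndex:
    """Per-chromosome sorted-array index supporting O(log n) overlap and
    nearest-edge-distance queries over half-open intervals."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        self.n = 0
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
            self.n += 1
        self._chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = np.array([s for s, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e in ivs], dtype=np.int64)
            self._chrom[chrom] = {
                "starts": starts,
                "ends": ends,
                "cummax_end": np.maximum.accumulate(ends),
                "sorted_ends": np.sort(ends),
            }

    def __len__(self) -> int:
        return self.n

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        d = self._chrom.get(chrom)
        if d is None:
            return False
        i = int(np.searchsorted(d["starts"], end, side="left"))
        return i > 0 and int(d["cummax_end"][i - 1]) > start

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        d = self._chrom.get(chrom)
        if d is None:
            return 0
        i = int(np.searchsorted(d["starts"], end, side="left"))
        if i == 0:
            return 0
        return int(np.count_nonzero(d["ends"][:i] > start))

    def nearest_distance(self, chrom: str, start: int, end: int) -> float:
        """Edge distance to the nearest interval on the same chromosome;
        0 on overlap, inf when the chromosome holds no interval."""
        d = self._chrom.get(chrom)
        if d is None:
            return float("inf")
        if self.overlaps_any(chrom, start, end):
            return 0.0
        left = float("inf")
        j = int(np.searchsorted(d["sorted_ends"], start, side="right"))
        if j > 0:
            left = float(start - d["sorted_ends"][j - 1])
        right = float("inf")
        k = int(np.searchsorted(d["starts"], end, side="left"))
        if k < len(d["starts"]):
            right = float(d["starts"][k] - end)
        return min(left, right)


def positions_in_intervals(
    positions: np.ndarray, intervals: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Boolean mask of which positions fall inside the union of half-open
    intervals (single chromosome).  Intervals are merged first, so nested or
    overlapping inputs are handled."""
    if len(intervals) == 0:
        return np.zeros(len(positions), dtype=bool)
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    bounds = np.array([b for iv in merged for b in iv], dtype=np.int64)
    idx = np.searchsorted(bounds, positions, side="right")
    return idx % 2 == 1


# ---------------------------------------------------------------------------
# methylation matrix


@dataclass
class MethylationMatrix:
    """Per-CpG methylation ratios and coverages across samples.

    ``ratio`` is (n_sites, n_samples) with NaN where ``coverage`` is 0;
    sites are sorted by (chrom, start) and unique.
    """

    chroms: np.ndarray
    starts: np.ndarray
    samples: list[str]
    ratio: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        n = len(self.starts)
        if self.ratio.shape != (n, len(self.samples)):
            raise ValidationError("ratio matrix shape does not match sites x samples")
        if self.coverage.shape != self.ratio.shape:
            raise ValidationError("coverage matrix shape does not match ratio matrix")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        with np.errstate(invalid="ignore"):
            bad = (~np.isnan(self.ratio)) & ((self.ratio < 0) | (self.ratio > 1))
        if bad.any():
            raise ValidationError("methylation ratios must lie in [0, 1]")
        miss = np.isnan(self.ratio)
        if ((self.coverage == 0) != miss).any():
            raise ValidationError("ratio must be missing iff coverage is 0")

    @property
    def n_sites(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + 1

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise ValidationError(f"unknown sample id {sample!r}") from None

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous slices of the site axis, one per chromosome, in order."""
        out: list[tuple[str, slice]] = []
        n = self.n_sites
        i = 0
        while i < n:
            j = i
            c = self.chroms[i]
            while j < n and self.chroms[j] == c:
                j += 1
            out.append((str(c), slice(i, j)))
            i = j
        return out

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chroms, "start": self.starts, "end": self.ends})


def sort_key(chroms: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Stable ordering by (chrom, start)."""
    return np.lexsort((starts, chroms.astype(str)))


# ---------------------------------------------------------------------------
# sample metadata

METADATA_COLUMNS = ("sample", "group", "age", "sex")


def validate_metadata(meta: pd.DataFrame, samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Check the sample-metadata contract: one row per sample, positive ages
    (log(age) must be finite), sex in {M, F}."""
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise ValidationError(f"metadata is missing column {col!r}")
    if meta["sample"].duplicated().any():
        raise ValidationError("metadata has duplicated sample ids")
    if (meta["age"] <= 0).any():
        raise ValidationError("ages must be > 0")
    if not set(meta["sex"]).issubset({"M", "F"}):
        raise ValidationError("sex must be 'M' or 'F'")
    if samples is not None:
        missing = set(samples) - set(meta["sample"])
        if missing:
            raise ValidationError(f"metadata missing samples: {sorted(missing)}")
    return meta


def group_samples(meta: pd.DataFrame, group: str) -> list[str]:
    sel = meta.loc[meta["group"] == group, "sample"].tolist()
    if not sel:
        raise ValidationError(f"group {group!r} absent from metadata")
    return sel


# ---------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationSet:
    """Categorized genomic intervals with optional gene ids.

    ``frame`` columns: chrom, start, end, category, gene, name.
    """

    frame: pd.DataFrame
    _indexes: dict[str, IntervalIndex] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("chrom", "start", "end", "category"):
            if col not in f.columns:
                raise ValidationError(f"annotation frame is missing column {col!r}")
        if (f["start"] >= f["end"]).any():
            raise ValidationError("annotation intervals must satisfy start < end")
        unknown = set(f["category"]) - ANNOTATION_CATEGORIES
        if unknown:
            raise ValidationError(f"unknown annotation categories: {sorted(unknown)}")
        if "gene" not in f.columns:
            f["gene"] = None
        if "name" not in f.columns:
            f["name"] = [f"feat_{i}" for i in range(len(f))]

    @property
    def categories(self) -> list[str]:
        return sorted(self.frame["category"].unique())

    def category_frame(self, category: str) -> pd.DataFrame:
        return self.frame[self.frame["category"] == category]

    def index_for(self, category: str) -> IntervalIndex:
        if category not in self._indexes:
            sub = self.category_frame(category)
            self._indexes[category] = IntervalIndex(
                zip(sub["chrom"], sub["start"], sub["end"])
            )
        return self._indexes[category]


# ---------------------------------------------------------------------------
# chain maps


@dataclass
class ChainRecord:
    """One UCSC chain: an ordered run of aligned blocks mapping a source
    (``t``) region onto a target (``q``) region."""

    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    # (aligned block size, gap on t after block, gap on q after block);
    # the final block has implicit gaps of 0.
    blocks: list[tuple[int, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        sizes = sum(b[0] for b in self.blocks)
        dts = sum(b[1] for b in self.blocks)
        dqs = sum(b[2] for b in self.blocks)
        if any(b[0] < 0 or b[1] < 0 or b[2] < 0 for b in self.blocks):
            raise ValidationError(f"chain {self.chain_id}: negative block size or gap")
        if self.t_strand not in "+-" or self.q_strand not in "+-":
            raise ValidationError(f"chain {self.chain_id}: strand must be + or -")
        if sizes + dts != self.t_end - self.t_start:
            raise ValidationError(
                f"chain {self.chain_id}: block arithmetic does not match source span"
            )
        if sizes + dqs != self.q_end - self.q_start:
            raise ValidationError(
                f"chain {self.chain_id}: block arithmetic does not match target span"
            )


@dataclass
class ChainMap:
    """Ordered collection of chains, queryable by source chromosome."""

    chains: list[ChainRecord]

    def __post_init__(self) -> None:
        self._by_t: dict[str, list[ChainRecord]] = {}
        for c in self.chains:
            self._by_t.setdefault(c.t_name, []).append(c)

    def __len__(self) -> int:
        return len(self.chains)

    def source_chroms(self) -> set[str]:
        return set(self._by_t)

    def overlapping(self, chrom: str, start: int, end: int) -> list[ChainRecord]:
        """Chains whose source span overlaps the query, best score first."""
        out = [
            c
            for c in self._by_t.get(chrom, [])
            if overlap_length(c.t_start, c.t_end, start, end) > 0
        ]
        out.sort(key=lambda c: (-c.score, c.chain_id))
        return out
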