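"""Chain-file liftover of intervals between genomes and DMR-set
correspondence metrics (direct >= 1 bp overlap and within-k edge
proximity).

Percent denominators deliberately include unmapped intervals: each percent
is over the full source set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import ChainMap, ChainRecord, IntervalIndex, overlap_length
from .errors import ValidationError

log = logging.getLogger(__name__)

DEFAULT_MIN_MAP_RATIO = 0.5
DEFAULT_PROXIMITY_BP = 10_000


@dataclass
class LiftResult:
    source: tuple[str, int, int]
    status: str  # mapped | unmapped | split | low_ratio
    target: tuple[str, int, int] | None
    mapped_fraction: float


@dataclass
class SetComparison:
    n_a: int
    n_b: int
    direct: int
    within_k: int
    unmapped: int
    k: int

    @property
    def direct_percent(self) -> float | None:
        return 100.0 * self.direct / self.n_a if self.n_a else None

    @property
    def within_k_percent(self) -> float | None:
        return 100.0 * self.within_k / self.n_a if self.n_a else None


def _mapped_segments(
    chain: ChainRecord, start: int, end: int
) -> list[tuple[int, int]]:
    """Plus-strand target segments of query bases falling inside this
    chain's aligned blocks (source assumed plus strand)."""
    if chain.t_strand != "+":
        raise ValidationError(f"chain {chain.chain_id}: source strand must be +")
    segments = []
    t = chain.t_start
    q = chain.q_start
    for size, dt, dq in chain.blocks:
        lo = max(start, t)
        hi = min(end, t + size)
        if lo < hi:
            q_lo = q + (lo - t)
            q_hi = q + (hi - t)
            if chain.q_strand == "+":
                segments.append((q_lo, q_hi))
            else:
                segments.append((chain.q_size - q_hi, chain.q_size - q_lo))
        t += size + dt
        q += size + dq
        if t >= end:
            break
    return segments


def _union_length(segments: list[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(segments):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        else:
            total += max(0, e - last_end)
            last_end = max(last_end, e)
    return total


def liftover_interval(
    chain_map: ChainMap,
    chrom: str,
    start: int,
    end: int,
    min_map_ratio: float = DEFAULT_MIN_MAP_RATIO,
) -> LiftResult:
    """Map an interval through the best-scoring overlapping chain.

    Status 'mapped' when the fraction of bases falling in aligned blocks of
    that chain is >= ``min_map_ratio``; 'split' when the best chain alone is
    insufficient but several chains together would reach the ratio;
    'low_ratio' when some bases map but too few; 'unmapped' otherwise.
    Minus-strand chains yield plus-strand target coordinates."""
    if end <= start:
        raise ValidationError("interval must have positive length")
    length = end - start
    chains = chain_map.overlapping(chrom, start, end)
    if not chains:
        return LiftResult((chrom, start, end), "unmapped", None, 0.0)
    best = chains[0]
    segments = _mapped_segments(best, start, end)
    mapped = sum(e - s for s, e in segments)
    frac = mapped / length
    if mapped and frac >= min_map_ratio:
        t_start = min(s for s, _ in segments)
        t_end = max(e for _, e in segments)
        return LiftResult((chrom, start, end), "mapped", (best.q_name, t_start, t_end), frac)
    if len(chains) > 1:
        # would combining chains rescue the interval?  then it is split
        per_chain = []
        for c in chains:
            segs = _mapped_segments(c, start, end)
            if segs:
                t_lo = max(start, c.t_start)
                t_hi = min(end, c.t_end)
                per_chain.append((t_lo, t_hi))
        combined = _union_length(per_chain) / length if per_chain else 0.0
        if combined >= min_map_ratio and len(per_chain) > 1:
            return LiftResult((chrom, start, end), "split", None, frac)
    if mapped:
        return LiftResult((chrom, start, end), "low_ratio", None, frac)
    return LiftResult((chrom, start, end), "unmapped", None, 0.0)


def _as_intervals(records) -> list[tuple[str, int, int]]:
    out = []
    for r in records:
        if isinstance(r, tuple):
            out.append((r[0], int(r[1]), int(r[2])))
        else:
            out.append((r.chrom, r.start, r.end))
    return out


def compare_dmr_sets(
    dmrs_a,
    dmrs_b,
    chain: ChainMap | None = None,
    k: int = DEFAULT_PROXIMITY_BP,
    min_map_ratio: float = DEFAULT_MIN_MAP_RATIO,
) -> tuple[SetComparison, list[LiftResult]]:
    """Correspondence of set A against set B.  With a chain, A is lifted to
    B's genome first; split/low-ratio/unmapped intervals count as unmapped
    but stay in the percent denominators.  Direct = >= 1 bp overlap;
    within-k = edge distance <= k (so within-0 equals direct)."""
    a = _as_intervals(dmrs_a)
    b = _as_intervals(dmrs_b)
    lifts: list[LiftResult] = []
    if chain is not None:
        a_chroms = {c for c, _, _ in a}
        if a and a_chroms.isdisjoint(chain.source_chroms()):
            raise ValidationError(
                "chain source chromosomes are disjoint from set A; genome mismatch?"
            )
        placed = []
        for chrom, s, e in a:
            lr = liftover_interval(chain, chrom, s, e, min_map_ratio)
            lifts.append(lr)
            placed.append(lr.target if lr.status == "mapped" else None)
    else:
        placed = list(a)
        lifts = [LiftResult(iv, "mapped", iv, 1.0) for iv in a]

    idx = IntervalIndex(b)
    direct = within = unmapped = 0
    for tgt in placed:
        if tgt is None:
            unmapped += 1
            continue
        chrom, s, e = tgt
        if idx.overlaps_any(chrom, s, e):
            direct += 1
            within += 1
        elif idx.nearest_distance(chrom, s, e) <= k:
            within += 1
    return (
        SetComparison(n_a=len(a), n_b=len(b), direct=direct, within_k=within, unmapped=unmapped, k=k),
        lifts,
    )


def bidirectional_comparison(
    dmrs_a,
    dmrs_b,
    chain_a2b: ChainMap,
    chain_b2a: ChainMap,
    k: int = DEFAULT_PROXIMITY_BP,
    min_map_ratio: float = DEFAULT_MIN_MAP_RATIO,
) -> tuple[SetComparison, SetComparison]:
    """A->B and B->A comparisons; asymmetry is reported, not reconciled."""
    fwd, _ = compare_dmr_sets(dmrs_a, dmrs_b, chain_a2b, k, min_map_ratio)
    rev, _ = compare_dmr_sets(dmrs_b, dmrs_a, chain_b2a, k, min_map_ratio)
    return fwd, rev
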