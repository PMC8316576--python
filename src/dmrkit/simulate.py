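"""Seeded synthetic-data generator: CpG landscapes with island/background
structure, planted focal hypomethylated regions whose depth scales with a
severity tier, beta-binomial per-CpG counts at configurable coverage,
block-shuffled genome pairs with valid chain files, and clustered
single-cell count matrices with planted per-cluster DEGs.

Ground truth is emitted alongside the data and never consumed by the
pipeline.  All sampling derives from the single config seed; identical
config + seed gives identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnnotationSet, ChainMap, ChainRecord, MethylationMatrix
from .errors import ValidationError
from .scrna import ExpressionMatrix

log = logging.getLogger(__name__)

TIERS = ("control", "severe", "mild", "haplo", "knockout")


@dataclass
class GroupSpec:
    name: str
    n: int
    tier: str = "control"

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValidationError(f"unknown tier {self.tier!r}")
        if self.n < 1:
            raise ValidationError("group size must be >= 1")


def _default_groups() -> list[GroupSpec]:
    # mouse-like cohort: 6 mutants vs 10 controls
    return [GroupSpec("control", 10, "control"), GroupSpec("mutant", 6, "severe")]


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome / CpG landscape
    n_chroms: int = 3
    chrom_length: int = 2_000_000
    background_spacing: int = 120
    island_spacing: int = 20
    n_islands_per_chrom: int = 12
    island_width: int = 1500
    baseline_island: float = 0.10
    baseline_background: float = 0.90
    baseline_sd: float = 0.03
    # planted regions
    n_regions: int = 50
    region_width_median: float = 650.0
    region_width_log_sd: float = 0.35
    min_region_cpgs: int = 12
    max_region_cpg_gap: int = 250  # planted regions sit on CpG-dense spans
    # per-tier (mean effect, between-region SD); hypo by default
    tier_effect_mean: dict = field(
        default_factory=lambda: {
            "severe": -0.35, "mild": -0.12, "haplo": -0.03, "knockout": -0.55,
        }
    )
    tier_effect_sd: dict = field(
        default_factory=lambda: {
            "severe": 0.08, "mild": 0.10, "haplo": 0.01, "knockout": 0.10,
        }
    )
    knockout_extra_regions: int = 30
    hyper_mode: bool = False
    noisy_region_fraction: float = 0.05
    noisy_region_sd: float = 0.2
    # read-count model
    jitter_concentration: float = 200.0
    coverage_mean: float = 18.0
    coverage_dispersion: float = 3.0
    # cohort
    groups: list = field(default_factory=_default_groups)
    age_min: float = 2.0
    age_max: float = 43.0
    n_age_effect_regions: int = 0
    age_effect_coef: float = 0.0
    # annotations
    gene_body_fraction: float = 0.6
    n_extra_gene_bodies: int = 40
    n_other_features: int = 20
    # chain shuffle
    chain_block_size: int = 100_000
    chain_invert_fraction: float = 0.1
    chain_delete_fraction: float = 0.0
    chain_max_gap: int = 5_000
    # scRNA
    n_clusters: int = 6
    cells_per_cluster: int = 100
    n_genes: int = 500  # must comfortably exceed the 250-expressed-genes QC bar
    n_markers_per_cluster: int = 10
    marker_boost: float = 5.0
    n_planted_degs_per_cluster: int = 5
    deg_fold_change: float = 4.0
    mito_gene_fraction: float = 0.05
    base_expression_mean: float = 2.0
    nb_dispersion: float = 2.0
    qc_violation_fraction: float = 0.02
    cluster_fractions_ref: list | None = None
    cluster_fractions_test: list | None = None

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class Genome:
    chroms: np.ndarray  # per-site chromosome
    starts: np.ndarray  # per-site position
    baseline: np.ndarray  # per-site baseline methylation
    annotations: AnnotationSet
    regions: pd.DataFrame  # planted-region truth
    chrom_lengths: dict[str, int]

    @property
    def n_sites(self) -> int:
        return len(self.starts)


# ---------------------------------------------------------------------------
# genome + CpG landscape


def _positions(rng, length, mean_spacing, offset=0) -> np.ndarray:
    n_est = int(length / mean_spacing * 1.6) + 10
    gaps = rng.geometric(1.0 / mean_spacing, size=n_est)
    pos = offset + np.cumsum(gaps)
    return pos[pos < offset + length]


def simulate_genome_cpgs(config: SimulationConfig, rng=None) -> Genome:
    """CpG positions (dense islands on a sparser background), per-site
    baseline methylation (islands low, background high), planted regions
    with per-tier effects, and a matching annotation set in which a
    configurable fraction of planted regions fall inside gene bodies."""
    rng = rng or config.rng()
    if config.n_islands_per_chrom * config.island_width * 3 > config.chrom_length:
        raise ValidationError("chromosome too short for the requested islands")

    all_chroms, all_starts, all_baseline = [], [], []
    islands_by_chrom: dict[str, list[tuple[int, int]]] = {}
    chrom_lengths = {}
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        L = config.chrom_length
        chrom_lengths[chrom] = L
        islands: list[tuple[int, int]] = []
        attempts = 0
        while len(islands) < config.n_islands_per_chrom and attempts < 10_000:
            attempts += 1
            s = int(rng.integers(0, L - config.island_width))
            iv = (s, s + config.island_width)
            if all(e <= s or iv[1] <= b for b, e in islands):
                islands.append(iv)
        islands.sort()
        islands_by_chrom[chrom] = islands

        bg = _positions(rng, L, config.background_spacing)
        isl = [
            _positions(rng, e - b, config.island_spacing, offset=b) for b, e in islands
        ]
        pos = np.unique(np.concatenate([bg] + isl)) if isl else np.unique(bg)
        in_island = np.zeros(len(pos), dtype=bool)
        for b, e in islands:
            in_island |= (pos >= b) & (pos < e)
        base = np.where(
            in_island,
            rng.normal(config.baseline_island, config.baseline_sd, len(pos)),
            rng.normal(config.baseline_background, config.baseline_sd, len(pos)),
        )
        base = np.clip(base, 0.02, 0.98)
        all_chroms.append(np.full(len(pos), chrom, dtype=object))
        all_starts.append(pos.astype(np.int64))
        all_baseline.append(base)

    chroms = np.concatenate(all_chroms)
    starts = np.concatenate(all_starts)
    baseline = np.concatenate(all_baseline)

    regions = _plant_regions(config, rng, chroms, starts, islands_by_chrom, chrom_lengths)
    annotations = _build_annotations(config, rng, regions, islands_by_chrom, chrom_lengths)
    return Genome(
        chroms=chroms,
        starts=starts,
        baseline=baseline,
        annotations=annotations,
        regions=regions,
        chrom_lengths=chrom_lengths,
    )


def _plant_regions(config, rng, chroms, starts, islands_by_chrom, chrom_lengths):
    chrom_names = list(chrom_lengths)
    site_pos = {c: starts[chroms == c] for c in chrom_names}
    rows = []
    n_total = config.n_regions + config.knockout_extra_regions
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    sign = 1.0 if config.hyper_mode else -1.0
    for i in range(n_total):
        ko_only = i >= config.n_regions
        ok = False
        for _ in range(2_000):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            width = int(
                np.exp(
                    np.log(config.region_width_median)
                    + rng.normal(0.0, config.region_width_log_sd)
                )
            )
            width = max(width, 150)
            L = chrom_lengths[chrom]
            s = int(rng.integers(0, max(1, L - width)))
            e = s + width
            if any(e > b and s < ee for b, ee in islands_by_chrom[chrom]):
                continue
            if any(e > b and s < ee for b, ee in placed[chrom]):
                continue
            pos = site_pos[chrom]
            lo, hi = np.searchsorted(pos, s), np.searchsorted(pos, e)
            n_cpg = int(hi - lo)
            if n_cpg < config.min_region_cpgs:
                continue
            inner = pos[lo:hi]
            if np.diff(inner).max(initial=0) > config.max_region_cpg_gap:
                continue
            if inner[0] - s > config.max_region_cpg_gap or e - inner[-1] > config.max_region_cpg_gap:
                continue
            ok = True
            break
        if not ok:
            raise ValidationError("could not place planted regions; genome too crowded")
        placed[chrom].append((s, e))
        effects = {}
        for tier in ("severe", "mild", "haplo", "knockout"):
            if ko_only and tier != "knockout":
                effects[tier] = 0.0
                continue
            mu = sign * abs(config.tier_effect_mean[tier])
            eff = rng.normal(mu, config.tier_effect_sd[tier])
            effects[tier] = sign * min(abs(eff), 0.85) if eff * sign > 0 else sign * 0.01
        rows.append(
            {
                "region_id": f"region_{i + 1}",
                "chrom": chrom,
                "start": s,
                "end": e,
                "n_cpgs": n_cpg,
                "ko_only": ko_only,
                "noisy": bool(rng.random() < config.noisy_region_fraction),
                **{f"effect_{t}": effects[t] for t in ("severe", "mild", "haplo", "knockout")},
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def _build_annotations(config, rng, regions, islands_by_chrom, chrom_lengths):
    rows = []
    gene_counter = 0
    main = regions[~regions["ko_only"]]
    n_in_gene = int(round(config.gene_body_fraction * len(main)))
    for _, r in main.head(n_in_gene).iterrows():
        gene_counter += 1
        pad_l = int(rng.integers(500, 2000))
        pad_r = int(rng.integers(500, 2000))
        s = max(0, r["start"] - pad_l)
        e = min(chrom_lengths[r["chrom"]], r["end"] + pad_r)
        gene = f"GENE{gene_counter}"
        rows.append((r["chrom"], s, e, "gene_body", gene, f"gene_body:{gene}"))
        rows.append((r["chrom"], max(0, s - 2000), s, "promoter", gene, f"promoter:{gene}"))
        rows.append((r["chrom"], max(0, s - 200), s + 200, "tss", gene, f"tss:{gene}"))
    chrom_names = list(chrom_lengths)
    for _ in range(config.n_extra_gene_bodies):
        gene_counter += 1
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        w = int(rng.integers(2_000, 20_000))
        s = int(rng.integers(0, chrom_lengths[chrom] - w))
        gene = f"GENE{gene_counter}"
        rows.append((chrom, s, s + w, "gene_body", gene, f"gene_body:{gene}"))
        rows.append((chrom, max(0, s - 2000), s, "promoter", gene, f"promoter:{gene}"))
        rows.append((chrom, max(0, s - 200), s + 200, "tss", gene, f"tss:{gene}"))
    for j in range(config.n_other_features):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        w = int(rng.integers(500, 3_000))
        s = int(rng.integers(0, chrom_lengths[chrom] - w))
        rows.append((chrom, s, s + w, "enhancer", None, f"enhancer:enh{j + 1}"))
    for chrom, islands in islands_by_chrom.items():
        for j, (b, e) in enumerate(islands):
            rows.append((chrom, b, e, "cpg_island", None, f"cpg_island:cgi_{chrom}_{j + 1}"))
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "category", "gene", "name"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    return AnnotationSet(frame=frame)


# ---------------------------------------------------------------------------
# methylation cohorts


def _site_mask(genome: Genome, sub: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(genome.n_sites, dtype=bool)
    for _, r in sub.iterrows():
        mask |= (
            (genome.chroms == r["chrom"])
            & (genome.starts >= r["start"])
            & (genome.starts < r["end"])
        )
    return mask


def tier_effect_vector(genome: Genome, tier: str) -> np.ndarray:
    """Per-site additive effect for a severity tier."""
    eff = np.zeros(genome.n_sites)
    if tier == "control":
        return eff
    col = f"effect_{tier}"
    for _, r in genome.regions.iterrows():
        if r[col] == 0.0:
            continue
        sel = (
            (genome.chroms == r["chrom"])
            & (genome.starts >= r["start"])
            & (genome.starts < r["end"])
        )
        eff[sel] = r[col]
    return eff


def simulate_methylation_samples(
    config: SimulationConfig, genome: Genome, rng=None
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Beta-binomial per-CpG counts for every sample of every group in the
    cohort design.  True methylation = clip(baseline + tier effect +
    age effect, 0, 1) with per-sample beta jitter; coverage is negative
    binomial around ``coverage_mean``; zero-coverage sites are missing."""
    rng = rng or config.rng()
    effect_by_tier = {g.tier: None for g in config.groups}
    for tier in effect_by_tier:
        effect_by_tier[tier] = tier_effect_vector(genome, tier)
    noisy_mask = _site_mask(genome, genome.regions[genome.regions["noisy"]])

    age_mask = np.zeros(genome.n_sites, dtype=bool)
    if config.n_age_effect_regions > 0:
        age_regions = genome.regions[~genome.regions["ko_only"]].head(
            config.n_age_effect_regions
        )
        age_mask = _site_mask(genome, age_regions)

    disp = config.coverage_dispersion
    p_nb = disp / (disp + config.coverage_mean)

    samples, ratios, covs, meta_rows = [], [], [], []
    sexes = ["M", "F"]
    si = 0
    for spec in config.groups:
        for i in range(spec.n):
            name = f"{spec.name}_{i + 1}"
            age = float(np.exp(rng.uniform(np.log(config.age_min), np.log(config.age_max))))
            sex = sexes[si % 2]
            si += 1
            true_m = genome.baseline + effect_by_tier[spec.tier]
            if config.age_effect_coef != 0.0:
                true_m = true_m + np.where(age_mask, config.age_effect_coef * np.log(age), 0.0)
            if spec.tier != "control" and noisy_mask.any():
                true_m = true_m + np.where(
                    noisy_mask, rng.normal(0.0, config.noisy_region_sd), 0.0
                )
            true_m = np.clip(true_m, 1e-3, 1 - 1e-3)
            c = config.jitter_concentration
            m_s = rng.beta(true_m * c, (1 - true_m) * c)
            m_s = np.clip(m_s, 0.0, 1.0)
            cov = rng.negative_binomial(disp, p_nb, size=genome.n_sites)
            meth = rng.binomial(cov, m_s)
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(cov > 0, meth / np.maximum(cov, 1), np.nan)
            samples.append(name)
            ratios.append(ratio)
            covs.append(cov)
            meta_rows.append((name, spec.name, age, sex))
    matrix = MethylationMatrix(
        chroms=genome.chroms,
        starts=genome.starts,
        samples=samples,
        ratio=np.column_stack(ratios),
        coverage=np.column_stack(covs).astype(np.int64),
    )
    metadata = pd.DataFrame(meta_rows, columns=["sample", "group", "age", "sex"])
    return matrix, metadata


def simulate_cohort(config: SimulationConfig):
    """Convenience: genome + methylation cohort from one seeded stream.
    Returns (genome, matrix, metadata)."""
    rng = config.rng()
    genome = simulate_genome_cpgs(config, rng)
    matrix, metadata = simulate_methylation_samples(config, genome, rng)
    return genome, matrix, metadata


# ---------------------------------------------------------------------------
# chain pairs


@dataclass
class ChainPair:
    forward: ChainMap  # source -> target
    reverse: ChainMap  # target -> source
    truth: pd.DataFrame  # per-block correspondence incl. deletions
    target_sizes: dict[str, int]


def simulate_chain_pair(config: SimulationConfig, genome: Genome, rng=None) -> ChainPair:
    """Partition each source chromosome into fixed-size blocks, delete and
    invert configurable fractions, permute the survivors onto a target
    chromosome with random gaps, and emit valid chain files both ways plus
    a per-block truth table."""
    rng = rng or config.rng()
    fwd: list[ChainRecord] = []
    rev: list[ChainRecord] = []
    truth_rows = []
    target_sizes = {}
    cid = 0
    for chrom, L in genome.chrom_lengths.items():
        q_name = f"{chrom}_q"
        bounds = list(range(0, L, config.chain_block_size)) + [L]
        blocks = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
        deleted = rng.random(len(blocks)) < config.chain_delete_fraction
        inverted = rng.random(len(blocks)) < config.chain_invert_fraction
        surviving = [i for i in range(len(blocks)) if not deleted[i]]
        order = rng.permutation(len(surviving))
        cursor = 0
        placement: dict[int, tuple[int, int]] = {}
        for k in order:
            i = surviving[k]
            s, e = blocks[i]
            gap = int(rng.integers(0, config.chain_max_gap))
            placement[i] = (cursor + gap, cursor + gap + (e - s))
            cursor = cursor + gap + (e - s)
        q_size = cursor + 10_000
        target_sizes[q_name] = q_size
        for i, (s, e) in enumerate(blocks):
            if deleted[i]:
                truth_rows.append((chrom, s, e, None, None, None, None, True))
                continue
            qs, qe = placement[i]
            strand = "-" if inverted[i] else "+"
            size = e - s
            cid += 1
            if strand == "+":
                q_start, q_end = qs, qe
            else:  # minus-strand chain coordinates count from the far end
                q_start, q_end = q_size - qe, q_size - qs
            fwd.append(
                ChainRecord(
                    score=float(size), t_name=chrom, t_size=L, t_strand="+",
                    t_start=s, t_end=e, q_name=q_name, q_size=q_size,
                    q_strand=strand, q_start=q_start, q_end=q_end,
                    chain_id=str(cid), blocks=[(size, 0, 0)],
                )
            )
            if strand == "+":
                r_qstart, r_qend = s, e
            else:
                r_qstart, r_qend = L - e, L - s
            rev.append(
                ChainRecord(
                    score=float(size), t_name=q_name, t_size=q_size, t_strand="+",
                    t_start=qs, t_end=qe, q_name=chrom, q_size=L,
                    q_strand=strand, q_start=r_qstart, q_end=r_qend,
                    chain_id=f"r{cid}", blocks=[(size, 0, 0)],
                )
            )
            truth_rows.append((chrom, s, e, q_name, qs, qe, strand, False))
    for c in fwd + rev:
        c.validate()
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "src_chrom", "src_start", "src_end",
            "dst_chrom", "dst_start", "dst_end", "strand", "deleted",
        ],
    )
    return ChainPair(
        forward=ChainMap(chains=fwd),
        reverse=ChainMap(chains=rev),
        truth=truth,
        target_sizes=target_sizes,
    )


def truth_map_interval(truth: pd.DataFrame, chrom: str, start: int, end: int):
    """Ground-truth target interval for an interval fully contained in one
    surviving block; None when the block was deleted or the interval spans
    block boundaries."""
    sub = truth[
        (truth["src_chrom"] == chrom)
        & (truth["src_start"] <= start)
        & (truth["src_end"] >= end)
    ]
    if len(sub) != 1:
        return None
    r = sub.iloc[0]
    if r["deleted"]:
        return None
    if r["strand"] == "+":
        off = start - r["src_start"]
        return (r["dst_chrom"], int(r["dst_start"] + off), int(r["dst_start"] + off + (end - start)))
    off = r["src_end"] - end
    return (r["dst_chrom"], int(r["dst_start"] + off), int(r["dst_start"] + off + (end - start)))


# ---------------------------------------------------------------------------
# scRNA


@dataclass
class ScrnaBundle:
    matrix: ExpressionMatrix
    reference: pd.DataFrame  # lineage x gene mean profiles
    truth_degs: pd.DataFrame  # cluster, gene, fold_change, direction


def simulate_scrna(config: SimulationConfig, rng=None) -> ScrnaBundle:
    """Clustered count matrices for a two-sample (control vs test genotype)
    design with marker blocks per cluster, planted per-cluster DEGs, a
    mitochondrial gene block, and a small fraction of deliberate QC
    violators.  Reference profiles are per-cluster mean expression vectors."""
    rng = rng or config.rng()
    n_mito = max(1, int(round(config.mito_gene_fraction * config.n_genes)))
    genes = [f"MT-{i + 1}" for i in range(n_mito)] + [
        f"GENE{i + 1}" for i in range(config.n_genes - n_mito)
    ]
    mito = np.array([g.startswith("MT-") for g in genes])
    base = rng.lognormal(np.log(config.base_expression_mean), 1.0, config.n_genes)
    # mito block sized so the typical cell sits near 3-4% mito with a ~2%
    # tail beyond the 10% QC bound once the per-cell factor is applied
    base[mito] = config.base_expression_mean

    clusters = [f"c{i + 1}" for i in range(config.n_clusters)]
    non_mito_idx = np.flatnonzero(~mito)
    marker_sets = {}
    deg_sets = {}
    cursor = 0
    for ci, cl in enumerate(clusters):
        marker_sets[cl] = non_mito_idx[cursor : cursor + config.n_markers_per_cluster]
        cursor += config.n_markers_per_cluster
    # planted DEGs drawn from the remaining well-expressed non-marker genes
    remaining = non_mito_idx[cursor:]
    well = remaining[base[remaining] >= np.median(base[remaining])]
    for cl in clusters:
        take = rng.choice(well, size=min(config.n_planted_degs_per_cluster, len(well)), replace=False)
        deg_sets[cl] = np.sort(take)

    frac_ref = config.cluster_fractions_ref or [1.0 / config.n_clusters] * config.n_clusters
    frac_test = config.cluster_fractions_test or frac_ref
    n_per_sample = config.cells_per_cluster * config.n_clusters

    counts_rows, meta_rows, barcodes = [], [], []
    disp = config.nb_dispersion
    truth_rows = []
    for cl in clusters:
        for g in deg_sets[cl]:
            truth_rows.append((cl, genes[g], config.deg_fold_change,
                               "up" if config.deg_fold_change > 1 else "down"))
    for sample, group, fracs in (
        ("ctrl", "control", frac_ref),
        ("case", "mutant", frac_test),
    ):
        n_cells_by_cluster = np.maximum(
            1, np.round(np.asarray(fracs) * n_per_sample).astype(int)
        )
        for cl, n_cells in zip(clusters, n_cells_by_cluster):
            mu = base.copy()
            mu[marker_sets[cl]] *= config.marker_boost
            if group == "mutant":
                mu[deg_sets[cl]] *= config.deg_fold_change
            p_nb = disp / (disp + mu)
            block = rng.negative_binomial(disp, p_nb, size=(n_cells, config.n_genes))
            # per-cell mito inflation so a small tail exceeds the QC bound
            mito_factor = rng.lognormal(0.0, 0.6, size=n_cells)
            block = block.astype(float)
            block[:, mito] *= mito_factor[:, None]
            block = np.floor(block).astype(np.int64)
            counts_rows.append(block)
            for i in range(n_cells):
                barcodes.append(f"{sample}-{cl}-{i + 1}")
                meta_rows.append((sample, group, cl))
    counts = np.vstack(counts_rows)
    # deliberate QC violators: thin a random small fraction of cells hard
    n_cells_total = counts.shape[0]
    n_bad = int(round(config.qc_violation_fraction * n_cells_total))
    if n_bad:
        bad = rng.choice(n_cells_total, size=n_bad, replace=False)
        counts[bad] = rng.binomial(counts[bad], 0.05)
    cell_meta = pd.DataFrame(meta_rows, columns=["sample", "group", "cluster"])
    matrix = ExpressionMatrix(
        counts=counts, genes=genes, barcodes=barcodes, cell_meta=cell_meta, mito=mito
    )
    # reference profiles: per-cluster mean of depth-normalized log expression
    totals = np.maximum(counts.sum(axis=1, dtype=float), 1.0)
    norm = np.log1p(counts * (10_000.0 / totals)[:, None])
    ref_rows = {}
    cl_arr = cell_meta["cluster"].to_numpy()
    for cl in clusters:
        ref_rows[f"lin_{cl}"] = norm[cl_arr == cl].mean(axis=0)
    reference = pd.DataFrame(ref_rows, index=genes).T
    truth_degs = pd.DataFrame(
        truth_rows, columns=["cluster", "gene", "fold_change", "direction"]
    )
    return ScrnaBundle(matrix=matrix, reference=reference, truth_degs=truth_degs)


# ---------------------------------------------------------------------------
# on-disk bundle


def write_cohort(config: SimulationConfig, out_dir) -> dict:
    """Generate and write the full synthetic bundle: per-sample methylation
    tables, metadata, annotations BED, chain files, scRNA matrix bundle,
    truth TSVs, and a manifest echoing the seed and config."""
    from . import io as dio
    from scipy.io import mmwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    genome = simulate_genome_cpgs(config, rng)
    matrix, metadata = simulate_methylation_samples(config, genome, rng)
    chain_pair = simulate_chain_pair(config, genome, rng)
    scrna = simulate_scrna(config, rng)

    meth_dir = out / "meth"
    meth_dir.mkdir(exist_ok=True)
    for s in matrix.samples:
        dio.write_methylation_table(matrix, s, meth_dir / f"{s}.tsv")
    dio.write_metadata(metadata, out / "metadata.tsv")
    dio.write_annotations(genome.annotations, out / "annotations.bed")
    dio.write_chain(chain_pair.forward, out / "forward.chain")
    dio.write_chain(chain_pair.reverse, out / "reverse.chain")

    sc_dir = out / "scrna"
    sc_dir.mkdir(exist_ok=True)
    from scipy import sparse as sp

    mmwrite(str(sc_dir / "matrix.mtx"), sp.csr_matrix(scrna.matrix.counts.T))
    (sc_dir / "features.tsv").write_text("\n".join(scrna.matrix.genes) + "\n")
    (sc_dir / "barcodes.tsv").write_text("\n".join(scrna.matrix.barcodes) + "\n")
    cells = scrna.matrix.cell_meta.copy()
    cells.insert(0, "barcode", scrna.matrix.barcodes)
    cells.to_csv(sc_dir / "cells.tsv", sep="\t", index=False)
    scrna.reference.to_csv(sc_dir / "reference.tsv", sep="\t")

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    genome.regions.to_csv(truth_dir / "regions.tsv", sep="\t", index=False)
    chain_pair.truth.to_csv(truth_dir / "chain_blocks.tsv", sep="\t", index=False)
    scrna.truth_degs.to_csv(truth_dir / "degs.tsv", sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if not callable(v)
        },
        "n_sites": int(genome.n_sites),
        "n_samples": len(matrix.samples),
        "n_cells": int(scrna.matrix.n_cells),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
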