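"""Synthetic cohorts with known Ising ground truth.

Generates a toy genome (CpG map, genes, CpG islands, PRC2-target promoters,
LOCK heterochromatin domains with embedded hypomethylated blocks), designs
group-structured landscapes encoding an aging/rejuvenation effect pattern,
and simulates read-level methylation data exactly from those landscapes:

* genome-wide mild hypomethylation in the aged groups,
* strong hypomethylation confined to block intervals inside LOCKs,
* PRC2-target promoters gaining methylation *and* entropy with age, with the
  treated group pulled back toward the young landscape at those promoters.

Every quantity the downstream pipeline estimates is therefore available
exactly from the generating parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _ising
from .genome_io import (
    GENE_COLUMNS,
    AnnotationSet,
    GenomePartition,
    ReadMatrix,
    intervals_overlap_mask,
    partition_genome,
)
from .landscape import IsingParameters

logger = logging.getLogger(__name__)

GROUPS = ("young", "old", "treated")
DEFAULT_GROUP_SIZES = {"young": 3, "old": 4, "treated": 5}


@dataclass(frozen=True)
class ToyGenomeConfig:
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    mean_cpg_spacing: int = 100
    n_genes: int = 2000
    island_fraction_of_promoters: float = 0.7
    prc2_target_fraction: float = 0.08
    lock_intervals: tuple[tuple[str, int, int], ...] | None = None
    seed: int = 0
    gene_length_range: tuple[int, int] = (2500, 4000)
    min_gene_gap: int = 200

    def __post_init__(self):
        if self.chrom_length < 3000:
            raise ValueError("chrom_length must be >= 3000")
        if self.mean_cpg_spacing < 2:
            raise ValueError("mean_cpg_spacing must be >= 2")
        for f in (self.island_fraction_of_promoters, self.prc2_target_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.lock_intervals is not None:
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for chrom, s, e in self.lock_intervals:
                if not 0 <= s < e <= self.chrom_length:
                    raise ValueError(f"LOCK interval out of bounds: {chrom}:{s}-{e}")
                by_chrom.setdefault(chrom, []).append((s, e))
            for ivs in by_chrom.values():
                ivs.sort()
                for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                    if s2 < e1:
                        raise ValueError("LOCK intervals must not overlap")

    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def default_locks(self) -> list[tuple[str, int, int]]:
        # two large domains per chromosome at fixed relative positions
        out = []
        for chrom in self.chromosomes():
            L = self.chrom_length
            out.append((chrom, int(0.10 * L), int(0.20 * L)))
            out.append((chrom, int(0.60 * L), int(0.68 * L)))
        return out


@dataclass(frozen=True)
class EffectDesign:
    """Ground-truth parameter offsets per group and region class.

    The aged state gets a mild genome-wide field decrease
    (``global_alpha_shift``), a strong field decrease inside hypomethylated
    block intervals (``lock_alpha_shift``), and, at PRC2-target promoter
    windows, a field increase (``prc2_alpha_shift``) on top of a shrinkage of
    all baseline parameters toward 0 (``prc2_disorder_shift``, raising
    configuration entropy).  The treated group equals the aged state except
    at PRC2-target windows, where its parameters are pulled a fraction
    ``treated_reversal_fraction`` of the way back toward the young state.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    global_alpha_shift: dict[str, float] = field(
        default_factory=lambda: {"young": 0.0, "old": -0.25, "treated": -0.25}
    )
    prc2_alpha_shift: float = 0.55
    prc2_disorder_shift: float = 0.5
    lock_alpha_shift: float = -0.9
    treated_reversal_fraction: float = 0.8

    def __post_init__(self):
        vals = [self.prc2_alpha_shift, self.prc2_disorder_shift, self.lock_alpha_shift]
        vals += list(self.global_alpha_shift.values())
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("effect offsets must be finite")
        if not 0.0 <= self.treated_reversal_fraction <= 1.0:
            raise ValueError("treated_reversal_fraction must lie in [0, 1]")

    def sample_ids(self) -> dict[str, list[str]]:
        return {
            g: [f"{g}_{i + 1}" for i in range(self.group_sizes[g])]
            for g in GROUPS
            if g in self.group_sizes
        }


def null_effects(group_sizes: dict[str, int] | None = None) -> EffectDesign:
    """An EffectDesign with every offset zero: all groups share the baseline
    landscape (used for null-calibration studies)."""
    return EffectDesign(
        group_sizes=group_sizes or dict(DEFAULT_GROUP_SIZES),
        global_alpha_shift={"young": 0.0, "old": 0.0, "treated": 0.0},
        prc2_alpha_shift=0.0,
        prc2_disorder_shift=0.0,
        lock_alpha_shift=0.0,
        treated_reversal_fraction=0.0,
    )


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------


def make_toy_genome(config: ToyGenomeConfig) -> AnnotationSet:
    """Build the toy genome annotation: CpG map with geometric inter-CpG
    spacing, non-overlapping stranded genes, CpG islands for a fraction of
    promoters, PRC2-target promoters chosen among island promoters outside
    LOCKs, LOCK domains, and hypomethylated block intervals inside LOCKs.

    Deterministic function of ``config`` (including its seed)."""
    rng = np.random.default_rng(config.seed)
    chroms = config.chromosomes()
    chrom_sizes = {c: config.chrom_length for c in chroms}

    # CpG map: geometric gaps with the requested mean, minimum dyad gap 2
    cpg_positions: dict[str, np.ndarray] = {}
    for chrom in chroms:
        n_draw = int(config.chrom_length / config.mean_cpg_spacing * 1.3) + 10
        gaps = rng.geometric(1.0 / config.mean_cpg_spacing, size=n_draw)
        gaps = np.maximum(gaps, 2)
        pos = np.cumsum(gaps)
        cpg_positions[chrom] = pos[pos < config.chrom_length].astype(np.int64)

    # genes: sequential placement with random gaps
    lo, hi = config.gene_length_range
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    rows = []
    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n_here)
        slack = config.chrom_length - int(lengths.sum()) - config.min_gene_gap * (n_here + 1)
        if slack < 0:
            raise ValueError(
                f"cannot place {n_here} genes of {lo}-{hi} bp on a "
                f"{config.chrom_length} bp chromosome"
            )
        shares = rng.exponential(size=n_here + 1)
        gaps = config.min_gene_gap + slack * shares / shares.sum()
        cursor = 0.0
        for i in range(n_here):
            cursor += gaps[i]
            start = int(cursor)
            end = start + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            rows.append((f"gene_{gid:05d}", chrom, start, end, strand))
            cursor = end
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)

    locks = config.lock_intervals
    if locks is None:
        locks = config.default_locks()
    locks_df = pd.DataFrame(locks, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )

    # hypomethylated blocks: several large subintervals confined to each LOCK
    block_rows = []
    for rec in locks_df.itertuples(index=False):
        w = rec.end - rec.start
        for f0, f1 in ((0.02, 0.14), (0.20, 0.35), (0.45, 0.61), (0.70, 0.92)):
            j0 = rec.start + int(f0 * w)
            j1 = rec.start + int(f1 * w)
            if j1 - j0 >= 3000:
                block_rows.append((rec.chrom, j0, j1))
    blocks_df = pd.DataFrame(block_rows, columns=["chrom", "start", "end"])

    # CpG islands at a fraction of promoters (interval around the TSS)
    n_island = int(round(config.island_fraction_of_promoters * len(genes)))
    island_gene_idx = (
        rng.permutation(len(genes))[:n_island] if len(genes) else np.array([], dtype=int)
    )
    island_rows = []
    for i in island_gene_idx:
        rec = genes.iloc[i]
        tss = rec.start if rec.strand == "+" else rec.end
        r1, r2 = rng.integers(300, 601, size=2)
        island_rows.append(
            (rec.chrom, max(0, tss - int(r1)), min(config.chrom_length, tss + int(r2)), rec.gene_id)
        )
    islands_df = pd.DataFrame(
        island_rows, columns=["chrom", "start", "end", "name"]
    ).sort_values(["chrom", "start"], ignore_index=True)

    # PRC2 targets: island-promoter genes outside LOCKs
    prc2_rows: list = []
    n_prc2 = int(round(config.prc2_target_fraction * len(genes)))
    if n_prc2 > 0:
        island_genes = genes.iloc[np.sort(island_gene_idx)].reset_index(drop=True)
        in_lock = intervals_overlap_mask(island_genes[["chrom", "start", "end"]], locks_df)
        candidates = island_genes[~in_lock].reset_index(drop=True)
        if len(candidates) < n_prc2:
            raise ValueError("not enough island promoters outside LOCKs for PRC2 targets")
        chosen = candidates.iloc[np.sort(rng.permutation(len(candidates))[:n_prc2])]
        for rec in chosen.itertuples(index=False):
            tss = rec.start if rec.strand == "+" else rec.end
            prc2_rows.append(
                (rec.chrom, max(0, tss - 2000), min(config.chrom_length, tss + 2000), rec.gene_id)
            )
    prc2_df = pd.DataFrame(prc2_rows, columns=["chrom", "start", "end", "name"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )

    return AnnotationSet(
        chrom_sizes=chrom_sizes,
        cpg_positions=cpg_positions,
        genes=genes,
        region_sets={
            "cpg_islands": islands_df,
            "prc2_targets": prc2_df,
            "locks": locks_df,
            "blocks": blocks_df,
        },
    )


# ---------------------------------------------------------------------------
# Landscape design
# ---------------------------------------------------------------------------


@dataclass
class LandscapeDesign:
    annotation: AnnotationSet
    partition: GenomePartition
    params: dict[str, dict[int, IsingParameters]]  # group -> window index -> params
    window_classes: pd.DataFrame  # window_index, is_island, is_prc2, is_block

    def groups(self) -> list[str]:
        return list(self.params)


def _window_class_mask(partition: GenomePartition, intervals: pd.DataFrame) -> np.ndarray:
    win_df = pd.DataFrame(
        [(w.chrom, w.start, w.end) for w in partition.windows],
        columns=["chrom", "start", "end"],
    )
    if intervals is None or not len(intervals):
        return np.zeros(len(win_df), dtype=bool)
    return intervals_overlap_mask(win_df, intervals)


def design_landscapes(
    annotation: AnnotationSet,
    effects: EffectDesign = EffectDesign(),
    seed: int = 0,
    partition: GenomePartition | None = None,
) -> LandscapeDesign:
    """Draw baseline window parameters and derive per-group landscapes.

    Baseline fields are methylated genome-wide (positive alpha) and
    unmethylated over CpG-island windows (negative alpha), with a positive
    nearest-neighbor coupling.  Group landscapes are the baseline plus the
    class-dependent offsets of ``effects``; the treated group's parameters at
    PRC2-target windows are the convex combination
    ``old + f * (young - old)`` with f the reversal fraction.
    """
    if partition is None:
        partition = partition_genome(annotation)
    rng = np.random.default_rng(seed)
    n_win = partition.n_windows
    sets = annotation.region_sets
    is_island = _window_class_mask(partition, sets.get("cpg_islands"))
    # the aging PRC2 effect acts on the CpG-island windows of target promoters
    islands = sets.get("cpg_islands")
    prc2 = sets.get("prc2_targets")
    if (
        islands is not None
        and prc2 is not None
        and "name" in islands.columns
        and "name" in prc2.columns
        and len(prc2)
    ):
        prc2_effect = islands[islands["name"].isin(set(prc2["name"]))]
    else:
        prc2_effect = prc2
    is_prc2 = _window_class_mask(partition, prc2_effect)
    is_block = _window_class_mask(partition, sets.get("blocks"))

    alpha0 = np.where(
        is_island,
        rng.normal(-1.6, 0.25, size=n_win),
        rng.normal(1.3, 0.3, size=n_win),
    )
    beta0 = rng.normal(0.0, 2.0, size=n_win)
    gamma0 = np.clip(rng.normal(0.25, 0.1, size=n_win), 0.02, None)
    base = np.stack([alpha0, beta0, gamma0], axis=1)

    aged_groups = {"old", "treated"}
    group_arrays: dict[str, np.ndarray] = {}
    for g in effects.group_sizes:
        theta = base.copy()
        if g in aged_groups:
            theta[is_prc2] *= 1.0 - effects.prc2_disorder_shift
            theta[is_prc2, 0] += effects.prc2_alpha_shift
            theta[is_block, 0] += effects.lock_alpha_shift
        theta[:, 0] += effects.global_alpha_shift.get(g, 0.0)
        group_arrays[g] = theta
    if {"treated", "young", "old"} <= set(group_arrays):
        f = effects.treated_reversal_fraction
        t = group_arrays["treated"]
        t[is_prc2] = group_arrays["old"][is_prc2] + f * (
            group_arrays["young"][is_prc2] - group_arrays["old"][is_prc2]
        )

    params = {
        g: {
            i: IsingParameters(*arr[i])
            for i in range(n_win)
            if partition.windows[i].n_cpgs > 0
        }
        for g, arr in group_arrays.items()
    }
    classes = pd.DataFrame(
        {
            "window_index": np.arange(n_win),
            "is_island": is_island,
            "is_prc2": is_prc2,
            "is_block": is_block,
        }
    )
    return LandscapeDesign(annotation, partition, params, classes)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    params: dict[int, IsingParameters],
    partition: GenomePartition,
    coverage: float = 10.0,
    read_span: int = 4,
    seed: int = 0,
) -> dict[int, ReadMatrix]:
    """Simulate one sample: per window, draw a Poisson number of reads with
    mean ``coverage * N / read_span``; each read exposes ``read_span``
    consecutive CpGs of an exact Ising-chain sample (transfer-matrix
    forward-filter backward-sampling) at a uniform random offset.

    Randomness is counter-based per window (substream keyed on
    ``[seed, window_index]``), so simulation order is irrelevant.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if read_span < 1:
        raise ValueError("read_span must be >= 1")
    out: dict[int, ReadMatrix] = {}
    for widx, p in params.items():
        win = partition.windows[widx]
        n = win.n_cpgs
        if n == 0:
            logger.info("window %d has 0 CpGs; skipped", widx)
            continue
        rng = np.random.default_rng([seed, widx])
        n_reads = int(rng.poisson(coverage * n / read_span)) if coverage > 0 else 0
        if n_reads == 0:
            out[widx] = ReadMatrix.from_reads(widx, n, [])
            continue
        a, c = p.fields(win)
        starts, flat, offsets = _ising.simulate_window_reads(
            a, c, n_reads, read_span, rng.random(n_reads), rng.random((n_reads, n))
        )
        out[widx] = ReadMatrix(widx, n, starts, offsets, flat)
    return out


@dataclass
class Cohort:
    """A simulated study: annotation, partition, ground-truth design, and
    per-sample read matrices."""

    config: ToyGenomeConfig
    effects: EffectDesign
    design: LandscapeDesign
    samples: dict[str, dict[int, ReadMatrix]]
    groups: dict[str, list[str]]
    coverage: float
    read_span: int
    seed: int

    @property
    def annotation(self) -> AnnotationSet:
        return self.design.annotation

    @property
    def partition(self) -> GenomePartition:
        return self.design.partition

    def group_of(self, sample_id: str) -> str:
        for g, ids in self.groups.items():
            if sample_id in ids:
                return g
        raise KeyError(sample_id)


def simulate_cohort(
    config: ToyGenomeConfig = ToyGenomeConfig(),
    effects: EffectDesign = EffectDesign(),
    coverage: float = 10.0,
    read_span: int = 4,
    seed: int = 0,
) -> Cohort:
    """Toy genome + designed landscapes + reads for every sample of every
    group.  Per-sample seeds derive from ``seed`` and the sample's position
    in the manifest."""
    genome_cfg = config if config.seed else replace(config, seed=seed)
    annotation = make_toy_genome(genome_cfg)
    design = design_landscapes(annotation, effects, seed=seed + 1)
    groups = effects.sample_ids()
    samples: dict[str, dict[int, ReadMatrix]] = {}
    stream = 0
    for g, ids in groups.items():
        for sid in ids:
            stream += 1
            samples[sid] = simulate_reads(
                design.params[g],
                design.partition,
                coverage,
                read_span,
                seed=(seed * 1000 + stream) % (2**31),
            )
    return Cohort(genome_cfg, effects, design, samples, groups, coverage, read_span, seed)


def ground_truth_table(design: LandscapeDesign) -> pd.DataFrame:
    """Exact per-region MML and NME per group from the generating parameters
    (via the landscape dynamic program, not from reads)."""
    from .landscape import window_level_distributions

    rows = []
    for g, per_window in design.params.items():
        for widx, p in per_window.items():
            win = design.partition.windows[widx]
            for j, d in enumerate(window_level_distributions(p, win)):
                if d is None:
                    continue
                s, e = win.region_bounds(j)
                rows.append(
                    (g, widx, design.partition.region_id(widx, j), win.chrom, s, e,
                     p.alpha, p.beta, p.gamma, d.n_cpgs, d.mml, d.nme)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "window_index", "region_id", "chrom", "start", "end",
            "alpha", "beta", "gamma", "n_cpgs", "mml", "nme",
        ],
    )


def cytosine_report_table(
    matrices: dict[int, ReadMatrix], partition: GenomePartition
) -> pd.DataFrame:
    """Aggregate one sample's reads into per-CpG counts (internal 0-based)."""
    rows = []
    for widx in sorted(matrices):
        rm = matrices[widx]
        win = partition.windows[widx]
        meth, unmeth = rm.cpg_counts()
        for i in range(win.n_cpgs):
            rows.append((win.chrom, int(win.positions[i]), "+", int(meth[i]), int(unmeth[i]), "CpG"))
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "count_methylated", "count_unmethylated", "context"],
    )
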