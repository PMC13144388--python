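"""Coordinate system, annotations, genome partitioning, and on-disk formats.

All internal coordinates are 0-based half-open (BED convention).  Cytosine
reports are 1-based on disk and converted on ingestion.  Windows tile each
chromosome from position 0; a trailing partial window is dropped so that every
window splits into exactly ``REGIONS_PER_WINDOW`` analysis regions.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_SIZE = 3000
REGION_SIZE = 150
REGIONS_PER_WINDOW = WINDOW_SIZE // REGION_SIZE  # 20
PROMOTER_FLANK = 2000  # promoter = 4-kb window centered at the TSS
SEX_CHROMOSOMES = ("chrX", "chrY")

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def _opener(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # fixed mtime so identical content yields identical bytes
            raw = gzip.GzipFile(path, mode="wb", mtime=0)
            return io.TextIOWrapper(raw) if "t" in mode else raw
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Annotation container
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Toy- or real-genome annotation bundle.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.
    cpg_positions
        Mapping chromosome -> sorted array of 0-based positions of the
        forward-strand C of each CpG dyad (strand-collapsed convention).
    genes
        DataFrame with columns gene_id, chrom, start, end, strand.
    region_sets
        Named interval collections (CpG islands, PRC2 targets, LOCKs, peaks,
        block DMRs, ...), each a DataFrame with chrom/start/end columns.
    """

    chrom_sizes: dict[str, int]
    cpg_positions: dict[str, np.ndarray]
    genes: pd.DataFrame
    region_sets: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, pos in self.cpg_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size and (np.any(np.diff(pos) <= 0)):
                raise ValueError(f"CpG positions not strictly increasing on {chrom}")
            if pos.size and (pos[0] < 0 or pos[-1] >= self.chrom_sizes[chrom]):
                raise ValueError(f"CpG positions out of bounds on {chrom}")
            self.cpg_positions[chrom] = pos
        if len(self.genes):
            bad = self.genes["start"] >= self.genes["end"]
            if bad.any():
                raise ValueError("gene start must be < end")

    @property
    def n_cpgs(self) -> int:
        return int(sum(p.size for p in self.cpg_positions.values()))

    def drop_sex_chromosomes(self) -> "AnnotationSet":
        keep = [c for c in self.chrom_sizes if c not in SEX_CHROMOSOMES]
        return AnnotationSet(
            chrom_sizes={c: self.chrom_sizes[c] for c in keep},
            cpg_positions={c: self.cpg_positions[c] for c in keep},
            genes=self.genes[self.genes["chrom"].isin(keep)].reset_index(drop=True),
            region_sets={
                k: v[v["chrom"].isin(keep)].reset_index(drop=True)
                for k, v in self.region_sets.items()
            },
        )


# ---------------------------------------------------------------------------
# Read-level data container
# ---------------------------------------------------------------------------


@dataclass
class ReadMatrix:
    """Per-window read x CpG methylation states as a ragged contiguous-run set.

    Each read observes a contiguous run of CpGs inside one window; CpGs
    outside the run are unobserved.  ``starts[i]`` is the 0-based index of the
    first observed CpG of read ``i`` within the window, and its states are
    ``flat[offsets[i]:offsets[i+1]]`` with 0 = unmethylated, 1 = methylated.
    """

    window_index: int
    n_cpgs: int
    starts: np.ndarray
    offsets: np.ndarray
    flat: np.ndarray

    @property
    def n_reads(self) -> int:
        return int(self.starts.size)

    @property
    def lengths(self) -> np.ndarray:
        return np.diff(self.offsets)

    @classmethod
    def from_reads(cls, window_index, n_cpgs, reads: Sequence[tuple[int, np.ndarray]]):
        starts = np.array([s for s, _ in reads], dtype=np.int32)
        states = [np.asarray(x, dtype=np.int8) for _, x in reads]
        offsets = np.zeros(len(states) + 1, dtype=np.int64)
        if states:
            offsets[1:] = np.cumsum([len(x) for x in states])
        flat = np.concatenate(states) if states else np.zeros(0, dtype=np.int8)
        return cls(window_index, n_cpgs, starts, offsets, flat.astype(np.int8))

    @classmethod
    def from_dense(cls, window_index, dense: np.ndarray):
        """Build from a read x CpG matrix with entries {0, 1, -1=unobserved}."""
        reads = []
        for row in np.asarray(dense):
            obs = np.flatnonzero(row >= 0)
            if obs.size == 0:
                continue
            if obs.size != obs[-1] - obs[0] + 1:
                raise ValueError("reads must observe a contiguous CpG run")
            reads.append((int(obs[0]), row[obs[0] : obs[-1] + 1]))
        return cls.from_reads(window_index, dense.shape[1] if dense.ndim == 2 else 0, reads)

    def to_dense(self) -> np.ndarray:
        out = np.full((self.n_reads, self.n_cpgs), -1, dtype=np.int8)
        for i in range(self.n_reads):
            seg = self.flat[self.offsets[i] : self.offsets[i + 1]]
            out[i, self.starts[i] : self.starts[i] + seg.size] = seg
        return out

    def cpg_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-CpG (methylated, unmethylated) read counts."""
        meth = np.zeros(self.n_cpgs, dtype=np.int64)
        unmeth = np.zeros(self.n_cpgs, dtype=np.int64)
        for i in range(self.n_reads):
            seg = self.flat[self.offsets[i] : self.offsets[i + 1]]
            sl = slice(self.starts[i], self.starts[i] + seg.size)
            meth[sl] += seg == 1
            unmeth[sl] += seg == 0
        return meth, unmeth


# ---------------------------------------------------------------------------
# Genome partition: 3-kb windows x 150-bp analysis regions
# ---------------------------------------------------------------------------


@dataclass
class WindowInfo:
    index: int
    chrom: str
    start: int
    end: int
    cpg_lo: int  # slice into the chromosome CpG array
    cpg_hi: int
    positions: np.ndarray  # absolute bp positions of member CpGs
    rho: np.ndarray  # CpG density covariate per CpG
    w: np.ndarray  # coupling distance weight per CpG pair (len N-1)

    @property
    def n_cpgs(self) -> int:
        return int(self.positions.size)

    def region_bounds(self, j: int) -> tuple[int, int]:
        s = self.start + j * REGION_SIZE
        return s, s + REGION_SIZE

    def region_cpg_slice(self, j: int) -> tuple[int, int]:
        """Indices (lo, hi) of this window's CpGs inside analysis region j."""
        s, e = self.region_bounds(j)
        lo = int(np.searchsorted(self.positions, s, side="left"))
        hi = int(np.searchsorted(self.positions, e, side="left"))
        return lo, hi


@dataclass
class GenomePartition:
    windows: list[WindowInfo]
    chrom_window_index: dict[str, tuple[int, int]]  # chrom -> (first, last+1) window index

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_regions(self) -> int:
        return self.n_windows * REGIONS_PER_WINDOW

    def region_id(self, window_index: int, j: int) -> int:
        return window_index * REGIONS_PER_WINDOW + j

    def region_location(self, region_id: int) -> tuple[str, int, int]:
        win = self.windows[region_id // REGIONS_PER_WINDOW]
        return (win.chrom,) + win.region_bounds(region_id % REGIONS_PER_WINDOW)

    def region_table(self) -> pd.DataFrame:
        rows = []
        for win in self.windows:
            for j in range(REGIONS_PER_WINDOW):
                s, e = win.region_bounds(j)
                rows.append((self.region_id(win.index, j), win.chrom, s, e))
        return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])


def partition_genome(
    annotation: AnnotationSet,
    density_halfwidth: int = 500,
    min_coupling_dist: int = 10,
) -> GenomePartition:
    """Tile each chromosome into consecutive non-overlapping 3-kb windows.

    Each window carries its member CpGs together with the two per-CpG model
    covariates: rho (count of CpGs within +/- ``density_halfwidth`` bp divided
    by 1000) and, for each adjacent pair, the distance weight
    ``100 / max(d, min_coupling_dist)``.
    """
    windows: list[WindowInfo] = []
    chrom_window_index: dict[str, tuple[int, int]] = {}
    for chrom in annotation.chrom_sizes:
        size = annotation.chrom_sizes[chrom]
        pos = annotation.cpg_positions.get(chrom, np.zeros(0, dtype=np.int64))
        n_win = size // WINDOW_SIZE
        # density covariate from the full chromosome CpG set
        hi_counts = np.searchsorted(pos, pos + density_halfwidth, side="right")
        lo_counts = np.searchsorted(pos, pos - density_halfwidth, side="left")
        rho_all = (hi_counts - lo_counts) / 1000.0
        first = len(windows)
        for k in range(n_win):
            ws, we = k * WINDOW_SIZE, (k + 1) * WINDOW_SIZE
            lo = int(np.searchsorted(pos, ws, side="left"))
            hi = int(np.searchsorted(pos, we, side="left"))
            p = pos[lo:hi]
            d = np.diff(p).astype(np.float64)
            w = 100.0 / np.maximum(d, float(min_coupling_dist))
            windows.append(
                WindowInfo(
                    index=len(windows),
                    chrom=chrom,
                    start=ws,
                    end=we,
                    cpg_lo=lo,
                    cpg_hi=hi,
                    positions=p,
                    rho=rho_all[lo:hi].astype(np.float64),
                    w=w,
                )
            )
        chrom_window_index[chrom] = (first, len(windows))
        dropped = size - n_win * WINDOW_SIZE
        if dropped:
            logger.debug("%s: trailing %d bp not covered by any window", chrom, dropped)
    return GenomePartition(windows, chrom_window_index)


def define_promoters(genes: pd.DataFrame, chrom_sizes: dict[str, int], flank: int = PROMOTER_FLANK):
    """Promoter = [TSS - flank, TSS + flank) clipped to the chromosome; the
    gene body is the remainder of the gene after removing promoter overlap."""
    prom_rows, body_rows = [], []
    for rec in genes.itertuples(index=False):
        size = chrom_sizes[rec.chrom]
        tss = rec.start if rec.strand == "+" else rec.end
        ps, pe = max(0, tss - flank), min(size, tss + flank)
        prom_rows.append((rec.gene_id, rec.chrom, ps, pe, rec.strand))
        if rec.strand == "+":
            bs, be = max(rec.start, pe), rec.end
        else:
            bs, be = rec.start, min(rec.end, ps)
        if bs < be:
            body_rows.append((rec.gene_id, rec.chrom, bs, be, rec.strand))
        else:
            logger.debug("gene %s fully inside its promoter; empty body", rec.gene_id)
    cols = GENE_COLUMNS
    return (
        pd.DataFrame(prom_rows, columns=cols),
        pd.DataFrame(body_rows, columns=cols),
    )


def map_regions_to_features(
    partition: GenomePartition, features: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Map each feature interval to the ordered analysis-region ids that share
    at least 1 bp with it.  Features with no overlapping region map to an
    empty array (unscorable, K=0)."""
    out: dict[str, np.ndarray] = {}
    id_col = "gene_id" if "gene_id" in features.columns else None
    for i, rec in enumerate(features.itertuples(index=False)):
        key = getattr(rec, id_col) if id_col else str(i)
        rng = partition.chrom_window_index.get(rec.chrom)
        if rng is None:
            out[key] = np.zeros(0, dtype=np.int64)
            continue
        first, last = rng
        chrom_offset = partition.windows[first].start  # always 0 by construction
        lo_region = max(0, (rec.start - chrom_offset) // REGION_SIZE)
        hi_region = -(-(rec.end - chrom_offset) // REGION_SIZE)  # ceil
        n_regions_chrom = (last - first) * REGIONS_PER_WINDOW
        lo_region = min(lo_region, n_regions_chrom)
        hi_region = max(lo_region, min(hi_region, n_regions_chrom))
        ids = np.arange(lo_region, hi_region, dtype=np.int64) + first * REGIONS_PER_WINDOW
        out[key] = ids
    return out


def intervals_overlap_mask(
    query: pd.DataFrame, targets: pd.DataFrame
) -> np.ndarray:
    """Boolean mask: does each query interval share >= 1 bp with any target?"""
    mask = np.zeros(len(query), dtype=bool)
    by_chrom = {c: g for c, g in targets.groupby("chrom")} if len(targets) else {}
    for chrom, grp in query.groupby("chrom"):
        tg = by_chrom.get(chrom)
        if tg is None or not len(tg):
            continue
        starts, ends = merge_intervals(tg["start"].to_numpy(), tg["end"].to_numpy())
        qs = grp["start"].to_numpy()
        qe = grp["end"].to_numpy()
        idx = np.searchsorted(starts, qe, side="left")
        hit = (idx > 0) & (ends[np.maximum(idx - 1, 0)] > qs)
        mask[grp.index.to_numpy()] = hit
    return mask


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    starts, ends = np.asarray(starts)[order], np.asarray(ends)[order]
    ms, me = [], []
    for s, e in zip(starts, ends):
        if me and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms, dtype=np.int64), np.asarray(me, dtype=np.int64)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 as 0-based half-open intervals, preserved as-is."""
    rows = []
    with _opener(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed BED coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{ln}: invalid interval [{start}, {end})")
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, name, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def write_bed(df: pd.DataFrame, path) -> None:
    with _opener(path, "wt") as fh:
        for rec in df.itertuples(index=False):
            name = getattr(rec, "name", None) or getattr(rec, "gene_id", ".")
            strand = getattr(rec, "strand", ".")
            if strand in (".", None) and name == ".":
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\n")
            else:
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{name}\t0\t{strand}\n")


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a cytosine-report TSV: chrom, 1-based position, strand,
    count_methylated, count_unmethylated, context.  Positions are converted to
    the internal 0-based convention."""
    rows = []
    with _opener(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{ln}: cytosine report needs >= 5 fields")
            try:
                chrom, pos1 = parts[0], int(parts[1])
                meth, unmeth = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed cytosine-report line") from exc
            if pos1 < 1:
                raise ValueError(f"{path}:{ln}: position must be >= 1 (1-based)")
            if meth < 0 or unmeth < 0:
                raise ValueError(f"{path}:{ln}: negative count")
            context = parts[5] if len(parts) > 5 else "CpG"
            rows.append((chrom, pos1 - 1, parts[2], meth, unmeth, context))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "count_methylated", "count_unmethylated", "context"]
    )


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    """Write internal 0-based per-CpG counts as a 1-based cytosine report."""
    with _opener(path, "wt") as fh:
        for rec in df.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{rec.pos + 1}\t{getattr(rec, 'strand', '+')}\t"
                f"{rec.count_methylated}\t{rec.count_unmethylated}\t"
                f"{getattr(rec, 'context', 'CpG')}\n"
            )


def write_read_matrices(matrices: dict[int, ReadMatrix], path) -> None:
    """Archive of per-window reads: window_id, read_id, first_cpg_index,
    state string over {0,1}."""
    with _opener(path, "wt") as fh:
        fh.write("window_id\tread_id\tfirst_cpg_index\tstates\n")
        for widx in sorted(matrices):
            rm = matrices[widx]
            for i in range(rm.n_reads):
                seg = rm.flat[rm.offsets[i] : rm.offsets[i + 1]]
                fh.write(f"{widx}\t{i}\t{rm.starts[i]}\t{''.join('1' if s else '0' for s in seg)}\n")


def read_read_matrices(path, window_n_cpgs: dict[int, int]) -> dict[int, ReadMatrix]:
    per_window: dict[int, list[tuple[int, np.ndarray]]] = {}
    with _opener(path) as fh:
        header = fh.readline()
        if not header.startswith("window_id"):
            raise ValueError(f"{path}:1: missing read-matrix header")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 fields")
            widx, start = int(parts[0]), int(parts[2])
            states = np.frombuffer(parts[3].encode(), dtype=np.uint8) - ord("0")
            if np.any(states > 1):
                raise ValueError(f"{path}:{ln}: state string must be over {{0,1}}")
            per_window.setdefault(widx, []).append((start, states.astype(np.int8)))
    return {
        widx: ReadMatrix.from_reads(widx, window_n_cpgs[widx], reads)
        for widx, reads in per_window.items()
    }


def write_bedgraph(df: pd.DataFrame, value_col: str, path) -> None:
    """Write a bedGraph track; rows with missing values are omitted."""
    with _opener(path, "wt") as fh:
        for rec in df.itertuples(index=False):
            v = getattr(rec, value_col)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{v:.6g}\n")


def write_results(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_list(path) -> list[str]:
    with _opener(path) as fh:
        return [line.split("\t")[0].strip() for line in fh if line.strip()]


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set collection: name, description, genes... (tab-separated)."""
    sets: dict[str, list[str]] = {}
    with _opener(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise ValueError(f"{path}:{ln}: GMT line needs >= 3 fields")
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path) -> None:
    with _opener(path, "wt") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
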