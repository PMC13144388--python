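"""Gene-list overlap tests, over-representation analysis, and the genomic
region-overlap permutation test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import merge_intervals


@dataclass
class OverlapResult:
    a: int  # in A and B
    b: int  # in A only
    c: int  # in B only
    d: int  # in neither
    odds_ratio: float
    p_value: float

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class PermutationOverlapResult:
    observed: int
    perm_mean: float
    perm_sd: float
    z: float
    p_value: float
    n_permutations: int
    seed: int
    alternative: str


def fisher_overlap(list_a, list_b, universe) -> OverlapResult:
    """Two-sided Fisher's exact test of gene-list overlap within a universe.

    The odds ratio is the sample cross-product (ad)/(bc), with 0.5 added to
    every cell only when some cell is zero."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sa, sb = set(list_a) & uni, set(list_b) & uni
    if set(list_a) - uni or set(list_b) - uni:
        raise ValueError("gene lists must be subsets of the universe")
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(uni) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return OverlapResult(a, b, c, d, float(orr), float(p))


def ora(gene_list, collection: dict[str, list[str]], universe) -> pd.DataFrame:
    """Over-representation analysis of one gene list against a gene-set
    collection: one-sided (upper-tail) hypergeometric p per set, BH-adjusted
    across the collection, ranked by p.  Sets are intersected with the
    universe before testing; empty intersections get p = 1 and a flag."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(gene_list) & uni
    n_uni, n_query = len(uni), len(query)
    rows = []
    for name, genes in collection.items():
        members = set(genes) & uni
        k = len(query & members)
        m = len(members)
        if m == 0:
            rows.append((name, 0, 0, 0, 1.0, True))
            continue
        # P(X >= k), X ~ Hypergeom(N=n_uni, K=m, n=n_query)
        p = float(stats.hypergeom.sf(k - 1, n_uni, m, n_query))
        rows.append((name, k, m, n_query, p, False))
    out = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "query_size", "p_value", "empty"]
    )
    from statsmodels.stats.multitest import multipletests

    out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out = out.sort_values(["p_value", "set"], ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _count_overlapping(
    starts: np.ndarray, lengths: np.ndarray, b_starts: np.ndarray, b_ends: np.ndarray
) -> np.ndarray:
    """For region start matrices (any shape) against merged sorted target
    intervals, return a boolean array: does each region overlap >= 1 bp?"""
    ends = starts + lengths
    idx = np.searchsorted(b_starts, ends, side="left")
    hit = (idx > 0) & (b_ends[np.maximum(idx - 1, 0)] > starts)
    return hit


def permutation_overlap(
    regions_a: pd.DataFrame,
    regions_b: pd.DataFrame,
    chrom_sizes: dict[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "enrichment",
) -> PermutationOverlapResult:
    """Permutation test of region-set overlap.

    The statistic is the number of A regions overlapping at least one B
    region.  Each permutation re-places every A region uniformly within its
    own chromosome, preserving lengths and chromosome assignment (overlaps
    among placed regions permitted).  p = (#{perm >= obs} + 1)/(n_perm + 1)
    for enrichment (the symmetric lower tail for depletion); the z-score is
    the distance of the observed count from the permutation mean in
    permutation standard deviations.
    """
    if alternative not in ("enrichment", "depletion"):
        raise ValueError("alternative must be 'enrichment' or 'depletion'")
    rng = np.random.default_rng(seed)
    b_by_chrom = {}
    for chrom, grp in regions_b.groupby("chrom"):
        b_by_chrom[chrom] = merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())

    observed = 0
    perm_counts = np.zeros(n_perm, dtype=np.int64)
    for chrom, grp in regions_a.groupby("chrom"):
        size = chrom_sizes[chrom]
        starts = grp["start"].to_numpy(np.int64)
        lengths = (grp["end"] - grp["start"]).to_numpy(np.int64)
        if np.any(lengths > size):
            raise ValueError(f"region longer than chromosome {chrom}")
        tb = b_by_chrom.get(chrom)
        if tb is None:
            continue  # nothing to overlap on this chromosome; permuted stays 0
        b_starts, b_ends = tb
        observed += int(_count_overlapping(starts, lengths, b_starts, b_ends).sum())
        max_start = size - lengths  # inclusive upper bound per region
        u = rng.random((n_perm, lengths.size))
        perm_starts = (u * (max_start + 1)).astype(np.int64)
        hits = _count_overlapping(perm_starts, lengths[None, :], b_starts, b_ends)
        perm_counts += hits.sum(axis=1)

    mean = float(perm_counts.mean())
    sd = float(perm_counts.std(ddof=0))
    if sd > 0:
        z = (observed - mean) / sd
    else:
        z = 0.0 if observed == mean else np.inf * np.sign(observed - mean)
    if alternative == "enrichment":
        r = int(np.sum(perm_counts >= observed))
    else:
        r = int(np.sum(perm_counts <= observed))
    p = (r + 1) / (n_perm + 1)
    return PermutationOverlapResult(
        observed, mean, sd, float(z), float(p), n_perm, seed, alternative
    )


def restrict_universe(
    universe, ranked_genes, sex_chrom_genes=None
) -> list[str]:
    """Background for overlaps involving landscape-derived rankings: the
    common set of genes assessed in both analyses, with sex-chromosome genes
    removed (no landscape values are reported there)."""
    uni = set(universe) & set(ranked_genes)
    if sex_chrom_genes:
        uni -= set(sex_chrom_genes)
    return sorted(uni)
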