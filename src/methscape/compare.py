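"""Comparative statistics on MML/NME region tracks.

Two complementary analyses: (i) independent Welch t tests on one
genome-wide (or restricted) average per sample, and (ii) a paired Wilcoxon
signed-rank test on the per-region group-mean tracks, reported with the
Hodges-Lehmann pseudo-median e of the paired differences.  Also: promoter
stratification by chromatin status with the 5-percentage-point rule on
CpG-island MML/NME, scaled metagene profiles, and ChIP spike-in scale
factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

WILCOXON_MIN_PAIRS = 10
EXACT_HL_MAX_N = 20_000
MC_WALSH_PAIRS = 2_000_000
CHANGE_THRESHOLD = 0.05  # absolute, on the [0,1] MML/NME scale


@dataclass
class ComparisonResult:
    statistic_name: str
    means_a: np.ndarray
    means_b: np.ndarray
    t_statistic: float
    p_two_sided: float
    p_one_sided: float
    wilcoxon_p: float | None = None
    pseudo_median: float | None = None
    n_tiles: int | None = None


def per_sample_mean(track: np.ndarray, restriction: np.ndarray | None = None) -> float:
    """Unweighted mean of a per-region track over regions with values,
    optionally restricted to a boolean region mask or index array."""
    t = np.asarray(track, dtype=float)
    if restriction is not None:
        restriction = np.asarray(restriction)
        if restriction.dtype == bool:
            if not restriction.any():
                raise ValueError("empty restriction")
            t = t[restriction]
        else:
            if restriction.size == 0:
                raise ValueError("empty restriction")
            t = t[restriction]
    t = t[~np.isnan(t)]
    if t.size == 0:
        raise ValueError("no covered regions under restriction")
    return float(t.mean())


def group_t_test(
    values_a, values_b, alternative: str = "two-sided"
) -> ComparisonResult:
    """Welch two-sample t test on one value per sample; reports both the
    two-sided p and the one-sided p for the configured alternative."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 samples per group")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        t, p2 = 0.0, 1.0
    else:
        t, p2 = stats.ttest_ind(a, b, equal_var=False)
    alt = alternative if alternative != "two-sided" else "less" if t < 0 else "greater"
    matches = (alt == "less" and t <= 0) or (alt == "greater" and t >= 0)
    p1 = p2 / 2 if matches else 1 - p2 / 2
    return ComparisonResult(
        statistic_name="welch_t",
        means_a=a,
        means_b=b,
        t_statistic=float(t),
        p_two_sided=float(p2),
        p_one_sided=float(p1),
    )


def _walsh_count_le(d_sorted: np.ndarray, t: float) -> int:
    """#{i <= j : (d_i + d_j)/2 <= t} by a two-pointer sweep, O(n)."""
    n = d_sorted.size
    count = 0
    j = n - 1
    for i in range(n):
        while j >= i and d_sorted[i] + d_sorted[j] > 2 * t:
            j -= 1
        if j < i:
            break
        count += j - i + 1
        # j only moves left overall; reset not needed since d sorted ascending
    return count


def _walsh_kth(d_sorted: np.ndarray, k: int) -> float:
    """k-th smallest Walsh average (1-based) by bisection on the value."""
    lo, hi = float(d_sorted[0]), float(d_sorted[-1])
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _walsh_count_le(d_sorted, mid) >= k:
            hi = mid
        else:
            lo = mid
        if hi - lo <= 1e-13 * max(1.0, abs(hi), abs(lo)):
            break
    return hi


def hodges_lehmann(differences, seed: int = 0, method: str = "auto") -> float:
    """Pseudo-median: the median of the Walsh averages (d_i + d_j)/2 over
    i <= j.  Exact for n <= 20,000 paired differences; beyond that, the
    median of 2,000,000 uniformly sampled Walsh pairs with a fixed seed.
    ``method`` may force "exact" or "monte-carlo"."""
    d = np.sort(np.asarray(differences, dtype=float))
    n = d.size
    if n == 0:
        raise ValueError("no differences")
    exact = n <= EXACT_HL_MAX_N if method == "auto" else method == "exact"
    if exact and n <= 2000:
        i, j = np.triu_indices(n)
        return float(np.median((d[i] + d[j]) / 2.0))
    if exact:
        m = n * (n + 1) // 2
        if m % 2 == 1:
            return _walsh_kth(d, (m + 1) // 2)
        return 0.5 * (_walsh_kth(d, m // 2) + _walsh_kth(d, m // 2 + 1))
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=MC_WALSH_PAIRS)
    j = rng.integers(0, n, size=MC_WALSH_PAIRS)
    return float(np.median((d[i] + d[j]) / 2.0))


def paired_wilcoxon_tiles(
    track_a: np.ndarray, track_b: np.ndarray, seed: int = 0
) -> tuple[float, float, int]:
    """Paired Wilcoxon signed-rank test on per-region group-mean tracks.

    Pairs with either side missing are dropped.  Returns
    (two-sided p, pseudo-median e of the differences a - b, n pairs used).
    """
    a = np.asarray(track_a, dtype=float)
    b = np.asarray(track_b, dtype=float)
    mask = ~(np.isnan(a) | np.isnan(b))
    d = a[mask] - b[mask]
    if d.size < WILCOXON_MIN_PAIRS:
        raise ValueError(f"need >= {WILCOXON_MIN_PAIRS} paired regions")
    e = hodges_lehmann(d, seed=seed)
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0, e, int(d.size)
    _, p = stats.wilcoxon(nz, alternative="two-sided", mode="auto")
    return float(p), e, int(d.size)


def compare_tracks(
    name: str,
    per_sample_tracks_a: list[np.ndarray],
    per_sample_tracks_b: list[np.ndarray],
    restriction: np.ndarray | None = None,
    alternative: str = "two-sided",
    seed: int = 0,
) -> ComparisonResult:
    """Full two-track comparison: Welch t on per-sample means plus paired
    Wilcoxon on the group-mean tracks, all under an optional region
    restriction."""
    means_a = np.array([per_sample_mean(t, restriction) for t in per_sample_tracks_a])
    means_b = np.array([per_sample_mean(t, restriction) for t in per_sample_tracks_b])
    res = group_t_test(means_a, means_b, alternative)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ga = np.nanmean(np.stack(per_sample_tracks_a), axis=0)
        gb = np.nanmean(np.stack(per_sample_tracks_b), axis=0)
    if restriction is not None:
        idx = restriction if restriction.dtype != bool else np.flatnonzero(restriction)
        ga, gb = ga[idx], gb[idx]
    p_w, e, n = paired_wilcoxon_tiles(ga, gb, seed=seed)
    return ComparisonResult(
        statistic_name=name,
        means_a=means_a,
        means_b=means_b,
        t_statistic=res.t_statistic,
        p_two_sided=res.p_two_sided,
        p_one_sided=res.p_one_sided,
        wilcoxon_p=p_w,
        pseudo_median=e,
        n_tiles=n,
    )


# ---------------------------------------------------------------------------
# Promoter stratification by chromatin status
# ---------------------------------------------------------------------------


def promoter_island_means(
    sample_tracks: dict[str, np.ndarray],
    promoter_regions: dict[str, np.ndarray],
    island_region_mask: np.ndarray,
) -> pd.DataFrame:
    """Per-promoter, per-sample mean over the promoter's analysis regions
    that overlap CpG islands.  Promoters with no covered island-overlapping
    region get NaN (excluded downstream)."""
    rows = {}
    for gene, rids in promoter_regions.items():
        rids = rids[island_region_mask[rids]] if rids.size else rids
        vals = {}
        for sid, track in sample_tracks.items():
            v = track[rids] if rids.size else np.zeros(0)
            v = v[~np.isnan(v)]
            vals[sid] = float(v.mean()) if v.size else np.nan
        rows[gene] = vals
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_changes(delta: pd.Series, threshold: float = CHANGE_THRESHOLD) -> pd.Series:
    """Increase / decrease / no-change by the 5-percentage-point rule on the
    difference of condition-level means (absolute, on the [0,1] scale)."""
    out = pd.Series("no-change", index=delta.index, dtype=object)
    out[delta > threshold] = "increase"
    out[delta < -threshold] = "decrease"
    out[delta.isna()] = np.nan
    return out


def stratify_promoters(
    chromatin_status: pd.Series,
    cond1_sample_means: pd.DataFrame,
    cond2_sample_means: pd.DataFrame,
    threshold: float = CHANGE_THRESHOLD,
) -> pd.DataFrame:
    """Classify each promoter's CpG-island MML or NME change between two
    conditions, stratified by chromatin status (e.g. H3K27me3
    unmarked/retained/lost).

    Condition-level means are the average of sample-level means; the class is
    increase/decrease/no-change by the threshold rule on cond1 - cond2.
    Promoters without island-overlapping covered regions are excluded.
    """
    m1 = cond1_sample_means.mean(axis=1)
    m2 = cond2_sample_means.mean(axis=1)
    delta = m1 - m2
    out = pd.DataFrame(
        {
            "status": chromatin_status.reindex(delta.index),
            "cond1_mean": m1,
            "cond2_mean": m2,
            "delta": delta,
            "change": classify_changes(delta, threshold),
        }
    )
    return out.dropna(subset=["delta"])


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------


def metagene_profile(
    signal: pd.DataFrame,
    genes: pd.DataFrame,
    body_bins: int = 100,
    flank_bins: int = 40,
    flank: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled metagene matrix: gene bodies scaled to ``body_bins`` bins,
    flanked by +/- ``flank`` bp of unscaled sequence in ``flank_bins`` bins;
    minus-strand genes are reversed so 5'->3' orientation is uniform.

    ``signal`` is a piecewise-constant track (chrom, start, end, value).
    Returns (per-gene matrix, per-bin mean curve ignoring missing bins).
    Genes shorter than one body bin are excluded.
    """
    if not len(genes):
        raise ValueError("empty gene set")
    total_bins = body_bins + 2 * flank_bins
    by_chrom = {}
    for chrom, grp in signal.groupby("chrom"):
        g = grp.sort_values("start")
        by_chrom[chrom] = (
            g["start"].to_numpy(float),
            g["end"].to_numpy(float),
            g["value"].to_numpy(float),
        )

    def bin_mean(chrom, bs, be):
        tr = by_chrom.get(chrom)
        if tr is None or be <= bs:
            return np.nan
        starts, ends, vals = tr
        lo = np.searchsorted(ends, bs, side="right")
        hi = np.searchsorted(starts, be, side="left")
        if hi <= lo:
            return np.nan
        s = np.maximum(starts[lo:hi], bs)
        e = np.minimum(ends[lo:hi], be)
        w = e - s
        keep = (w > 0) & ~np.isnan(vals[lo:hi])
        if not keep.any():
            return np.nan
        return float(np.average(vals[lo:hi][keep], weights=w[keep]))

    mats = []
    for rec in genes.itertuples(index=False):
        glen = rec.end - rec.start
        if glen < body_bins:
            continue
        row = np.full(total_bins, np.nan)
        # upstream flank, body, downstream flank in genomic orientation
        up_edges = np.linspace(rec.start - flank, rec.start, flank_bins + 1)
        body_edges = np.linspace(rec.start, rec.end, body_bins + 1)
        dn_edges = np.linspace(rec.end, rec.end + flank, flank_bins + 1)
        edges = np.concatenate([up_edges[:-1], body_edges[:-1], dn_edges])
        for k in range(total_bins):
            row[k] = bin_mean(rec.chrom, edges[k], edges[k + 1])
        if rec.strand == "-":
            row = row[::-1]
        mats.append(row)
    if not mats:
        raise ValueError("no genes long enough for the requested binning")
    mat = np.vstack(mats)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        curve = np.nanmean(mat, axis=0)
    return mat, curve


# ---------------------------------------------------------------------------
# ChIP spike-in scaling
# ---------------------------------------------------------------------------


def spike_in_scale(exogenous_counts) -> np.ndarray:
    """Per-sample scale factors from exogenous-genome mapped read counts:
    factor_i = min_j(D_j) / D_i, so the least-deep sample has factor 1."""
    d = np.asarray(exogenous_counts, dtype=float)
    if np.any(d <= 0):
        raise ValueError("spike-in read counts must be > 0")
    return d.min() / d
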