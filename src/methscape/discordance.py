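"""Jensen-Shannon-distance discordance scoring and gene ranking.

Per analysis region, the JSD between the methylation-level distributions of a
test and a reference condition quantifies epigenetic discordance; a feature
(promoter or gene body) is scored by the JSD magnitude, the root mean square
of the JSDs of its K overlapping regions.  Significance is calibrated on a
null built from reference-vs-reference comparisons, stratified by K; feature
p-values are combined per gene with Fisher's summary statistic, genes are
ranked (ties broken by rank products across comparisons) and flagged by
Benjamini-Hochberg q-values.

Group-versus-group comparisons default to *depth-matched pooled* landscapes:
each side's reads are pooled over its samples and thinned so the pooled depth
matches a single sample, making a test-versus-reference comparison
statistically exchangeable with the single-sample reference pairs that build
the null.  Sample-averaged and median-pairwise alternatives are available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomePartition, ReadMatrix
from .landscape import LevelDistribution, RegionLevels, fit_all_windows, region_level_table

logger = logging.getLogger(__name__)

K_BIN_EDGES = ((1, 5), (6, 10), (11, 20), (21, 40), (41, np.inf))
MIN_NULL_PER_BIN = 200


# ---------------------------------------------------------------------------
# JSD primitives
# ---------------------------------------------------------------------------


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def jsd(p, q) -> float:
    """Jensen-Shannon distance sqrt((D(P,M) + D(Q,M))/2), M = (P+Q)/2, logs
    base 2.  Symmetric, in [0, 1]; 0 iff P = Q, 1 iff disjoint supports."""
    if isinstance(p, LevelDistribution):
        if not isinstance(q, LevelDistribution) or p.n_cpgs != q.n_cpgs:
            raise ValueError("JSD requires distributions on the same support")
        p, q = p.probabilities, q.probabilities
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("JSD requires distributions on the same support")
    m = 0.5 * (p + q)
    div = 0.5 * (_kl(p, m) + _kl(q, m))
    return float(np.sqrt(max(div, 0.0)))


def jsd_magnitude(values) -> float:
    """Root mean square of the JSD values over a feature's K regions."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("jsd_magnitude requires K >= 1 values")
    return float(np.sqrt(np.mean(v**2)))


def region_jsd_track(a: RegionLevels, b: RegionLevels, n_regions: int) -> np.ndarray:
    """Per-region JSD between two sets of level distributions; NaN where
    either side is missing."""
    out = np.full(n_regions, np.nan)
    keys = a.distributions.keys() & b.distributions.keys()
    for rid in keys:
        pa, pb = a.distributions[rid], b.distributions[rid]
        if pa.size != pb.size:
            raise ValueError(f"region {rid}: mismatched level supports")
        out[rid] = jsd(pa, pb)
    return out


# ---------------------------------------------------------------------------
# Group-level landscapes
# ---------------------------------------------------------------------------


def pool_reads(
    matrices_list: list[dict[int, ReadMatrix]],
    partition: GenomePartition,
    thin: float | None = None,
    seed: int = 0,
) -> dict[int, ReadMatrix]:
    """Pool reads across samples per window, optionally keeping each read
    with probability ``thin`` (counter-based per-window substreams)."""
    out: dict[int, ReadMatrix] = {}
    windows = set()
    for m in matrices_list:
        windows |= m.keys()
    for widx in sorted(windows):
        win = partition.windows[widx]
        reads: list[tuple[int, np.ndarray]] = []
        for m in matrices_list:
            rm = m.get(widx)
            if rm is None:
                continue
            for i in range(rm.n_reads):
                seg = rm.flat[rm.offsets[i] : rm.offsets[i + 1]]
                reads.append((int(rm.starts[i]), seg))
        if thin is not None and thin < 1.0 and reads:
            rng = np.random.default_rng([seed, widx])
            keep = rng.random(len(reads)) < thin
            reads = [r for r, k in zip(reads, keep) if k]
        out[widx] = ReadMatrix.from_reads(widx, win.n_cpgs, reads)
    return out


def sample_region_levels(
    matrices: dict[int, ReadMatrix],
    partition: GenomePartition,
    min_reads: int = 5,
) -> RegionLevels:
    """Fit every window of one sample (or pooled pseudo-sample) and flatten
    to per-region level distributions."""
    fits = fit_all_windows(matrices, partition, min_reads=min_reads)
    return region_level_table(fits, partition)


def group_region_levels(
    matrices_list: list[dict[int, ReadMatrix]],
    partition: GenomePartition,
    mode: str = "pooled",
    seed: int = 0,
    min_reads: int = 5,
    sample_levels: list[RegionLevels] | None = None,
) -> RegionLevels:
    """One set of per-region level distributions for a group of samples.

    mode="pooled": fit the pooled reads thinned to single-sample depth
    (keep probability 1/n_samples).  mode="average": average the member
    samples' per-region P_L (requires ``sample_levels``).
    """
    if mode == "pooled":
        pooled = pool_reads(
            matrices_list, partition, thin=1.0 / max(len(matrices_list), 1), seed=seed
        )
        return sample_region_levels(pooled, partition, min_reads=min_reads)
    if mode == "average":
        if sample_levels is None:
            raise ValueError("mode='average' requires per-sample levels")
        n_regions = sample_levels[0].mml.size
        dists: dict[int, np.ndarray] = {}
        keys = set(sample_levels[0].distributions)
        for sl in sample_levels[1:]:
            keys &= sl.distributions.keys()
        mml_arr = np.full(n_regions, np.nan)
        nme_arr = np.full(n_regions, np.nan)
        n_arr = np.zeros(n_regions, dtype=np.int32)
        for rid in keys:
            stack = np.stack([sl.distributions[rid] for sl in sample_levels])
            p = stack.mean(axis=0)
            dists[rid] = p
            d = LevelDistribution(p.size - 1, p)
            mml_arr[rid] = d.mml
            nme_arr[rid] = d.nme
            n_arr[rid] = p.size - 1
        return RegionLevels(mml_arr, nme_arr, n_arr, dists)
    raise ValueError(f"unknown group mode: {mode}")


# ---------------------------------------------------------------------------
# Feature scoring
# ---------------------------------------------------------------------------


def score_features(
    region_jsd: np.ndarray, feature_regions: dict[str, np.ndarray], kind: str
) -> pd.DataFrame:
    """JSD magnitude per feature over its covered regions.  Features whose
    regions are all missing get K=0 and NaN magnitude (unscorable)."""
    rows = []
    for key, rids in feature_regions.items():
        vals = region_jsd[rids] if rids.size else np.zeros(0)
        vals = vals[~np.isnan(vals)]
        k = int(vals.size)
        mag = jsd_magnitude(vals) if k else np.nan
        rows.append((key, kind, k, mag))
    return pd.DataFrame(rows, columns=["gene_id", "kind", "K", "jsd_magnitude"])


def score_comparison(
    test_matrices: list[dict[int, ReadMatrix]],
    ref_matrices: list[dict[int, ReadMatrix]],
    partition: GenomePartition,
    feature_regions: dict[str, dict[str, np.ndarray]],
    mode: str = "pooled",
    seed: int = 0,
    min_reads: int = 5,
    sample_levels: tuple[list[RegionLevels], list[RegionLevels]] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Score all features for one test-versus-reference comparison.

    ``feature_regions`` maps feature kind (promoter/body) -> gene -> region
    ids.  Returns (feature table, per-region JSD track).
    """
    if mode == "median-pair":
        if sample_levels is None:
            raise ValueError("mode='median-pair' requires per-sample levels")
        test_levels, ref_levels = sample_levels
        n_regions = partition.n_regions
        tracks = [
            region_jsd_track(t, r, n_regions) for t in test_levels for r in ref_levels
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            track = np.nanmedian(np.stack(tracks), axis=0)
    else:
        if mode == "average":
            if sample_levels is None:
                raise ValueError("mode='average' requires per-sample levels")
            tl = group_region_levels(
                test_matrices, partition, "average", sample_levels=sample_levels[0]
            )
            rl = group_region_levels(
                ref_matrices, partition, "average", sample_levels=sample_levels[1]
            )
        else:
            tl = group_region_levels(
                test_matrices, partition, mode, seed=seed, min_reads=min_reads
            )
            rl = group_region_levels(
                ref_matrices, partition, mode, seed=seed + 1, min_reads=min_reads
            )
        track = region_jsd_track(tl, rl, partition.n_regions)
    tables = [
        score_features(track, regions, kind) for kind, regions in feature_regions.items()
    ]
    return pd.concat(tables, ignore_index=True), track


# ---------------------------------------------------------------------------
# Reference-derived null
# ---------------------------------------------------------------------------


@dataclass
class NullModel:
    """Pooled reference-pair JSD magnitudes, stratified by feature kind and
    region count K.

    ``strata`` maps (kind, merged-bin index) to the sorted null values for
    that stratum; within each kind, K-bins with fewer than
    ``MIN_NULL_PER_BIN`` values were merged forward (the trailing bin
    backward)."""

    bin_edges: tuple
    strata: dict[tuple[str, int], np.ndarray]
    bin_map: dict[tuple[str, int], tuple[str, int]]
    n_pairs: int

    def bin_index(self, k: int) -> int:
        for i, (lo, hi) in enumerate(self.bin_edges):
            if lo <= k <= hi:
                return i
        raise ValueError(f"K={k} outside all bins")

    def stratum(self, kind: str, k: int) -> np.ndarray:
        return self.strata[self.bin_map[(kind, self.bin_index(k))]]


def build_null(
    ref_sample_levels: list[RegionLevels],
    partition: GenomePartition,
    feature_regions: dict[str, dict[str, np.ndarray]],
    bin_edges: tuple = K_BIN_EDGES,
    min_per_bin: int = MIN_NULL_PER_BIN,
) -> NullModel:
    """Null JSD magnitudes from all unordered reference-sample pairs,
    scored with the same feature definitions as the test comparison."""
    if len(ref_sample_levels) < 2:
        raise ValueError("null requires >= 2 reference samples")
    n_regions = partition.n_regions
    mags: list[pd.DataFrame] = []
    n_pairs = 0
    for i in range(len(ref_sample_levels)):
        for j in range(i + 1, len(ref_sample_levels)):
            n_pairs += 1
            track = region_jsd_track(ref_sample_levels[i], ref_sample_levels[j], n_regions)
            for kind, regions in feature_regions.items():
                mags.append(score_features(track, regions, kind))
    pooled = pd.concat(mags, ignore_index=True).dropna(subset=["jsd_magnitude"])
    pooled = pooled[pooled["K"] >= 1]
    if not len(pooled):
        raise ValueError("null model is empty")

    strata: dict[tuple[str, int], np.ndarray] = {}
    bin_map: dict[tuple[str, int], tuple[str, int]] = {}
    nbins = len(bin_edges)
    for kind, grp in pooled.groupby("kind"):
        raw: dict[int, list[float]] = {i: [] for i in range(nbins)}
        for k, mag in zip(grp["K"].to_numpy(), grp["jsd_magnitude"].to_numpy()):
            for i, (lo, hi) in enumerate(bin_edges):
                if lo <= k <= hi:
                    raw[i].append(mag)
                    break
        kind_map = {i: i for i in range(nbins)}
        merged = {i: list(v) for i, v in raw.items()}
        i = 0
        while i < nbins - 1:  # forward-merge sparse bins
            if len(merged[i]) < min_per_bin:
                merged[i + 1] = merged[i] + merged[i + 1]
                for j, tgt in kind_map.items():
                    if tgt == i:
                        kind_map[j] = i + 1
                merged[i] = []
            i += 1
        last = nbins - 1  # trailing sparse bin merges backward
        if len(merged[last]) < min_per_bin:
            prev = max(
                (t for t in set(kind_map.values()) if t != last and len(merged[t]) > 0),
                default=None,
            )
            if prev is not None:
                merged[prev] = merged[prev] + merged[last]
                for j, tgt in kind_map.items():
                    if tgt == last:
                        kind_map[j] = prev
                merged[last] = []
        all_vals = np.sort(grp["jsd_magnitude"].to_numpy())
        for i in range(nbins):
            tgt = kind_map[i]
            if len(merged[tgt]) > 0:
                strata[(kind, tgt)] = np.sort(np.asarray(merged[tgt]))
                bin_map[(kind, i)] = (kind, tgt)
            else:  # whole kind too sparse: fall back to its global pool
                strata[(kind, -1)] = all_vals
                bin_map[(kind, i)] = (kind, -1)
    return NullModel(bin_edges, strata, bin_map, n_pairs)


def feature_pvalue(score: float, k: int, null: NullModel, kind: str = "combined") -> float:
    """One-sided upper-tail empirical p with add-one smoothing:
    p = (r + 1) / (m + 1), r = #{null >= score} in the kind- and K-matched
    stratum."""
    arr = null.stratum(kind, k)
    m = arr.size
    if m == 0:
        raise ValueError("empty null stratum")
    r = m - int(np.searchsorted(arr, score, side="left"))
    return (r + 1) / (m + 1)


def feature_pvalues(table: pd.DataFrame, null: NullModel) -> pd.Series:
    out = np.full(len(table), np.nan)
    ks = table["K"].to_numpy()
    mags = table["jsd_magnitude"].to_numpy()
    kinds = table["kind"].to_numpy()
    for i in range(len(table)):
        if ks[i] >= 1 and np.isfinite(mags[i]):
            out[i] = feature_pvalue(mags[i], int(ks[i]), null, str(kinds[i]))
    return pd.Series(out, index=table.index, name="p_value")


# ---------------------------------------------------------------------------
# Parametric (location-scale-shape) null refinement
# ---------------------------------------------------------------------------


@dataclass
class ParametricNull:
    """Skew-t fit of logit null magnitudes with location and log-scale linear
    in log K (a location-scale-shape regression in the GAMLSS spirit)."""

    coef: np.ndarray  # (b0, b1, s0, s1, log_a, log_b)
    eps: float = 1e-6

    def pvalue(self, score: float, k: int) -> float:
        z = _logit(score, self.eps)
        b0, b1, s0, s1, la, lb = self.coef
        x = np.log(k)
        loc = b0 + b1 * x
        scale = np.exp(s0 + s1 * x)
        return float(stats.jf_skew_t.sf(z, np.exp(la), np.exp(lb), loc=loc, scale=scale))


def _logit(x, eps):
    x = np.clip(x, eps, 1.0 - eps)
    return np.log(x / (1.0 - x))


def fit_parametric_null(
    magnitudes: np.ndarray, ks: np.ndarray, eps: float = 1e-6
) -> ParametricNull:
    """Maximum-likelihood location-scale-shape fit of the null magnitudes."""
    z = _logit(np.asarray(magnitudes, dtype=float), eps)
    x = np.log(np.asarray(ks, dtype=float))

    def nll(theta):
        b0, b1, s0, s1, la, lb = theta
        loc = b0 + b1 * x
        scale = np.exp(np.clip(s0 + s1 * x, -10, 5))
        a, b = np.exp(np.clip(la, -3, 4)), np.exp(np.clip(lb, -3, 4))
        with np.errstate(all="ignore"):
            ll = stats.jf_skew_t.logpdf(z, a, b, loc=loc, scale=scale)
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -float(ll.sum())

    from scipy.optimize import minimize

    x0 = np.array([float(np.median(z)), 0.0, float(np.log(np.std(z) + 1e-6)), 0.0, 0.5, 0.5])
    res = minimize(nll, x0, method="Nelder-Mead", options={"maxiter": 4000, "fatol": 1e-8})
    return ParametricNull(res.x, eps)


# ---------------------------------------------------------------------------
# Evidence combination and ranking
# ---------------------------------------------------------------------------


def combine_fisher(pvalues, null_size: int | None = None) -> tuple[float, float]:
    """Fisher's summary statistic X = -2 sum ln p_i with the chi-square
    upper tail on 2m degrees of freedom.  Zero p-values are clamped to the
    smoothing floor 1/(null_size+1) with a warning."""
    ps = np.asarray([p for p in np.atleast_1d(pvalues) if np.isfinite(p)], dtype=float)
    if ps.size == 0:
        return np.nan, np.nan
    if np.any(ps <= 0):
        floor = 1.0 / ((null_size or 10**6) + 1)
        warnings.warn(f"p=0 clamped to {floor:g} before Fisher combination")
        ps = np.maximum(ps, floor)
    if np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * float(np.log(ps).sum())
    return x, float(stats.chi2.sf(x, df=2 * ps.size))


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (NaN-aware)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.size, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        from statsmodels.stats.multitest import multipletests

        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def combined_feature_regions(
    promoter_regions: dict[str, np.ndarray], body_regions: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Whole-gene feature: the ordered union of promoter and body regions."""
    out = {}
    for gene in promoter_regions.keys() | body_regions.keys():
        a = promoter_regions.get(gene, np.zeros(0, dtype=np.int64))
        b = body_regions.get(gene, np.zeros(0, dtype=np.int64))
        out[gene] = np.unique(np.concatenate([a, b]))
    return out


def gene_table_for_comparison(
    features: pd.DataFrame, null: NullModel, comparison_id: str
) -> pd.DataFrame:
    """Per-gene summary for one comparison.

    The gene-level p is the empirical p of the whole-gene ("combined")
    feature, calibrated against kind- and K-matched reference-pair nulls; the
    Fisher combination of the promoter and body feature p-values is reported
    alongside (``fisher_p``).  BH q-values are computed on the gene p across
    all scorable genes.
    """
    features = features.copy()
    features["p_value"] = feature_pvalues(features, null)
    wide = features.pivot_table(
        index="gene_id",
        columns="kind",
        values=["K", "jsd_magnitude", "p_value"],
        aggfunc="first",
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index()
    m_null = max(len(v) for v in null.strata.values())
    fisher = []
    for rec in wide.itertuples(index=False):
        ps = [
            getattr(rec, f"p_value_{kind}", np.nan)
            for kind in ("promoter", "body")
        ]
        ps = [p for p in ps if np.isfinite(p)]
        fisher.append(combine_fisher(ps, m_null)[1] if ps else np.nan)
    wide["fisher_p"] = fisher
    if "p_value_combined" in wide.columns:
        wide["p_value"] = wide["p_value_combined"]
        wide["jsd_magnitude"] = wide.get("jsd_magnitude_combined")
    else:  # no combined features supplied: fall back to the Fisher summary
        wide["p_value"] = wide["fisher_p"]
    wide["q_value"] = benjamini_hochberg(wide["p_value"].to_numpy())
    wide.insert(1, "comparison", comparison_id)
    return wide


def rank_genes(
    per_comparison: dict[str, pd.DataFrame], fdr: float = 0.05
) -> pd.DataFrame:
    """Combine per-comparison gene tables into one ranked list.

    Cross-comparison evidence is Fisher-combined; the primary sort is the
    combined p, with ties broken by the geometric mean of the per-comparison
    p-value ranks (rank product).  BH is applied per comparison and to the
    combined p; genes unscorable everywhere are dropped.
    """
    merged: pd.DataFrame | None = None
    for cid, tbl in per_comparison.items():
        cols = {
            c: f"{c}_{cid}"
            for c in tbl.columns
            if c not in ("gene_id", "comparison")
        }
        t = tbl.drop(columns=["comparison"], errors="ignore").rename(columns=cols)
        merged = t if merged is None else merged.merge(t, on="gene_id", how="outer")
    assert merged is not None
    comp_ids = list(per_comparison)
    pcols = [f"p_value_{cid}" for cid in comp_ids]
    merged = merged.dropna(subset=pcols, how="all").reset_index(drop=True)

    ranks = np.full((len(merged), len(comp_ids)), np.nan)
    for j, cid in enumerate(comp_ids):
        p = merged[f"p_value_{cid}"].to_numpy(dtype=float)
        mask = np.isfinite(p)
        r = np.full(p.size, np.nan)
        r[mask] = stats.rankdata(p[mask], method="average")
        ranks[:, j] = r
        merged[f"rank_{cid}"] = r
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        merged["rank_product"] = np.exp(np.nanmean(np.log(ranks), axis=1))

    fisher = [
        combine_fisher([p for p in row if np.isfinite(p)])[1]
        for row in merged[pcols].to_numpy()
    ]
    merged["combined_p"] = fisher
    merged["combined_q"] = benjamini_hochberg(merged["combined_p"].to_numpy())
    merged["significant"] = merged["combined_q"] < fdr
    merged = merged.sort_values(
        ["combined_p", "rank_product", "gene_id"], ignore_index=True
    )
    merged["rank"] = np.arange(1, len(merged) + 1)
    return merged


def top_genes(ranked: pd.DataFrame, n: int = 500) -> list[str]:
    """Top-n genes of a ranked table (the conventional top-500 selection for
    over-representation analysis)."""
    return ranked["gene_id"].head(n).tolist()
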