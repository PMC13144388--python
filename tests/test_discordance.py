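"""JSD primitives, null construction, p-value calibration machinery, and
gene ranking."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methscape import discordance as D
from methscape.landscape import LevelDistribution, RegionLevels


class TestJSD:
    def test_identical_distributions_give_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert D.jsd(p, p) == 0.0

    def test_disjoint_supports_give_one(self):
        assert D.jsd(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # P=(1,0), Q=(1/2,1/2), M=(3/4,1/4):
        # D(P,M) = log2(4/3); D(Q,M) = .5 log2(2/3) + .5 log2(2)
        expected = np.sqrt(0.5 * (np.log2(4 / 3) + 0.5 * np.log2(2 / 3) + 0.5))
        assert D.jsd(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.5579, abs=1e-4)

    def test_level_distribution_interface_and_support_check(self):
        p = LevelDistribution(1, np.array([0.3, 0.7]))
        q = LevelDistribution(2, np.array([0.2, 0.3, 0.5]))
        with pytest.raises(ValueError, match="support"):
            D.jsd(p, q)
        assert D.jsd(p, p) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 8))
    def test_symmetry_and_bounds(self, seed, n):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(n))
        q = rng.dirichlet(np.ones(n))
        v = D.jsd(p, q)
        assert v == pytest.approx(D.jsd(q, p), abs=1e-12)
        assert 0.0 <= v <= 1.0 + 1e-12


class TestMagnitude:
    def test_constant_values_idempotent(self):
        assert D.jsd_magnitude([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_hand_value(self):
        assert D.jsd_magnitude([0.6, 0.8]) == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_bounded_by_max(self):
        rng = np.random.default_rng(0)
        v = rng.random(17)
        assert D.jsd_magnitude(v) <= v.max() + 1e-12

    def test_order_invariant(self):
        v = [0.1, 0.5, 0.9, 0.2]
        assert D.jsd_magnitude(v) == D.jsd_magnitude(v[::-1])

    def test_empty_unscorable(self):
        with pytest.raises(ValueError):
            D.jsd_magnitude([])


def _levels_from_tracks(dists: dict[int, np.ndarray], n_regions: int) -> RegionLevels:
    mml = np.full(n_regions, np.nan)
    nme = np.full(n_regions, np.nan)
    ncp = np.zeros(n_regions, dtype=np.int32)
    for rid, p in dists.items():
        d = LevelDistribution(p.size - 1, p)
        mml[rid], nme[rid], ncp[rid] = d.mml, d.nme, p.size - 1
    return RegionLevels(mml, nme, ncp, dists)


class TestScoring:
    def test_identical_groups_average_mode_score_zero(self, small_cohort):
        part = small_cohort.partition
        sids = small_cohort.groups["young"]
        levels = [
            D.sample_region_levels(small_cohort.samples[s], part) for s in sids
        ]
        feature_regions = {"combined": {"g": np.arange(40, dtype=np.int64)}}
        feats, track = D.score_comparison(
            [small_cohort.samples[s] for s in sids],
            [small_cohort.samples[s] for s in sids],
            part,
            feature_regions,
            mode="average",
            sample_levels=(levels, levels),
        )
        assert np.nanmax(track) == pytest.approx(0.0, abs=1e-12)
        assert feats["jsd_magnitude"].dropna().max() == pytest.approx(0.0, abs=1e-12)

    def test_unscorable_feature_reported_with_k_zero(self):
        track = np.full(10, np.nan)
        feats = D.score_features(track, {"g": np.array([0, 1])}, "promoter")
        assert feats.loc[0, "K"] == 0 and np.isnan(feats.loc[0, "jsd_magnitude"])

    def test_missing_regions_reduce_k(self):
        track = np.array([0.5, np.nan, 0.5, 0.1])
        feats = D.score_features(track, {"g": np.arange(4)}, "body")
        assert feats.loc[0, "K"] == 3


class TestNull:
    def _toy_levels(self, rng, n_regions=300, n=3):
        dists = {}
        for rid in range(n_regions):
            p = rng.dirichlet(np.ones(4))
            dists[rid] = p
        return _levels_from_tracks(dists, n_regions)

    def test_three_references_make_three_pairs(self):
        rng = np.random.default_rng(1)
        levels = [self._toy_levels(rng) for _ in range(3)]

        class FakePartition:
            n_regions = 300

        fr = {"combined": {f"g{i}": np.arange(i * 10, i * 10 + 10, dtype=np.int64) for i in range(30)}}
        null = D.build_null(levels, FakePartition(), fr, min_per_bin=10)
        assert null.n_pairs == 3

    def test_single_reference_rejected(self):
        with pytest.raises(ValueError, match="2 reference"):
            D.build_null([None], None, {})

    def test_pvalue_smoothing_and_ties(self):
        null = D.NullModel(
            bin_edges=((1, np.inf),),
            strata={("combined", 0): np.sort(np.array([0.1, 0.2, 0.3, 0.4, 0.5]))},
            bin_map={("combined", 0): ("combined", 0)},
            n_pairs=1,
        )
        m = 5
        # score above every null value
        assert D.feature_pvalue(0.9, 3, null) == pytest.approx(1 / (m + 1))
        # score below every null value
        assert D.feature_pvalue(0.01, 3, null) == pytest.approx(1.0)
        # tie with the unique maximum counts as >=
        assert D.feature_pvalue(0.5, 3, null) == pytest.approx(2 / (m + 1))
        # median of the null
        assert D.feature_pvalue(0.3, 3, null) == pytest.approx(4 / (m + 1))

    def test_k_bin_merging_forward(self):
        rng = np.random.default_rng(2)
        levels = [self._toy_levels(rng, n_regions=400) for _ in range(2)]

        class FakePartition:
            n_regions = 400

        # features with K=2 (sparse bin) and K=30 (dense bin)
        fr = {
            "combined": {
                **{f"s{i}": np.array([i * 2, i * 2 + 1], dtype=np.int64) for i in range(3)},
                **{f"b{i}": np.arange(100 + i * 30, 130 + i * 30, dtype=np.int64) for i in range(9)},
            }
        }
        null = D.build_null(levels, FakePartition(), fr, min_per_bin=5)
        # the K=2 bin (3 values < 5) merged forward into a nonempty stratum
        assert D.feature_pvalue(0.5, 2, null) > 0

    def test_parametric_null_recovers_tail(self):
        rng = np.random.default_rng(3)
        ks = rng.integers(5, 40, size=2000)
        mags = 1 / (1 + np.exp(-(rng.standard_t(8, 2000) * 0.3 - 2.0 + 0.1 * np.log(ks))))
        pn = D.fit_parametric_null(mags, ks)
        # p decreasing in score at fixed K
        ps = [pn.pvalue(s, 20) for s in (0.05, 0.1, 0.2, 0.4)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        # roughly calibrated in the bulk
        med = np.median(mags[ks == 20]) if (ks == 20).any() else np.median(mags)
        assert 0.2 < pn.pvalue(float(med), 20) < 0.8


class TestCombination:
    def test_all_ones(self):
        x, p = D.combine_fisher([1.0, 1.0, 1.0])
        assert x == 0.0 and p == pytest.approx(1.0)

    def test_two_point_oh_fives(self):
        x, p = D.combine_fisher([0.05, 0.05])
        assert x == pytest.approx(-2 * np.log(0.05) * 2, abs=1e-9)
        assert x == pytest.approx(11.98, abs=0.01)
        assert p == pytest.approx(stats.chi2.sf(x, 4), abs=1e-12)
        assert p == pytest.approx(0.0175, abs=5e-4)

    def test_single_p_identity(self):
        _, p = D.combine_fisher([0.37])
        assert p == pytest.approx(0.37, abs=1e-12)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            _, p = D.combine_fisher([0.0, 0.5], null_size=99)
        assert np.isfinite(p) and p > 0


class TestBHAndRanking:
    def test_bh_step_up_by_hand(self):
        q = D.benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_bh_monotone_in_p(self):
        rng = np.random.default_rng(4)
        p = rng.random(50)
        q = D.benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_single_gene(self):
        tbl = pd.DataFrame({"gene_id": ["g"], "p_value": [0.2], "q_value": [0.2]})
        ranked = D.rank_genes({"c1": tbl})
        assert ranked.loc[0, "rank"] == 1
        assert ranked.loc[0, "combined_q"] == pytest.approx(0.2)

    def test_tie_break_by_rank_product(self):
        # identical combined p; order determined by per-comparison ranks
        t1 = pd.DataFrame({"gene_id": ["a", "b"], "p_value": [0.5, 0.5], "q_value": [0.5, 0.5]})
        t2 = pd.DataFrame({"gene_id": ["a", "b"], "p_value": [0.9, 0.1], "q_value": [0.9, 0.1]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranked = D.rank_genes({"c1": t1, "c2": t2})
        assert ranked.loc[ranked["rank"] == 1, "gene_id"].item() == "b"

    def test_combined_feature_regions_union(self):
        prom = {"g": np.array([1, 2, 3], dtype=np.int64)}
        body = {"g": np.array([3, 4], dtype=np.int64), "h": np.array([9], dtype=np.int64)}
        comb = D.combined_feature_regions(prom, body)
        assert comb["g"].tolist() == [1, 2, 3, 4]
        assert comb["h"].tolist() == [9]
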