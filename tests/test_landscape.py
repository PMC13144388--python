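"""Ising landscape fitting and level distributions against brute-force
enumeration and closed forms."""

import numpy as np
import pytest

from methscape import _ising
from methscape.genome_io import ReadMatrix, partition_genome
from methscape.landscape import (
    DEFAULT_STARTS,
    IsingParameters,
    LevelDistribution,
    enumerate_configurations,
    enumerate_level_distribution,
    enumerate_read_log_likelihood,
    fit_window,
    ising_log_likelihood,
    level_distribution,
    mml,
    nme,
    window_level_distributions,
)

from conftest import make_annotation


def random_window(rng, n_cpgs, length=3000):
    pos = np.sort(rng.choice(np.arange(10, length - 10), size=n_cpgs, replace=False))
    ann = make_annotation({"chr1": length}, {"chr1": pos})
    return partition_genome(ann).windows[0]


def random_reads(rng, n_cpgs, n_reads, max_span=5):
    reads = []
    for _ in range(n_reads):
        span = int(rng.integers(1, min(max_span, n_cpgs) + 1))
        start = int(rng.integers(0, n_cpgs - span + 1))
        reads.append((start, rng.integers(0, 2, size=span).astype(np.int8)))
    return ReadMatrix.from_reads(0, n_cpgs, reads)


class TestLikelihood:
    def test_matches_enumeration_on_random_windows(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(2, 11))
            win = random_window(rng, n)
            params = IsingParameters(*rng.uniform([-3, -10, -2], [3, 10, 2]))
            rm = random_reads(rng, n, 8)
            ll = ising_log_likelihood(params, rm, win)
            ref = enumerate_read_log_likelihood(params, rm, win)
            assert ll == pytest.approx(ref, abs=1e-10)

    def test_gamma_zero_is_independent_bernoulli(self):
        rng = np.random.default_rng(1)
        win = random_window(rng, 6)
        params = IsingParameters(0.7, -3.0, 0.0)
        rm = random_reads(rng, 6, 10)
        a = params.alpha + params.beta * win.rho
        p_site = np.exp(a) / (np.exp(a) + np.exp(-a))
        expected = 0.0
        for r in range(rm.n_reads):
            seg = rm.flat[rm.offsets[r] : rm.offsets[r + 1]]
            for k, x in enumerate(seg):
                p = p_site[rm.starts[r] + k]
                expected += np.log(p if x else 1 - p)
        assert ising_log_likelihood(params, rm, win) == pytest.approx(expected, abs=1e-10)

    def test_full_coverage_read_is_configuration_probability(self):
        rng = np.random.default_rng(2)
        win = random_window(rng, 3)
        params = IsingParameters(0.5, 1.0, 0.8)
        config = np.array([1, 0, 1], dtype=np.int8)
        rm = ReadMatrix.from_reads(0, 3, [(0, config)])
        probs = enumerate_configurations(params, win)
        idx = int("".join(map(str, config)), 2)
        assert ising_log_likelihood(params, rm, win) == pytest.approx(
            np.log(probs[idx]), abs=1e-10
        )

    def test_empty_read_set_is_zero(self, single_window):
        rm = ReadMatrix.from_reads(0, single_window.n_cpgs, [])
        assert ising_log_likelihood(IsingParameters(1, 0, 1), rm, single_window) == 0.0

    def test_non_finite_parameters_rejected(self, single_window):
        rm = ReadMatrix.from_reads(0, single_window.n_cpgs, [(0, np.array([1], dtype=np.int8))])
        with pytest.raises(ValueError, match="finite"):
            ising_log_likelihood(IsingParameters(np.nan, 0, 0), rm, single_window)


class TestLevelDistribution:
    def test_matches_enumeration_all_regions(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(2, 11))
            win = random_window(rng, n)
            params = IsingParameters(*rng.uniform([-3, -10, -2], [3, 10, 2]))
            for j in range(20):
                d = level_distribution(params, win, j)
                ref = enumerate_level_distribution(params, win, j)
                if d is None:
                    assert ref is None
                    continue
                np.testing.assert_allclose(d.probabilities, ref.probabilities, atol=1e-10)
                assert d.mml == pytest.approx(ref.mml, abs=1e-10)
                assert d.nme == pytest.approx(ref.nme, abs=1e-10)

    def test_zero_field_zero_coupling_is_fair_binomial(self):
        from scipy.stats import binom

        rng = np.random.default_rng(4)
        win = random_window(rng, 8)
        params = IsingParameters(0.0, 0.0, 0.0)
        for j in range(20):
            d = level_distribution(params, win, j)
            if d is None:
                continue
            np.testing.assert_allclose(
                d.probabilities, binom.pmf(np.arange(d.n_cpgs + 1), d.n_cpgs, 0.5), atol=1e-10
            )

    def test_strong_positive_field_gives_point_mass_at_one(self):
        rng = np.random.default_rng(5)
        win = random_window(rng, 5)
        dists = window_level_distributions(IsingParameters(12.0, 0.0, 0.0), win)
        for d in dists:
            if d is None:
                continue
            assert d.probabilities[-1] == pytest.approx(1.0, abs=1e-6)
            assert d.mml == pytest.approx(1.0, abs=1e-6)
            assert d.nme == pytest.approx(0.0, abs=1e-5)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(6)
        win = random_window(rng, 10)
        params = IsingParameters(2.0, 5.0, -1.0)
        for d in window_level_distributions(params, win):
            if d is not None:
                assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-9)


class TestMMLNME:
    def test_uniform_has_maximal_entropy(self):
        d = LevelDistribution(4, np.full(5, 0.2))
        assert nme(d) == pytest.approx(1.0)
        assert mml(d) == pytest.approx(0.5)

    def test_point_mass_has_zero_entropy(self):
        d = LevelDistribution(4, np.array([0, 0, 1.0, 0, 0]))
        assert nme(d) == 0.0
        assert mml(d) == pytest.approx(0.5)

    def test_hand_computed_example(self):
        d = LevelDistribution(1, np.array([0.25, 0.75]))
        assert mml(d) == pytest.approx(0.75)
        h = -(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75))
        assert nme(d) == pytest.approx(h, abs=1e-12)
        assert nme(d) == pytest.approx(0.8113, abs=1e-4)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            LevelDistribution(2, np.array([0.5, 0.6, 0.2]))


class TestFit:
    def test_independent_site_alpha_closed_form(self):
        rng = np.random.default_rng(42)
        pos = np.arange(50, 2990, 140)
        ann = make_annotation({"chr1": 3000}, {"chr1": pos})
        win = partition_genome(ann).windows[0]
        n = win.n_cpgs
        reads, n_obs = [], 0
        while n_obs < 2000:
            st = int(rng.integers(0, n - 3))
            states = (rng.random(4) < 0.8).astype(np.int8)
            reads.append((st, states))
            n_obs += 4
        rm = ReadMatrix.from_reads(0, n, reads)
        fit = fit_window(rm, win, fixed={"beta": 0.0, "gamma": 0.0})
        assert fit.estimated and fit.converged
        assert fit.params.alpha == pytest.approx(0.5 * np.log(4), abs=0.05)

    def test_all_methylated_hits_boundary(self):
        rng = np.random.default_rng(7)
        win = random_window(rng, 10)
        rm = ReadMatrix.from_reads(0, 10, [(0, np.ones(10, dtype=np.int8))] * 20)
        fit = fit_window(rm, win)
        assert fit.at_boundary
        assert fit.params.alpha == pytest.approx(5.0, abs=1e-2)

    def test_too_few_reads_not_estimated(self, single_window):
        rm = ReadMatrix.from_reads(0, single_window.n_cpgs, [(0, np.array([1], dtype=np.int8))])
        fit = fit_window(rm, single_window)
        assert not fit.estimated and fit.params is None

    def test_more_data_never_hurts_fit_at_its_own_optimum(self):
        """Optimizer sanity: the parameters fitted on the full read set score
        the full set at least as well as parameters fitted on a subset."""
        rng = np.random.default_rng(8)
        win = random_window(rng, 12)
        truth = IsingParameters(0.4, 0.0, 0.3)
        a, c = truth.fields(win)
        reads = []
        for _ in range(60):
            cfg = _ising.sample_chain(a, c, rng.random(12))
            st = int(rng.integers(0, 9))
            reads.append((st, cfg[st : st + 4]))
        small = ReadMatrix.from_reads(0, 12, reads[:30])
        big = ReadMatrix.from_reads(0, 12, reads)
        fit_small = fit_window(small, win)
        fit_big = fit_window(big, win)
        ll_big_at_small = ising_log_likelihood(fit_small.params, big, win)
        assert fit_big.log_likelihood >= ll_big_at_small - 1e-6

    def test_recovery_at_origin(self):
        """1,000 full-coverage reads at the maximum-entropy point: alpha and
        gamma recover near 0 (the density covariate is nearly constant within
        a window, so beta is checked on the field scale it acts through)."""
        rng = np.random.default_rng(9)
        pos = np.arange(75, 3000, 150)
        ann = make_annotation({"chr1": 3000}, {"chr1": pos})
        win = partition_genome(ann).windows[0]
        n = win.n_cpgs
        truth = IsingParameters(0.0, 0.0, 0.0)
        a, c = truth.fields(win)
        reads = [(0, _ising.sample_chain(a, c, rng.random(n))) for _ in range(1000)]
        rm = ReadMatrix.from_reads(0, n, reads)
        fit = fit_window(rm, win)
        assert abs(fit.params.alpha + fit.params.beta * win.rho.mean()) < 0.15
        assert abs(fit.params.gamma) < 0.15

    def test_region_level_recovery_over_many_windows(self):
        """Median |exact - estimated| region NME <= 0.05 and MML <= 0.03 over
        200 simulated windows at default coverage."""
        from methscape.landscape import fit_all_windows, region_level_table
        from methscape.synthetic_data import (
            ToyGenomeConfig,
            make_toy_genome,
            null_effects,
            design_landscapes,
            simulate_reads,
            ground_truth_table,
        )

        cfg = ToyGenomeConfig(
            n_chromosomes=1, chrom_length=600_000, n_genes=60, seed=21
        )
        ann = make_toy_genome(cfg)
        design = design_landscapes(ann, null_effects({"young": 1}), seed=22)
        mats = simulate_reads(design.params["young"], design.partition, coverage=10, read_span=4, seed=23)
        fits = fit_all_windows(mats, design.partition)
        est = region_level_table(fits, design.partition)
        gt = ground_truth_table(design)
        rid = gt["region_id"].to_numpy()
        mml_err = np.abs(est.mml[rid] - gt["mml"].to_numpy())
        nme_err = np.abs(est.nme[rid] - gt["nme"].to_numpy())
        mml_err = mml_err[~np.isnan(mml_err)]
        nme_err = nme_err[~np.isnan(nme_err)]
        assert np.median(nme_err) <= 0.05
        assert np.median(mml_err) <= 0.03
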