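"""Toy-genome generation, landscape design, and exact Ising read simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from methscape import _ising
from methscape.landscape import IsingParameters, enumerate_configurations
from methscape.genome_io import partition_genome
from methscape.synthetic_data import (
    EffectDesign,
    ToyGenomeConfig,
    design_landscapes,
    ground_truth_table,
    make_toy_genome,
    null_effects,
    simulate_reads,
)

from conftest import make_annotation

SMALL = ToyGenomeConfig(
    n_chromosomes=1, chrom_length=120_000, n_genes=10, seed=5,
    lock_intervals=(("chr1", 10_000, 40_000),),
)


class TestToyGenome:
    def test_deterministic_in_seed(self):
        a1 = make_toy_genome(SMALL)
        a2 = make_toy_genome(SMALL)
        np.testing.assert_array_equal(a1.cpg_positions["chr1"], a2.cpg_positions["chr1"])
        pd.testing.assert_frame_equal(a1.genes, a2.genes)
        for k in a1.region_sets:
            pd.testing.assert_frame_equal(a1.region_sets[k], a2.region_sets[k])

    def test_no_genes_degenerate(self):
        ann = make_toy_genome(ToyGenomeConfig(n_chromosomes=1, chrom_length=50_000, n_genes=0, seed=1))
        assert len(ann.genes) == 0
        assert ann.n_cpgs > 0

    def test_cpg_count_near_expectation(self):
        # length/spacing CpGs expected; allow a generous Poisson-scale band
        ann = make_toy_genome(ToyGenomeConfig(n_chromosomes=2, chrom_length=1_000_000, seed=2, n_genes=0))
        expected = 2 * 1_000_000 / 100
        assert abs(ann.n_cpgs - expected) < 6 * np.sqrt(expected)

    def test_genes_non_overlapping_within_chromosome(self):
        ann = make_toy_genome(SMALL)
        g = ann.genes.sort_values("start")
        assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_infeasible_placement_raises(self):
        with pytest.raises(ValueError, match="cannot place"):
            make_toy_genome(ToyGenomeConfig(n_chromosomes=1, chrom_length=30_000, n_genes=50, seed=1))

    def test_blocks_confined_to_locks(self):
        ann = make_toy_genome(SMALL)
        locks = ann.region_sets["locks"]
        for b in ann.region_sets["blocks"].itertuples(index=False):
            inside = (
                (locks["chrom"] == b.chrom)
                & (locks["start"] <= b.start)
                & (locks["end"] >= b.end)
            )
            assert inside.any()

    def test_lock_validation(self):
        with pytest.raises(ValueError, match="out of bounds"):
            ToyGenomeConfig(chrom_length=10_000, lock_intervals=(("chr1", 0, 20_000),))
        with pytest.raises(ValueError, match="overlap"):
            ToyGenomeConfig(
                chrom_length=100_000,
                lock_intervals=(("chr1", 0, 20_000), ("chr1", 10_000, 30_000)),
            )

    def test_prc2_targets_are_island_promoters(self):
        ann = make_toy_genome(SMALL)
        island_genes = set(ann.region_sets["cpg_islands"]["name"])
        assert set(ann.region_sets["prc2_targets"]["name"]) <= island_genes


class TestLandscapeDesign:
    def test_null_design_makes_groups_identical(self):
        ann = make_toy_genome(SMALL)
        design = design_landscapes(ann, null_effects(), seed=3)
        p_y = design.params["young"]
        for g in ("old", "treated"):
            for widx, p in design.params[g].items():
                assert p == p_y[widx]

    def test_full_reversal_matches_young_at_prc2_windows(self):
        ann = make_toy_genome(SMALL)
        eff = EffectDesign(treated_reversal_fraction=1.0)
        design = design_landscapes(ann, eff, seed=3)
        prc2 = design.window_classes.query("is_prc2")["window_index"]
        assert len(prc2)
        for widx in prc2:
            assert design.params["treated"][widx] == design.params["young"][widx]

    def test_total_disorder_shift_gives_maximum_entropy_windows(self):
        """Scaling parameters by 0 at target windows leaves a = c = 0, the
        entropy-maximizing landscape: every configuration equally likely
        (verified by enumeration)."""
        ann = make_toy_genome(SMALL)
        eff = EffectDesign(
            global_alpha_shift={"young": 0.0, "old": 0.0, "treated": 0.0},
            prc2_alpha_shift=0.0,
            prc2_disorder_shift=1.0,
            lock_alpha_shift=0.0,
        )
        design = design_landscapes(ann, eff, seed=3)
        prc2 = design.window_classes.query("is_prc2")["window_index"].tolist()
        widx = prc2[0]
        p = design.params["old"][widx]
        assert p.alpha == 0 and p.beta == 0 and p.gamma == 0
        win = design.partition.windows[widx]
        if win.n_cpgs <= 10:
            probs = enumerate_configurations(p, win)
            np.testing.assert_allclose(probs, 1 / probs.size, atol=1e-12)

    def test_ground_truth_effect_directions(self, small_cohort):
        gt = ground_truth_table(small_cohort.design)
        piv = gt.pivot_table(index="region_id", columns="group", values=["mml", "nme"])
        # genome-wide hypomethylation with age, on average
        assert piv["mml"]["old"].mean() < piv["mml"]["young"].mean()
        # strict per-region gains at PRC2-target windows
        prc2 = small_cohort.design.window_classes.query("is_prc2")["window_index"]
        rids = gt[gt["window_index"].isin(prc2)]["region_id"].unique()
        sub = piv.loc[rids]
        assert (sub["mml"]["old"] > sub["mml"]["young"]).all()
        assert (sub["nme"]["old"] > sub["nme"]["young"]).all()
        # partial reversal: treated NME between old and young
        assert (
            (sub["nme"]["treated"] <= sub["nme"]["old"] + 1e-12)
            & (sub["nme"]["treated"] >= sub["nme"]["young"] - 1e-12)
        ).all()


class TestSimulateReads:
    def test_deterministic_in_seed(self):
        ann = make_toy_genome(SMALL)
        design = design_landscapes(ann, EffectDesign(), seed=3)
        m1 = simulate_reads(design.params["young"], design.partition, 5, 4, seed=9)
        m2 = simulate_reads(design.params["young"], design.partition, 5, 4, seed=9)
        assert m1.keys() == m2.keys()
        for w in m1:
            np.testing.assert_array_equal(m1[w].to_dense(), m2[w].to_dense())

    def test_zero_coverage_gives_empty_matrices(self):
        ann = make_toy_genome(SMALL)
        design = design_landscapes(ann, EffectDesign(), seed=3)
        mats = simulate_reads(design.params["young"], design.partition, 0, 4, seed=9)
        assert all(rm.n_reads == 0 for rm in mats.values())

    def test_invalid_arguments(self):
        ann = make_toy_genome(SMALL)
        design = design_landscapes(ann, EffectDesign(), seed=3)
        with pytest.raises(ValueError):
            simulate_reads(design.params["young"], design.partition, -1, 4)
        with pytest.raises(ValueError):
            simulate_reads(design.params["young"], design.partition, 5, 0)

    def test_independent_site_methylated_fraction(self):
        """gamma = 0 with field alpha: per-site methylation probability is
        e^a / (e^a + e^-a); the empirical fraction over ~10,000 site
        observations matches within 3 standard errors."""
        pos = np.arange(50, 3000, 30)
        ann = make_annotation({"chr1": 3000}, {"chr1": pos})
        part = partition_genome(ann)
        alpha = 0.6
        p_site = np.exp(alpha) / (np.exp(alpha) + np.exp(-alpha))
        params = {0: IsingParameters(alpha, 0.0, 0.0)}
        mats = simulate_reads(params, part, coverage=110, read_span=4, seed=13)
        rm = mats[0]
        frac = rm.flat.mean()
        n_obs = rm.flat.size
        assert n_obs >= 10_000
        se = np.sqrt(p_site * (1 - p_site) / n_obs)
        assert abs(frac - p_site) < 3 * se

    def test_sampler_matches_enumerated_ising_distribution(self):
        """Empirical configuration frequencies from 200,000 exact samples of
        a 5-CpG window agree with enumeration (chi-square GOF p > 0.001)."""
        pos = np.array([100, 220, 300, 450, 500])
        ann = make_annotation({"chr1": 3000}, {"chr1": pos})
        win = partition_genome(ann).windows[0]
        params = IsingParameters(0.3, 1.0, 0.5)
        a, c = params.fields(win)
        probs = enumerate_configurations(params, win)
        rng = np.random.default_rng(17)
        n = 200_000
        u = rng.random((n, 5))
        counts = np.zeros(32)
        for i in range(n):
            s = _ising.sample_chain(a, c, u[i])
            counts[int("".join(map(str, s)), 2)] += 1
        _, p = chisquare(counts, probs * n)
        assert p > 0.001


def test_effect_design_validation():
    with pytest.raises(ValueError, match="reversal_fraction"):
        EffectDesign(treated_reversal_fraction=1.5)
    with pytest.raises(ValueError, match="finite"):
        EffectDesign(prc2_alpha_shift=np.inf)
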