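import numpy as np
import pandas as pd
import pytest

from methscape.genome_io import AnnotationSet, partition_genome
from methscape.synthetic_data import EffectDesign, ToyGenomeConfig, simulate_cohort


def make_annotation(chrom_sizes, cpg_positions, genes=None, region_sets=None):
    genes = (
        pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"])
        if genes
        else pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"])
    )
    return AnnotationSet(
        chrom_sizes=dict(chrom_sizes),
        cpg_positions={c: np.asarray(p, dtype=np.int64) for c, p in cpg_positions.items()},
        genes=genes,
        region_sets=region_sets or {},
    )


@pytest.fixture
def single_window():
    """One 3-kb window with 8 irregularly spaced CpGs."""
    ann = make_annotation(
        {"chr1": 3000},
        {"chr1": [120, 340, 355, 900, 1400, 1410, 2250, 2900]},
    )
    return partition_genome(ann).windows[0]


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale cohort with the default effect pattern: 1 x 150 kb
    genome, 15 genes, 2 samples per group."""
    cfg = ToyGenomeConfig(
        n_chromosomes=1,
        chrom_length=150_000,
        n_genes=15,
        seed=7,
        lock_intervals=(("chr1", 15_000, 45_000),),
    )
    eff = EffectDesign(group_sizes={"young": 2, "old": 2, "treated": 2})
    return simulate_cohort(cfg, eff, coverage=8, read_span=4, seed=3)
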