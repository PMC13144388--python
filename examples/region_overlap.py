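"""Overlap statistics: region permutation test and gene-list Fisher test.

Asks whether the embedded hypomethylated blocks colocalize with LOCK
heterochromatin domains (they do, by construction) and whether two gene
lists overlap more than chance within a shared universe.
"""

import numpy as np

from methscape.enrichment import fisher_overlap, permutation_overlap
from methscape.synthetic_data import ToyGenomeConfig, make_toy_genome

ann = make_toy_genome(ToyGenomeConfig(seed=1))
blocks = ann.region_sets["blocks"]
locks = ann.region_sets["locks"]

res = permutation_overlap(blocks, locks, ann.chrom_sizes, n_perm=1000, seed=31)
print(
    f"blocks vs LOCKs: {res.observed}/{len(blocks)} blocks overlap a LOCK; "
    f"permutation mean {res.perm_mean:.2f}, z={res.z:.2f}, p={res.p_value:.4g}"
)

rng = np.random.default_rng(0)
universe = ann.genes["gene_id"].tolist()
list_a = list(rng.choice(universe, size=300, replace=False))
# list B shares half of A's genes
list_b = list_a[:150] + list(
    rng.choice(sorted(set(universe) - set(list_a)), size=150, replace=False)
)
ov = fisher_overlap(list_a, list_b, universe)
print(
    f"gene lists: 2x2 = [[{ov.a},{ov.b}],[{ov.c},{ov.d}]], "
    f"OR={ov.odds_ratio:.2f}, Fisher p={ov.p_value:.3g}"
)
print(
    "\nReading: blocks sit inside LOCKs, so the observed overlap exceeds every\n"
    "length- and chromosome-preserving random placement (z >> 2, p at the\n"
    "permutation floor); the constructed half-shared gene lists give an odds\n"
    "ratio well above 1."
)
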