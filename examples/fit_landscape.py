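"""Fit one window's Ising potential-energy landscape from simulated reads.

Simulates reads from a known (alpha, beta, gamma), fits the landscape by
maximum likelihood, and compares the exact and estimated methylation-level
summaries (MML, NME) of the window's 150-bp analysis regions.
"""

import numpy as np
import pandas as pd

from methscape.genome_io import AnnotationSet, partition_genome
from methscape.landscape import IsingParameters, fit_window, window_level_distributions
from methscape.synthetic_data import simulate_reads

rng = np.random.default_rng(0)
positions = np.sort(rng.choice(np.arange(20, 2980), size=30, replace=False))
annotation = AnnotationSet(
    {"chr1": 3000},
    {"chr1": positions.astype(np.int64)},
    pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"]),
)
partition = partition_genome(annotation)
window = partition.windows[0]

truth = IsingParameters(alpha=-0.8, beta=0.0, gamma=0.4)
reads = simulate_reads({0: truth}, partition, coverage=40, read_span=4, seed=11)[0]
fit = fit_window(reads, window)

print(f"window: {window.n_cpgs} CpGs, {reads.n_reads} reads")
print(f"truth:    alpha={truth.alpha:+.3f} gamma={truth.gamma:+.3f}")
print(f"estimate: alpha={fit.params.alpha:+.3f} gamma={fit.params.gamma:+.3f} "
      f"(converged={fit.converged}, loglik={fit.log_likelihood:.1f})")

rows = []
for j, (d_true, d_est) in enumerate(
    zip(window_level_distributions(truth, window), window_level_distributions(fit.params, window))
):
    if d_true is None:
        continue
    rows.append((j, d_true.n_cpgs, d_true.mml, d_est.mml, d_true.nme, d_est.nme))
table = pd.DataFrame(rows, columns=["region", "N", "mml_true", "mml_est", "nme_true", "nme_est"])
print("\nper-region summaries (exact vs estimated):")
print(table.round(3).to_string(index=False))
print(
    "\nReading: the fitted landscape reproduces the exact region-level MML\n"
    "and NME to a few hundredths at this coverage; a negative field gives a\n"
    "mostly unmethylated, low-entropy window."
)
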