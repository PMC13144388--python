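"""Rank genes by Jensen-Shannon discordance on a small simulated study.

Runs the full pipeline (simulate -> landscape -> rank -> compare -> overlap)
on a 1 x 300 kb cohort and prints the top-ranked genes with their JSD
magnitudes, empirical p-values and BH q-values, marking the embedded
PRC2-target genes.
"""

import tempfile

from methscape.pipeline import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    config = RunConfig.from_dict(
        dict(
            outdir=f"{tmp}/run",
            seed=2,
            coverage=8.0,
            n_permutations=500,
            genome=dict(
                n_chromosomes=1,
                chrom_length=300_000,
                n_genes=30,
                seed=7,
                lock_intervals=[["chr1", 30_000, 90_000]],
            ),
            effects=dict(group_sizes={"young": 3, "old": 3, "treated": 3}),
        )
    )
    result = run_pipeline(config)

prc2 = set(result.cohort.annotation.region_sets["prc2_targets"]["name"])
top = result.ranked.head(8).copy()
top["prc2_target"] = top["gene_id"].isin(prc2)
cols = ["rank", "gene_id", "combined_p", "combined_q", "rank_product", "prc2_target"]
print(f"{len(result.ranked)} genes ranked; {len(prc2)} embedded PRC2 targets\n")
print(top[cols].to_string(index=False))

sig = result.ranked[result.ranked["combined_q"] < 0.05]
hit = set(sig["gene_id"]) & prc2
print(f"\n{len(sig)} genes at combined q<0.05 across both comparisons; "
      f"{len(hit)}/{len(prc2)} embedded PRC2 targets among them")
print(
    "\nReading: genes whose promoters carry the designed old-specific\n"
    "methylation/entropy gain dominate the top of the ranking; their JSD\n"
    "magnitude exceeds anything the reference-pair null produces.  (At this\n"
    "miniature scale the empirical null holds only ~90 values per stratum, so\n"
    "p-values floor near 0.01; the full-scale study resolves far smaller p.)"
)
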