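# Pipeline configuration for a desk-scale demonstration run.
# All randomness flows from `seed`; the genome block mirrors ToyGenomeConfig
# and the effects block mirrors EffectDesign.
outdir: runs/demo
seed: 1
coverage: 8.0
read_span: 4
mode: pooled          # depth-matched pooled group comparison (default)
min_reads: 5
fdr: 0.05
top_n: 500
n_permutations: 1000
genome:
  n_chromosomes: 1
  chrom_length: 300000
  n_genes: 30
  mean_cpg_spacing: 100
  island_fraction_of_promoters: 0.7
  prc2_target_fraction: 0.08
  seed: 7
  lock_intervals:
    - [chr1, 30000, 90000]
effects:
  group_sizes: {young: 3, old: 3, treated: 3}
  global_alpha_shift: {young: 0.0, old: -0.25, treated: -0.25}
  prc2_alpha_shift: 0.55
  prc2_disorder_shift: 0.5
  lock_alpha_shift: -0.9
  treated_reversal_fraction: 0.8
comparisons:
  - {id: old_vs_young, test: old, reference: young}
  - {id: treated_vs_old, test: treated, reference: old}
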