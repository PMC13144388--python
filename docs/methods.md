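# Methods

## The window model

Each chromosome is tiled from coordinate 0 into consecutive, non-overlapping
3-kb estimation windows; a trailing partial window is dropped so every
window divides exactly into twenty 150-bp analysis regions.  Within a
window, the joint methylation state of the N member CpGs is a 1D Ising
chain on ±1 spins with per-site field `a_n = α + β·ρ_n` and nearest-neighbor
coupling `c_n = γ·100/max(d_n, 10)`.  The covariates are fixed, fully stated
constants: ρ_n counts CpGs within ±500 bp of site n (computed from the full
chromosome CpG map, so windows see their flanks' density) divided by 1000,
and d_n is the bp distance to the next CpG *within the window* — chains do
not couple across window boundaries, which is the model's independence
assumption, not a numerical shortcut.  CpG counts are strand-collapsed to
the forward-strand C of each dyad on ingestion; cytosine reports are 1-based
on disk and 0-based half-open internally (BED convention throughout).

All chain computations (partition function, per-read marginals, exact
sampling, level-distribution DP) use per-step renormalized transfer-matrix
messages, so fields up to the optimization bounds cannot overflow.  A
brute-force enumeration path over all 2^N configurations is kept in the
package as an independent reference and is compared against the
transfer-matrix path to 1e-10 in the tests.

## Likelihood and fitting

A read is a contiguous run of observed CpGs; its likelihood is the marginal
probability of the run under the window chain, obtained by multiplying the
prefix and suffix messages into the run's endpoints (cost O(N) per read).
The window's (α, β, γ) maximize the summed read log-likelihood via a
bounded, projected Nelder–Mead simplex run from four fixed starts
((0,0,0), (2,0,0.5), (−2,0,0.5), (0,0,−0.5)), bounds α∈[−5,5], β∈[−20,20],
γ∈[−5,5], function tolerance 1e-6, simplex tolerance 1e-4, at most 400
iterations per start; the best objective wins, ties broken by lowest start
index.  Parameters within 1e-3 of a bound flag the fit as boundary
(degenerate separation, e.g. all reads fully methylated).  Windows with
fewer than 5 reads (default `min_reads`) are flagged not-estimated and
propagate as missing for all their regions; nothing is imputed.

A caveat stated here because the tests exercise it: with realistic CpG
spacing, ρ is of order 0.01 and nearly constant within a window, so β is
very weakly identified relative to α.  Fitted β values are meaningful only
through the field scale β·ρ; distribution-level quantities (P_L, MML, NME)
are unaffected, which is what the recovery tests assert (median absolute
region error ≤ 0.05 NME, ≤ 0.03 MML at 10× coverage).

## Level distributions, MML, NME, JSD

For each analysis region the exact distribution of the methylation level is
computed by a forward DP over (spin, count of methylated CpGs inside the
region), marginalizing window CpGs outside the region.  MML is the mean of
that distribution; NME its Shannon entropy divided by log₂(N+1) (0·log 0≡0),
so NME is 1 exactly when all N+1 levels are equally likely and 0 exactly at
a point mass.  Regions with no CpGs are excluded.  The JSD between two
level distributions uses base-2 logs and is the square root of the
Jensen–Shannon divergence: 0 iff the distributions coincide, 1 iff their
supports are disjoint.

## Group comparison and the reference-derived null

A feature (promoter = TSS±2 kb clipped to the chromosome; body = the gene
minus promoter overlap; combined = their region union) is scored by the JSD
magnitude, the root mean square of the JSDs of its K covered regions;
regions missing on either side drop out and reduce K.

The default group-versus-group comparison is a **depth-matched pooled fit**:
each side's reads are pooled across its samples and Bernoulli-thinned with
keep probability 1/n, so the pooled depth is distributed exactly like a
single sample's (Poisson thinning).  The point of this construction is
calibration: the null is built by scoring every unordered pair of reference
samples with the same feature definitions, and a test comparison built from
two single-sample-depth virtual samples is statistically exchangeable with
those pairs under the no-effect hypothesis.  Group-averaged P_L
(`mode="average"`) and median-pairwise JSD (`mode="median-pair"`) are
available as alternatives; both use replicate information differently and
are *not* exchangeable with single-sample null pairs, so their p-values are
conservative under the null.

Null magnitudes are pooled across features and stratified by feature kind
and K-bin ({1–5, 6–10, 11–20, 21–40, ≥41}); bins with fewer than 200 values
merge forward (the trailing bin backward).  A feature's p-value is the
add-one-smoothed upper-tail rank `(r+1)/(m+1)` in its stratum, so the
smallest attainable p is 1/(m+1).  Stratified empirical calibration is
aggregate: across genes the p-values are uniform because each gene's test
score is exchangeable with its own contributions to the stratum mixture;
per-gene calibration is only as fine as the strata.  A parametric
refinement in the location-scale-shape spirit is provided
(`fit_parametric_null`): a Jones–Faddy skew-t on logit magnitudes with
location and log-scale linear in log K, fitted by maximum likelihood.  The
empirical null remains the default because it is assumption-free.

The gene-level p for one comparison is the combined-feature empirical p.
Fisher's summary statistic (−2Σln p against χ² with 2m df) is reported for
the promoter+body pair within a comparison (`fisher_p`) and is the
cross-comparison combiner for the final ranking; zero p-values are clamped
to the smoothing floor with a warning.  Genes are sorted by combined p with
ties broken by the geometric mean of per-comparison p ranks (rank product),
and BH q-values are computed per comparison and on the combined p; genes
with no scorable feature are excluded from the multiplicity count.

## Two-track comparative statistics

Per-sample genome-wide (or region-restricted) means of MML/NME feed a Welch
unequal-variance t test (the two-sample design has 3–5 animals per group;
Welch is the safer default when the variance equality is unstated), with
both two-sided and configured one-sided p reported.  In parallel, per-region
group-mean tracks feed a paired two-sided Wilcoxon signed-rank test with the
Hodges–Lehmann pseudo-median *e* of the differences: exact (median of all
Walsh averages, via an O(n log) bisection selection) up to 20,000 pairs, and
the median of 2,000,000 uniformly sampled Walsh pairs with a fixed seed
beyond that (agreement within 0.002 on 10,000-pair fixtures is tested).
Promoter CpG-island stratification computes per-promoter sample-level means
over island-overlapping regions, averages them into condition-level means,
and classifies ΔMML/ΔNME by the 5-percentage-point rule — read as 0.05
absolute on the [0,1] scale, since MML and NME are already proportions;
promoters without covered island regions are excluded.  Metagene profiles
scale gene bodies to 100 bins with ±2 kb unscaled flanks in 40 bins,
reversing minus-strand genes.  ChIP spike-in scaling divides by
exogenous-genome read counts, normalized so the least-deep sample has
factor 1.

## Overlap statistics

Gene-list overlaps use two-sided Fisher's exact tests on the 2×2 built
within an explicit universe (the common set of genes assessed in both
analyses; sex-chromosome genes are removed from universes involving
landscape-derived rankings because no landscape values are reported there).
The reported odds ratio is the sample cross-product ad/bc, with 0.5 added to
every cell only when a cell is zero.  Over-representation analysis is
one-sided hypergeometric per gene set with BH across the collection.  The
region permutation test re-places each query region uniformly within its own
chromosome, preserving lengths and chromosome assignment (placed regions may
overlap); the statistic is the count of query regions overlapping the target
set, p is add-one smoothed, and z is the observed count's distance from the
permutation mean in permutation SDs.  Uniform re-placement (rather than
circular rotation) is the stated randomization; it is fully specified and
reproduces the intended null of "same lengths, same chromosomes, random
positions".

## The synthetic generator

The generator emulates the data the likelihood assumes, with known truth:

* CpG maps with geometric inter-CpG spacing (default mean 100 bp, minimum
  dyad gap 2); non-overlapping stranded genes (default 2000 genes of
  2.5–4 kb on 2 × 5 Mb); CpG islands around 70% of promoters; PRC2 targets
  chosen among island promoters outside LOCKs (8% of genes); two LOCK
  domains per chromosome with four large hypomethylated block subintervals
  each.
* Baseline landscapes: methylated background (α ~ N(1.3, 0.3)),
  unmethylated island windows (α ~ N(−1.6, 0.25)), positive coupling
  (γ ~ N(0.25, 0.1) clipped ≥ 0.02 so entropy is monotone along the
  reversal path), β ~ N(0, 2).
* Effects: aged groups get α −0.25 genome-wide, α −0.9 inside blocks, and,
  at PRC2-target island windows, all parameters shrunk by 0.5 toward 0
  (disorder) plus α +0.55 (methylation gain); the treated group equals the
  aged state except at PRC2 windows, where it is pulled 0.8 of the way back
  toward young.  These magnitudes were chosen once so that the exact
  summaries reproduce the qualitative study pattern — mild global MML loss
  with NME gain, MML+NME gain at PRC2 promoters, partial reversal — at
  effect sizes detectable at 10× coverage with 3–5 replicates.
* Reads: per window, Poisson(coverage·N/read_span) reads (default coverage
  10, span 4 CpGs); each read exposes a contiguous run of an *exact* chain
  sample (forward-filter backward-sampling) at a uniform offset.  Randomness
  is counter-based per window so simulation order is irrelevant.

What the generator does **not** emulate: bisulfite conversion errors,
sequence context, SNPs, gapped or variable-length reads, cell-type mixtures,
batch effects — and, importantly, within-group biological heterogeneity
(samples of a group share one landscape, so between-sample variation is
purely read sampling).  Passing tests therefore demonstrate the correctness
and calibration of the statistical machinery under its own assumptions, not
performance on real WGBS data, where replicate heterogeneity would widen the
reference-pair null.

## Numerical and design choices

* All message passing renormalizes per step; enumeration subtracts the max
  energy before exponentiating.
* Level distributions are renormalized to sum to 1 within 1e-9; violations
  raise.
* Degenerate inputs: empty read sets give log-likelihood 0; windows with no
  CpGs are skipped with a notice; features with no covered regions are
  reported unscorable (K=0) rather than dropped silently; identical groups
  give all-zero JSD tracks.
* Pipeline runs are deterministic given the config seeds: per-sample,
  per-window, and per-comparison substreams derive from the master seed, and
  gzip outputs are written with a fixed timestamp so byte-level checksums
  reproduce.
* The canonical study sizes (2 × 5 Mb, 2000 genes, 12 samples, 10×
  coverage) keep a full run-all near seven minutes on one CPU while leaving
  every stage with thousands of features; the miniature examples run in
  seconds.

## Known limitations

* β is near-unidentifiable within single windows (see above); interpret
  fitted β only through β·ρ.
* The empirical null calibrates in aggregate per stratum, not per gene;
  genes with atypical local noise are mildly mis-calibrated relative to
  their stratum (the parametric refinement shares this limitation through
  its K-only covariate).
* Promoters of adjacent genes may share analysis regions at high gene
  density, inducing local dependence between neighboring genes' scores;
  BH's FDR control is robust to this positive dependence but gene-level
  p-values are not independent.
* Chains are independent across 3-kb windows; methylation correlation
  across window boundaries is not modeled.
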