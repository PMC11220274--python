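# Methods

`menstab` implements the co-occurrence-network workflow used in soil
microbiome surveys that compare community complexity and stability between
management regimes (e.g. continuous cropping vs crop rotation): abundance
tables → rank-correlation screening → random-matrix-theory (RMT) threshold
selection → signed networks → topology and degree-preserving null models →
module/role analysis, robustness and cohesion → group-contrast statistics.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic benchmark does and does not show.

## Input model and filtering

The central object is a taxa × samples matrix of non-negative counts
(zOTU/ASV tables), with optional per-sample group labels and per-taxon
lineages. Two upstream filters are retained:

- **Low-abundance filter** (`min_total`, default 8): a taxon whose total
  count across samples is below 8 is dropped (strict `<`, so a total of
  exactly 8 survives). This mirrors the denoising convention of discarding
  variants supported by fewer than 8 reads.
- **Prevalence filter** (`min_fraction`, default 0.5 in the CLI): a taxon
  must be detected in at least `ceil(min_fraction × n_samples)` samples.
  The majority-of-samples default is the convention of molecular-ecological
  network pipelines; it is configurable because surveys differ.

Environment tables (pH, TOC, SOM, TN, TP, TK, NO3-N, NH4-N, AP, AK) are
validated strictly: a missing value is an error, never imputed.

## Correlation screening

Associations are tie-corrected Spearman correlations between taxa across
samples (rank-then-Pearson with average ranks). Constant taxa are excluded
with a warning. By default the table is converted to relative abundances
first — the convention for sequencing counts. One subtlety: the
relative-abundance transform preserves cross-sample ranks only when all
samples have the same total (as they do for fixed-depth simulated counts);
for data already on an abundance scale, `normalize=False` correlates raw
values. Two taxa under compositional closure are perfectly anticorrelated by
construction, so correlation screening is only meaningful for tables with
many taxa.

## RMT threshold selection

The similarity threshold is chosen by the GOE→Poisson transition of the
thresholded matrix's eigenvalue spacing statistics:

1. For each candidate threshold `s` on a grid (default 0.30–0.99, step
   0.01), entries with |r| < s are zeroed and empty rows/columns dropped.
2. Eigenvalues of the retained matrix are *unfolded*: numerically equal
   eigenvalues (within 1e-8) are collapsed, and the cumulative spectral
   function is smoothed with a monotone cubic (PCHIP) through ~10 knots per
   100 eigenvalues; unfolded eigenvalues are the fitted cumulative counts.
3. Nearest-neighbour spacings (normalised to unit mean) are tested against
   the Poisson form P(d) = e^(−d) by a chi-square goodness-of-fit on bins of
   width 0.5 over [0, 3] plus an open tail bin, pooled so every expected
   count is ≥ 5; significance level 0.05. A noise-dominated matrix instead
   shows Wigner–Dyson level repulsion, P(d) = (πd/2)e^(−πd²/4).
4. The selected threshold is the smallest `s` that fits Poisson **and**
   whose larger evaluable thresholds stay Poisson, tolerating up to 20%
   isolated rejections in that tail. The tolerance is needed because the
   chi-square test falsely rejects at rate α under the Poisson null, so on a
   70-point grid a literal "all larger thresholds must fit" rule almost
   surely fails somewhere; treating those isolated rejections as the test's
   own type-I error makes the selection consistent. Thresholds retaining
   fewer than 30 distinct eigenvalues cannot be tested meaningfully and
   neither qualify nor veto.

Matrices with fewer than ~50 taxa trigger a warning (the spectrum is too
short for spacing statistics) and a fixed threshold override is available —
also the right tool when several networks must share one threshold for
comparability across groups.

On planted two-block data (two 50-taxon modules with latent correlation 0.9
over a 0.05 background, 200 taxa, 30 samples) the scan selects thresholds of
roughly 0.44–0.50, recovering ≥ 90% of planted pairs with ~1–3% of
non-planted pairs admitted (noise edges at n = 30 samples have a Spearman
null standard deviation of ≈ 0.19, which sets the noise floor the transition
tracks).

## Signed network and topology

An edge joins every pair with |r| ≥ s, carrying sign(r) and weight |r|;
taxa without any edge are dropped, so every node has degree ≥ 1. All
topological indices treat edges as unweighted and unsigned (signs matter
only for the positive-edge fraction and cohesion):

- avgK = 2L/n; density = 2L/(n(n−1)); mean local clustering (degree-<2
  nodes contribute 0); transitivity = 3 × triangles / connected triples.
- GD, the mean geodesic distance, averages over connected pairs only, so
  multi-component networks (the rule, not the exception, for sparse
  co-occurrence graphs) keep a finite GD.
- CD, Freeman degree centralization Σ(k_max − k_i)/((n−1)(n−2)); needs
  n ≥ 3.
- Power-law R²: OLS of log10(count of nodes with degree k) on log10(k) over
  observed degrees, no xmin search — the descriptive scale-free index
  commonly reported alongside these tables, not a maximum-likelihood fit.
- Modularity Q and module count come from Clauset–Newman–Moore greedy
  agglomeration (deterministic given the graph).

The null ensemble rewires the graph by Maslov–Sneppen double-edge swaps
(default 10 × L swaps, a standard mixing heuristic), rejecting self-loops
and parallel edges so each node's degree is preserved exactly; edge signs
are then redealt uniformly, preserving the global positive-edge count. A
graph with no legal swap (e.g. a triangle) is returned unchanged with a
warning. The ensemble summary reports mean ± sd of avgCC, GD and modularity
over (default) 100 replicates.

The small-world check flags a network when GD is within a factor (default
2×) of ln(n) **and** clustering exceeds the null-ensemble mean by 2 ensemble
standard deviations. The significance margin (rather than a bare ratio > 1)
exists because a degree-matched random graph exceeds its own ensemble mean
about half the time by chance.

## Node roles, robustness, cohesion

- **Zi–Pi roles.** Zi is the within-module degree z-score (standardised
  against the node's own module; a module with zero spread gives Zi = 0, so
  regular or singleton modules classify as non-hubs). Pi = 1 − Σ_m
  (k_i,m/k_i)². Cutoffs follow the Olesen convention: network hub (Zi > 2.5
  and Pi > 0.62), module hub (Zi only), connector (Pi only), else
  peripheral.
- **Robustness.** Each replicate removes ⌊f × n⌋ nodes uniformly at random
  (default f = 0.5, 100 replicates), then iteratively removes survivors
  whose degree has dropped to zero until a fixed point — the secondary-
  extinction step. Without it the statistic would be identically 1 − f;
  the cascading reading is what makes reported values like 0.28–0.31
  possible at 50% removal. The replicate value is survivors / original n.
- **Cohesion.** Each taxon's positive (negative) connectedness is the mean
  of its positive (negative) pairwise Pearson correlations on relative
  abundances, 0 when it has none; a sample's positive (negative) cohesion is
  the relative-abundance-weighted sum, guaranteed ≥ 0 (≤ 0). On data with
  no real associations the positive component converges to E[r | r > 0]
  (≈ 0.8/√n_samples — a function of sample count), while the *net*
  (positive + negative) cohesion cancels toward 0 as taxa accumulate; tests
  assert the net form. The Herren–McMahon-style taxon-shuffle null
  correction (subtract each pair's mean correlation over within-taxon
  abundance shuffles) is available via `null_iterations`, off by default.
- **Group contrast.** `stability_report` compares metric vectors between
  groups by two-sided Mann–Whitney (no normality assumption) with
  significance tiers 0.05/0.01/0.001; negative cohesion is compared on
  absolute values so "larger" reads as more intense competition.

## Diversity and permutation statistics

Richness, Chao1 (classic S_obs + F1²/(2F2); bias-corrected form when no
doubletons exist) and Shannon (natural log) per sample; Jaccard
(presence/absence) and Bray–Curtis (counts) distances; NMDS via SMACOF
(scikit-learn) with `n_starts` seeded restarts, reporting Kruskal stress-1
recomputed through isotonic regression with the primary (averaging)
treatment of ties, so the stress value does not depend on the optimiser's
internal normalisation.

PERMANOVA (Anderson's pseudo-F from squared distances), ANOSIM (rank-based
R), MRPP (weighted mean within-group distance δ, lower-tailed, with
chance-corrected A = 1 − δ_obs/mean δ_perm) and the Mantel test (upper-tail
correlation of lower-triangle vectors under simultaneous row/column
permutation) share one engine. Monte-Carlo p-values use the add-one
(Phipson–Smyth) rule and can never be 0; `n_perm="exhaustive"` enumerates
every distinct relabelling and returns the exact fraction, with the identity
labelling included.

## Synthetic communities

The generator plants known structure so every downstream stage has ground
truth: a latent Gaussian copula with block correlation (modules at
`within_module_rho`, off-blocks at `between_module_rho`), log-normal
marginals (`base_log_sd` 1.5 gives realistic dominance), multiplicative
group effects on chosen taxa, and fixed-depth multinomial counts, optionally
through a Dirichlet-multinomial layer (concentration = depth/dispersion;
`dispersion` default 1, 0 = exact multinomial so column sums equal the depth
exactly). Planted negative associations are sign-flipped block entries;
when flips break positive semi-definiteness the matrix is repaired by
eigenvalue clipping (with a warning), or an error is raised if
`psd_repair=False`. Soil variables are linear combinations of linked taxa's
log relative abundances plus Gaussian noise (`env_noise_sd` 0.3 relative to
the signal's spread); unlinked variables are pure noise.

The default design mirrors a two-regime survey: 10 "continuous" + 9
"rotation" samples, hundreds of taxa, four modules. The paired benchmark
scenarios differ **only** in module density and planted positive-association
probability: continuous-like (module sizes 10/10/8/8, within-ρ 0.75,
positive probability 0.6) vs rotation-like (16/16/13/13, within-ρ 0.85,
positive probability 0.95), 150 taxa, depth 50,000. With networks built at
a single consistent threshold (0.70) for comparability, the rotation-like
arm shows more links, a higher positive-edge fraction, higher robustness
and higher positive cohesion — the qualitative contrast the workflow is
designed to detect.

What passing these benchmarks does **not** show: real communities are not
Gaussian copulas (no phylogenetic structure, no true interaction dynamics,
no batch effects), sampling depth is uniform here but not in real runs, and
compositional closure is mild at these taxon counts. The benchmarks validate
the estimators and their calibration, not ecological truth.

## Problem sizes and numerical choices

Defaults used by the test suite and the acceptance script were chosen to
exercise every stage at desk scale: 150–200 taxa, 19–30 samples, 100
null/robustness replicates, 999 permutations (199 in calibration loops, 200
simulations per calibration), 10–20 generator seeds per contrast. Key
numerical conventions: eigenvalue degeneracy tolerance 1e-8 before spacing
computation; 1e-10 Cholesky jitter; add-one p-values; Wilcoxon/Mann–Whitney
for group contrasts; all RNG through `numpy.random.default_rng` with every
seed surfaced in results objects.

## Known limitations

- The RMT scan needs enough taxa (≥ ~50 retained) for spacing statistics;
  small communities should use a fixed threshold.
- Spacing-based selection tracks the sample-size-dependent noise floor
  (≈ 1/√n_samples), not the latent correlation scale; with few samples the
  selected threshold admits weak edges.
- Cohesion without null correction inherits the positive bias of
  E[r | r > 0]; comparisons between groups of equal sample size are
  unaffected, absolute values should be read with care.
- Greedy modularity is deterministic but not optimal; Q values are lower
  bounds on the best partition.
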