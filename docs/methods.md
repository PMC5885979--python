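# Methods

This note records the models and estimators implemented in `gmprnorm`,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic benchmarks do and do not establish.

## Size-factor estimators

### GMPR

For a feature-by-sample count table `c_ki` (q features, n samples), the
pairwise ratio of samples i and j is the median of `c_ki/c_kj` over the
shared support `{k : c_ki·c_kj ≠ 0}`, and the size factor is the geometric
mean of sample i's pairwise ratios, self-ratio `r_ii = 1` included:

    s_i = ( ∏_{j=1..n} r_ij )^{1/n}

Conventions that the formula leaves open, and how this implementation
resolves them:

* **Undefined pairs.** When two samples share fewer than `min_shared`
  nonzero features (default 2), `r_ij` is treated as undefined and dropped;
  the exponent becomes one over the number of *defined* ratios. A sample
  with no defined partner raises an error naming the sample rather than
  returning NaN. The cutoff guards against medians of one or two noisy
  ratios dominating the geometric mean.
* **Median.** Midpoint of the two central order statistics for even-sized
  shared sets. A consequence accepted as-is: `r_ij = 1/r_ji` holds exactly
  only for odd shared-set sizes, so both triangle entries are computed.
* **Numerics.** The geometric mean is accumulated in log space, so large n
  and extreme ratios cannot overflow. Complexity is O(n²q); no
  approximation for very large n is attempted.

On zero-free multiplicative data (columns `d_i·m`) every pairwise ratio is
`d_i/d_j` exactly and the median-rescaled factors equal `d_i/median(d)` to
machine precision; this exactness is used as a test invariant.

### Comparators

* **TSS** — the column total.
* **RLE** — median ratio to a per-feature geometric-mean reference, defined
  only through features nonzero in every sample; with none, the method
  fails loudly. `RLE+` adds a pseudo-count of 1 to every cell first. The
  direct median ratio is already on the library-size scale (it equals the
  conventional relative factor multiplied by the total count), so it is
  reported as the scaled size factor.
* **TMM** — reference sample chosen as the one whose upper quartile of
  depth-scaled counts is closest to the mean of those quartiles; M (log2
  ratio) and A (mean log2 abundance) computed over features nonzero in both
  sample and reference; two-sided rank trimming of 30% on M and 5% on A
  (ranks kept in `[⌊n·t⌋+1, n−⌊n·t⌋]`); precision-weighted mean of the
  surviving M with inverse asymptotic binomial variances as weights; scaled
  factor = 2^mean × library size. If nothing survives trimming the factor
  falls back to 1 with a warning. The trims and reference rule are the
  canonical published defaults, exposed through `TMMConfig`.
* **CSS** — a *CSS-compatible* variant pinned to a reproducible recipe: on
  a common probability grid (101 points), compute each sample's quantile
  function of nonzero counts and a reference curve (per-probability mean of
  the zero-inclusive sorted columns); the instability profile is the median
  absolute deviation from the reference across samples; the chosen
  percentile is the smallest grid point whose relative instability
  increment exceeds 0.1, floored at 0.5; the size factor is the sum of each
  sample's counts at or below its own chosen quantile of nonzero counts.
  This follows the published data-driven percentile idea but is not claimed
  to be bit-identical to the original implementation.

All methods can be put on a common scale by dividing by the median factor.
Rare-feature filtering is deliberately *not* performed inside any
normalizer; each is a pure function of its input table.

## Synthetic data

### Dirichlet-multinomial benchmark tables

Each sample's composition is drawn from Dirichlet(π·(1−θ)/θ) around a
common mean vector π and counts are multinomial at a drawn library size,
so the column total *is* the true depth. Defaults (the "stool-like"
preset, chosen once for realism):

* π: ranked power law `π_k ∝ k^{−1.2}` over q = 625 features — a few
  dominant taxa, a long rare tail.
* Library sizes: log-normal, median ≈ 15,000 reads, log-sd 0.6, truncated
  to [2,000, 150,000], rounded.
* Dispersion θ: calibrated, not fixed. `calibrate_dispersion` bisects θ
  (bounds 10⁻⁴–0.95) against the simulated zero fraction at the target
  sample size, using a fixed internal seed (common random numbers keep the
  response monotone); tolerance 0.01. The three sparsity presets target
  60%, 70% and 80% zero cells; an unattainable target reports the
  attainable range instead of looping. At the 70% preset a pair of samples
  shares ≈ 98 nonzero features on average — the same order as real stool
  tables of this size.

Perturbations corrupt a round(fraction·q)-feature subset: strong
perturbation maps counts to √c (decrease) or c² (increase), moderate to
0.25c or 4c; results are rounded half-up and zeros stay zero (so √c of a
structural zero cannot invent a count). "Fixed" mode uses one global
subset with one Bernoulli(½) direction per feature shared by all samples
(differential abundance); "random" mode draws subset and directions
independently per sample (sample-specific outliers). Perturbation is the
only step that breaks the equality between column sums and true depths —
that is the point of the benchmark. The "true" size against which factors
are scored is always the pre-perturbation column total.

### Two-group ZINB tables

Counts are a point mass at zero with probability `p_k` (structural
absence) or NB with mean `μ_k` and dispersion `φ_k` (variance μ + φμ²),
drawn as a gamma–Poisson mixture. Defaults, again chosen once for stool
realism:

* The two most abundant features are pinned at expected relative
  abundances 0.168 and 0.083; the remaining mass follows `k^{−1.8}`.
* Structural-zero probability grows quadratically with rarity rank,
  `p_k = 0.02 + 0.93·x²` (x = rank fraction): dominant taxa are nearly
  always present, the tail is mostly absent, overall ≈ 60% zero cells.
  Prevalence tracking abundance is the empirically observed shape; an
  abundance-independent zero curve both misrepresents real tables and
  starves any count-model test of power.
* `φ_k ~ LogNormal(ln 0.8, 0.6)`; per-sample depth multipliers
  `LogNormal(0, 0.7)` on μ make size factors identifiable (a benchmark
  convention — the generative model needs *some* depth heterogeneity for
  normalization to have anything to recover).

Designs: 49 samples per group; 5% of features differential (half-up
rounding) with the affected group drawn uniformly per feature and the NB
mean multiplied by fold 4 in that group. The "unbalanced" scene
additionally forces the two dominant features differential in one fixed
group, shifting ≈ 75% of the expected total mass into it — the strong
compositional regime in which total-sum scaling misattributes depth.

## Differential abundance test

A deliberately plain per-feature NB Wald GLM: log link, two-level group
covariate, log size factor as offset. Dispersion is profiled by maximum
likelihood — method-of-moments start, safeguarded Newton steps on log φ
with numeric derivatives and a grid-scan fallback, floor 10⁻⁸ — and the
mean model is refit by IRLS after each dispersion update (at most three
rounds). Two-sided Wald p-values from the expected information;
Benjamini–Hochberg adjustment; no independent filtering, no shrinkage, no
outlier refitting. Features observed in fewer than two samples are not
tested (p = 1, flagged); a group with no observed counts gets a 0.5
continuity correction so the fold estimate is finite with an honestly
large standard error; numerical failures are flagged with p = 1 rather
than raised.

The absence of empirical-Bayes dispersion shrinkage is intentional: the
benchmark contrasts *normalizations* holding the test engine fixed, and a
fully specified engine keeps that contrast interpretable. Absolute power
and FDR therefore do not transfer to shrinkage-based pipelines; the
between-normalization ordering is the claim being exercised.

## Evaluation statistics

* **Size-factor correlation** — Spearman by default (the robustness
  benchmark is about rank agreement and the quantity is heavy-tailed);
  Pearson available. Constant vectors yield NaN, reported as NA.
* **Perturbation benchmark** — per grid cell (sparsity preset × mode ×
  strength × fraction), mean correlation across repetitions with a normal
  95% CI (mean ± 1.96·SE). RLE failures become NA cells, never crashes.
  Cell seeds are derived deterministically from the master seed, so
  reports are byte-reproducible.
* **Variance ranking** — per dataset and method, the median across
  features of the across-sample variance of normalized abundances
  (factors median-rescaled first); methods ranked with average ranks on
  ties; an unnormalized RAW pseudo-method can be included. Per-feature
  ranks among methods are also reported. Prevalence strata are cut at the
  terciles of the prevalence values, a feature on a cutpoint going to the
  higher stratum — hence a table with uniform prevalence is entirely
  "top", and distinct prevalences give strata whose sizes differ by at
  most one.
* **Paired signed-rank** — zero differences dropped, midranks on ties;
  exact two-sided p by dynamic programming over sign assignments for up to
  25 pairs (midranks doubled to integer support), tie-corrected normal
  approximation with continuity correction beyond.
* **ICC** — one-way random-effects ANOVA estimator: σ̂²_ε = MSW,
  σ̂²_b = max(0, (MSB − MSW)/k₀) with k₀ the unbalanced-design average
  group size, ρ clamped to [0, 1]. Chosen over iterative mixed-model
  fitting because it is deterministic, dependency-free, and unbiased in
  expectation for the one-way model the definition describes. Size factors
  may be estimated on one table and applied to another with the same
  samples (e.g. estimated at feature level, applied to genus-level
  aggregates).

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run everything at sizes a
laptop handles in about a minute, stated here as the package's own
defaults for its self-checks: sparsity calibration at q = 625, n = 98
averaged over 25 tables; the perturbation comparison at the 70% preset
with 10 repetitions and fractions {0.16, 0.32}; the DAA benchmark at
q = 300 with 20 repetitions per scene; oracle-equivalence checks on 200
random micro-instances per statistic. Larger grids are available through
`gmprnorm benchmark` flags.

## Known limitations

* The synthetic presets emulate the *shape* of stool OTU tables (ranked
  abundances, prevalence–abundance coupling, depth spread), not any real
  dataset's parameters; conclusions about method *ordering* are expected to
  transfer, absolute correlations/FDRs are not. Estimating DM/ZINB
  parameters from a user's own table is out of scope.
* Features are generated independently; phylogenetic or ecological
  correlation between taxa is not modeled.
* The CSS variant is reproducible but not bit-identical to the original
  implementation's percentile search.
* GMPR here is the exact O(n²q) computation; no streaming or block-wise
  variant for cohorts of many thousands of samples.
* Distance-based/ordination evaluation and rarefaction are intentionally
  outside the package's contract.
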