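# Methods

This note records the models implemented in `hybridpred`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions a
maintainer would want written down. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Study design being emulated

A factorial hybrid breeding experiment: `F` female and `M` male inbred
lines (defaults 120 and 15), their F1 hybrids (default 1,604 of the 1,800
possible, drawn uniformly — how the realized subset of crosses was chosen
in practice is not documented, so uniform sampling is the assumption),
evaluated in up to six environments. Each environment holds three adjacent
trials linked by ten common check genotypes; lines and checks are grown in
both replications, 29 % of the hybrids as well; plots are grouped into
incomplete blocks. Parents are genotyped (biallelic SNPs, dosages 0/2
after QC with ≤ 5 % missingness, ≤ 5 % heterozygosity in inbreds and
MAF ≥ 5 %); hybrid marker profiles are deduced as the parental mean dosage,
exact in integer arithmetic.

## Synthetic-data generator

* **Genotypes.** Markers are simulated in linkage equilibrium with
  per-marker allele frequencies uniform on `[maf_low, maf_high]`
  (defaults 0.05–0.5). Columns are built by count (a fixed number of
  carrier lines per marker, randomly placed), which pins every realized
  frequency inside the band — a Bernoulli scheme would scatter small-panel
  frequencies below the QC floor. Positions are uniform cM on 21
  equally sized chromosomes. Real LD is not modelled by default; an
  optional duplicate-with-noise mode (`add_ld_proxy`) copies a focal
  marker column with a configurable flip rate to emulate a tight local
  block of tagging markers around a major QTL.
* **Genetic values.** `g_i = Σ_q a_q z_A(i,q) + d_q z_D(i,q)` under F∞
  coding with `a_q ~ N(0, σ²_a)`, `d_q ~ N(0, σ²_d)`. With `σ_d = 0`
  every hybrid value equals its mid-parent value exactly — the heterosis
  null used throughout the tests.
* **Trials.** Plot values add independent Normal effects for environment,
  trial (nested in environment), replication, block, genotype×environment
  and residual. Replications are modelled as complete replicates of an
  environment crossed with the trials (the phenotypic model lists trial
  and replication as separate main-effect vectors); blocks are nested in
  trial × replication. The realized draws of every effect are recorded in
  `DataFrame.attrs["realized_variances"]` as the parameter-recovery
  oracle; for factors nested in environment the within-environment stratum
  variance is stored, because the between-environment component of their
  draws is not separable from the environment term by any estimator.
* **Entry-mean bundles.** The cross-validation studies run on data
  generated at the entry-mean level: observed hybrid BLUEs are the true
  genetic values plus iid noise calibrated so the entry-mean heritability
  equals the target (default 0.8). This isolates the relatedness /
  composition / density questions from the phenotypic-analysis stage,
  which is exercised separately (two-stage chain, one-step REML) on
  plot-level data. What passing these studies does *not* show: robustness
  to unbalancedness beyond the generator's layout, to genotyping error
  (not modelled), or to real LD and ascertainment.

## Phenotypic analysis

Stage one (per environment) fits fixed genotype effects with random trial,
replication and block effects; stage two combines per-environment means
with a random environment effect. With a single environment stage two is
the identity. The one-step model treats everything except the intercept as
random; the ten checks ride along as extra levels of the line factor.
Significance of a component is a likelihood-ratio test against the model
without it, with the p-value halved because the null value lies on the
boundary (a statistic of 0 gives p = 0.5); these refits are computed on
demand, not eagerly.

Heritability (the standard quantitative-genetics forms are adopted): entry-mean `h² = σ²_G/(σ²_G + σ²_G×E/E + σ²_e/(E·R))`, plot
basis `σ²_G/(σ²_G + σ²_G×E + σ²_e)`, both clamped to [0, 1]. `E` is the
number of environments actually present in the data; `R` the maximum
replication count observed.

### REML engine

`y = Xβ + Σ_k u_k + e`, `u_k ~ N(0, σ²_k G_k)` with `G_k` an equality
indicator (or an arbitrary PSD relationship matrix). Average-information
steps with step-halving; parameters pinned at the zero boundary with a
downhill gradient are dropped from the AI system (they otherwise corrupt
the Newton direction); an EM update is the fallback when no AI step
improves the restricted likelihood. Convergence: relative change of the
restricted log-likelihood < 1e-8, at most 200 iterations; a variance below
twice the floor (1e-10 × var(y)) is reported as 0. The engine was checked
against lme4 on the full nine-component one-step model (agreement to four
decimals in every component).

### GCA/SCA

Fixed-effects least squares under sum-to-zero constraints (the
identifiability constraint is otherwise arbitrary); SCA is the per-cross
residual. In a balanced factorial the GCAs are the classical row/column
mean deviations. For the *variances* needed by the shrinkage ratios a
separate REML fit with random female and male GCA effects is used; its
cross-level residual absorbs SCA plus the error of the means, so
`σ²_SCA` is that residual minus the known mean-level error variance
(floored at a small positive fraction of the trait variance).

## Association mapping

The scan model is `Y = Xβ + Ss + Zu + e` over adjusted entry means within
environments (or BLUEs with an intercept-only fixed part), with
`var(u) = K σ²_u`. The default mode estimates `(σ²_u, σ²_e)` once under
the null by profiled REML on the eigendecomposition of `ZKZ'` and reuses
them for every marker (the standard population-parameters-previously-
determined approximation); `mode="exact"` re-estimates the ratio per
marker. Tests are F(1, n−p−1) Wald tests; monomorphic markers are skipped
and flagged. Kinship is `W W'/m` (marker count scaling; a VanRaden-style
`2Σp(1−p)` alternative is available) — several scalings are in field
use and the choice only rescales the polygenic variance, so the simple,
reproducible marker-count scaling is the default. Dominance scans
use the 0/1 heterozygosity codes, informative only where hybrids are
present. Marker×environment interaction is a fixed-interaction F-test in
the same model. `p_G = R²_adj/h²` is capped at 1 with a flag.

A noise-free monogenic trait is a degenerate input: the null model then
sits at `σ²_e = 0` and the polygenic term, whose kinship contains the
causal marker, absorbs the signal entirely (proximal contamination). Any
realistic residual restores the expected behaviour; the tests use a small
residual for this construction.

## Genomic prediction

RR-BLUP solves the block mixed-model equations exactly; for `2m > n` the
dual (BLUP) form is used, with a tested numerical-equality contract
(max |difference| < 1e-8 on random instances) and the RR-BLUP ≡ GBLUP
identity (`K = Z_A Z_A'/m`, ratio `λ/m`) as a second independent route.
W-BLUP implements the functional-marker extension as per-column shrinkage
`λ/w` with default `w = 100`: the penalty on the functional columns is a
genuinely open choice, and this parameterisation interpolates continuously
between plain RR-BLUP (`w = 1`, an exact reduction used as a test) and
fixed covariates (`w → ∞`).

Bayes-Cπ: per-class inclusion indicators `δ_g ~ Bernoulli(1−π_g)`, uniform
prior on `π_g` (Beta full conditional), scaled-inverse-χ² priors with
df = 4 for the variances; the effect-variance prior scale is matched to
half the phenotypic variance spread over the expected number of included
markers at π = ½, the residual scale to half the phenotypic variance.
Chain defaults 10,000 iterations / 2,000 burn-in / thinning 10; the
studies use shorter, seeded chains sized by their own convergence checks
(doubling the chain moves posterior means by less than the Monte-Carlo
error). Chains are bitwise reproducible under a fixed seed.

## Cross-validation

Estimation sets: 80/120 females, 10/15 males, 610 estimation hybrids drawn
among the crosses internal to them; remaining hybrids classified T2/T1/T0
by the shared-parent rule. On a full factorial this leaves exactly
190 T2 hybrids (800 − 610). When the realized plan is not a full
factorial the sampler errors unless `best_effort` is set (then it takes
all internal crosses), keeping the fixed-size contract testable.
Accuracy = Pearson r / √h², clamped at 1; h² is estimated once from the
full data, not per run. MAS runs scan the estimation set, select markers
at each threshold (Bonferroni–Holm and raw 0.0001…0.10), estimate joint
effects by GLS with the scan's polygenic covariance, and predict the test
sets; empty selections contribute accuracy 0 (conservative; the
alternative of dropping such runs would bias MAS upward). Seeding is
master-seed-plus-offset so runs are independent and studies reproducible.

## Validation-study conditions (scripts/acceptance.py, tests)

Problem sizes are the package's own choices for desk-scale studies:

* Solver identities: 25 random instances, n ≤ 50, m ≤ 200; tolerance 1e-8
  (1e-6 for the GBLUP identity).
* Family-wise error: 200 global-null replicates of 150 genotypes × 500
  markers with polygenic background; the bound is 0.05 plus a one-sided
  95 % binomial margin.
* Major-QTL stability: one injected QTL calibrated to 30 % of hybrid
  genotypic variance over a 30-QTL background, h² = 0.85, 400 markers;
  100 estimation-set resamples.
* Relatedness ordering: 400 markers, 200 QTL, h² = 0.8, no major QTL;
  30 CV runs for RR-BLUP and MAS(Holm).
* Parameter recovery: 20 replicates of 36 lines + 164 hybrids in 4
  environments (3 trials, 2 replications, no checks) with variance vector
  (1.0, 0.3, 0.4, 0.15, 0.3, 0.6) for environment/trial/replication/
  block/G×E/error and genetic variances 0.6 (lines) and 0.5 (hybrids) —
  all components away from the zero boundary, where the median-ratio
  comparison is meaningful. Estimates are compared with the realized
  variance of the effects drawn in the same replicate (see generator
  notes) because at 4–12 levels the realized and population variances
  differ by far more than any estimator could resolve. The environment
  component is compared at its stratum — σ̂²_env + σ̂²_trial/T + σ̂²_rep/R
  against the realized variance of the per-environment shifts — because
  with nested children only that sum is identified from 4 environments.
* Resampling trends: female grid 30/60/90/120 (estimation = two thirds of
  them, 10 males, 100 hybrids) and hybrid grid 100/300/500/610 on a
  400-marker panel; marker densities m/8 and m (window 173) on a
  1,600-marker panel, dense enough that an eighth still estimates the
  realized relationships; 30 runs each. Trends are asserted as endpoint
  ordering plus a positive least-squares slope over the grid.

## Known limitations

* Linkage equilibrium by default; the duplicate-with-noise LD mode gives a
  crude local block, not a realistic genome-wide LD decay profile.
* No genotyping-error or missing-data mechanism in the generator (QC and
  imputation are exercised on constructed inputs instead).
* The one-step REML is dense (O(n³) per iteration) and intended for series
  up to a few thousand plots.
* Outlier handling in the phenotypic stage is a plain robust
  studentized-residual cutoff, not a specialised field-trial outlier test.
* GCA/MP predictors require trained/phenotyped parents by construction;
  they raise for T1/T0-type targets rather than falling back silently.
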