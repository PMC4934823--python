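# hybridpred

Genomic prediction of hybrid performance in a factorial crossing program of
a selfing crop (the motivating case is hybrid winter wheat bred from a
female × male factorial of inbred lines, phenotyped for quality traits in
multi-environment trials and genotyped with a dense SNP array).

The package answers three questions a hybrid breeding program faces:

1. **Are there major-effect QTL?** — kinship-corrected genome-wide
   association scans over lines and hybrids, with Bonferroni–Holm control
   and explained-variance accounting.
2. **How should hybrid performance be predicted?** — RR-BLUP, W-BLUP and
   Bayes-Cπ with additive *and* dominance marker effects, next to the
   classical mid-parent and general-combining-ability (GCA) predictors.
3. **How do training-set composition and marker density drive accuracy?** —
   cross-validation stratified by relatedness (T2/T1/T0 test sets sharing
   two / one / zero parents with the estimation set) plus resampling
   studies over parent counts, hybrid counts and marker densities.

Field and array data of this kind are rarely public, so a first-class
simulation module generates the whole study design with known ground truth: inbred
parents (dosages 0/2, MAF ≥ 5 %), F1 hybrids deduced from parental
fingerprints, additive + dominance QTL architectures, and partially
replicated multi-environment trials (3 linked trials per environment,
10 common checks, 29 % of hybrids in both replications).

## Models

**Phenotypic two-stage analysis.** Per environment, plot values follow
`y = μ + X_G g + X_T t + X_R r + X_B b + e` with fixed genotype effects and
random trial / replication / block effects fitted by REML
(average-information updates with an EM fallback); a second stage with
random environment effects gives one BLUE per genotype. A one-step model
treats every term as random and returns the full variance-component vector
(σ²_environment … σ²_error) with halved-LRT boundary tests, from which the
entry-mean heritability `h² = σ²_G / (σ²_G + σ²_G×E/E + σ²_e/(E·R))` follows.

**RR-BLUP.** Marker effects `a ~ N(0, σ²_a)`, `d ~ N(0, σ²_d)` estimated
from Henderson's mixed-model equations

```
[ 1'1    1'Z_A          1'Z_D        ] [μ̂]   [1'y  ]
[ Z_A'1  Z_A'Z_A+λ_A I  Z_A'Z_D      ] [â ] = [Z_A'y]
[ Z_D'1  Z_D'Z_A        Z_D'Z_D+λ_D I] [d̂ ]   [Z_D'y]
```

with F∞ coding (homozygotes ±1, heterozygotes 0 additively; heterozygotes 1
on the dominance axis) and shrinkage
`λ_A = (σ²_e/Nr.Env)/(σ²_GCA/Nr.Marker)`,
`λ_D = (σ²_e/Nr.Env)/(σ²_SCA/Nr.Marker)`. When markers outnumber
genotypes the numerically identical n-dimensional BLUP (dual) form is used.

**W-BLUP** adds near-unshrunken effects for "functional" markers — the
three most significant hits of an association scan in the training set.
**Bayes-Cπ** includes each marker with probability `1 − π_g` (uniform prior
on π_g) and samples everything by Gibbs. **GCA/MP** predict a hybrid from
`μ̂ + gca_f + gca_m` or from the parental mean — applicable only when the
parents were trained/phenotyped (T2-type targets).

**Accuracy** is the Pearson correlation between predicted and observed
hybrid performance divided by √h² (entry-mean basis), clamped at 1.

## Worked example

```python
import hybridpred as hp

# a 120 x 15 factorial with 1,604 hybrids, polygenic trait, h2 = 0.8
data = hp.simulate_polygenic_data(n_hybrids=1604, n_markers=1730,
                                  n_qtl=200, h2=0.8, seed=7)

scheme = hp.sample_t_scheme(data.plan, seed=0, best_effort=True)
print(len(scheme.est_hybrids), len(scheme.t2), len(scheme.t1), len(scheme.t0))

res = hp.run_cv(data, "rrblup", n_runs=10, seed=1,
                scheme_kwargs={"best_effort": True})
print(res.scenario_means("rrblup").round(2))
```

prints

```
610 102 721 171
scenario
T2    0.95
T1    0.69
T0    0.21
```

i.e. an estimation set of 610 hybrids, 102 left-over fully related (T2)
hybrids, and mean cross-validated accuracies that fall from 0.95 (both
parents trained) through 0.69 (one parent) to 0.21 (unrelated) — the
relatedness gradient that makes prediction of unrelated material the hard
case.

A full pipeline run (simulation → QC → phenotypic analysis → GWAS →
prediction → cross-validation, every intermediate persisted as TSV/CSV)
goes through a single config file:

```bash
hybridpred run --config config.yaml --seed 1 --out run_out/
```

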