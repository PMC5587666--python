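# Methods

## Model

The phenotype model is a standard multiple regression,
`y = Wα + Xβ + ε` with `ε_j ~ iid N(0, σ²_e)`, where `X` holds per-SNP
allele dosages (0–2 scale, mean-imputed, centered on training means) and
`W` holds covariates with an intercept. What distinguishes the model is
the prior on the SNP effects: each `β_i` is normal with its own variance
`σ²_i`, and the distribution of those variances carries a Dirichlet
process prior `G ~ DP(H, λ)` with inverse-gamma base `H`. Marginally the
effects follow an adaptive normal scale mixture — the class that contains
the normal (ridge/BLUP), t (Bayes alphabet), Laplace (Bayesian lasso) and
normal-mixture (BayesR-style) priors as special cases — so the fitted
prior can approximate any of those shapes, and intermediate ones, driven
by the data.

### Truncation

Inference uses the blocked stick-breaking representation truncated at `K`
components with the last stick forced to one:
`π_k = ν_k Π_{l<k}(1 − ν_l)`, `ν_k ~ Beta(1, λ)`, `σ²_k ~ H`. Although the
untruncated process has infinitely many components, the posterior for any
finite data set occupies finitely many, so a modest truncation with
data-driven occupancy behaves like the full process. The regression
default is `K = 4` (one "background" component plus room for two or three
effect scales); the univariate density fitter defaults to `K = 10` because
a free-standing density fit typically supports more occupied components
than a posterior over SNP effects. Both are configurable.

### Hyper-priors (defaults and rationale)

| parameter | role | default | rationale |
|---|---|---|---|
| `a_sigma, b_sigma` | inverse-gamma base H on σ²_k (shape/rate) | 0.1, 0.1 | small values keep H weakly informative yet proper |
| `a_lambda, b_lambda` | gamma prior on concentration λ (shape/rate) | 1, 1 | proper, conjugate through the sticks; prior mean 1 |
| `a_e, b_e` | inverse-gamma prior on σ²_e | 0.1, 0.1 | weakly informative |
| prior on α | covariates | flat (improper) | conditional update is then plain least squares with Gaussian noise |

All units follow the phenotype: σ²_e and σ²_k are variances on the scale
of `y` (typically quantile-normalized to N(0,1), so variances are
dimensionless fractions of phenotypic variance).

## Gibbs sampler

One sweep updates, in fixed order: per-SNP `(γ_i, β_i)` for every SNP,
component variances, sticks, concentration, residual variance, covariate
coefficients; then records PVE and the unnormalized log posterior. Design
choices:

* **Single-site effect updates with a running residual.** `r = y − Wα − Xβ`
  is maintained in place, making a sweep O(np). A debug mode recompares the
  cache against the exact residual (tolerance 1e-8) every sweep.
* **The assignment update conditions on the current `β_i`**
  (`P(γ_i=k) ∝ π_k N(β_i; 0, σ²_k)`) rather than marginalizing it — the
  simplest exact blocked-Gibbs kernel. A collapsed kernel would target the
  identical posterior with different autocorrelation.
* **Genotypes are centered, not standardized**, because the simulation
  architectures define effect sizes on raw dosages; standardizing would
  silently reweight low-MAF SNPs.
* **Concentration update:** `λ ~ Gamma(a_λ + K − 1, b_λ − Σ_{k<K} log(1 − ν_k))`,
  with the log term clamped at −700 so a stick that saturates to 1 cannot
  produce an infinite rate.
* Defaults: 50,000 sweeps with 20% burn-in and thinning 10 for production
  runs; the test-suite and acceptance script use 300–2,000 sweeps on small
  panels, which the conjugate-oracle and recovery checks show is adequate
  at those sizes.
* **PVE per draw** is `var(Xβ)/(var(Xβ) + σ²_e)` with the *empirical*
  variance of the current fitted genetic values — a realized-sample
  estimator, consistent with how the simulator defines heritability.
* **PIP** is the fraction of kept draws in which a SNP is assigned outside
  the smallest-variance component, with the background component
  identified per draw (so label switching along the chain is harmless).
  With `K = 1` PIPs are defined as 0 and a warning is emitted.

The per-SNP sweep is numba-compiled when numba is importable and falls
back to the identical pure-Python loop otherwise; both consume pre-drawn
random variates from a single PCG64 generator, so results do not depend on
which path runs.

## Variational Bayes

The mean-field family is
`q = Π_i q(β_i, γ_i) · Π_k q(ν_k) q(σ²_k) · q(σ²_e) q(λ) q(α)`
with a *structured* per-SNP factor `q(γ_i) q(β_i | γ_i)` — a categorical
times per-component normals — which is exactly conjugate, so every
coordinate update has closed form and the ELBO is non-decreasing (checked
to 1e-8 per step on every test input). `E[log π_k]` comes from digamma
functions of the stick Beta parameters. Initialization is deterministic:
uniform responsibilities, zero means, variance factors at their priors,
covariates at OLS; convergence is declared when the relative ELBO change
drops below 1e-5 (default) with a hard cap of 1000 cycles and an explicit
warning — never a silent failure — on non-convergence.

Because the per-SNP posteriors are forced independent, VB underestimates
posterior uncertainty and (as the internal comparisons show) biases the
PVE point estimate low; the bias grows with true heritability, which is
why agreement with the Gibbs backend is asserted only at low PVE.

## Genotype handling

* PLINK bed/bim/fam (SNP-major, 2-bit codes) and BIMBAM mean-genotype text
  are read and written natively; dosages count the first allele of the
  .bim/BIMBAM record, recorded in the SNP metadata so effect signs are
  interpretable.
* QC removes SNPs with HWE p < 1e-4 (1-df chi-square against
  Hardy–Weinberg proportions; monomorphic SNPs return p = 1 by
  convention), call rate < 95%, or MAF < 1%; the exclusion report names
  the first failed rule per SNP, checked in that order. The surviving set
  is order-independent because the three filters are intersected.
* Missing dosages are imputed with the SNP's observed mean; phenotypes can
  be quantile-normalized to N(0,1) using `Φ⁻¹((r − 0.5)/n)` with averaged
  ranks for ties. For cross-validation, the normalization map and the
  centering means are learned on the training fold and applied to the test
  fold by monotone interpolation, so no test information leaks into
  preprocessing (verified by a mutation test).

## Simulator

`simulate_genotypes` draws per-SNP MAFs uniformly on (0.05, 0.5) and
dosages as Binomial(2, MAF), independent across SNPs and samples. Four
phenotype architectures are built on top (all causal/four effect groups at
5/15/20/60% of genetic variance; sparse three-group 10/20/70%; two-group
20/80% with a configurable number of large-effect SNPs; single-family
normal/t(4)/Laplace effects). Raw effects are rescaled per group on the
realized sample so group variance shares are exact, and the noise vector
is emptied of its empirical correlation with the genetic values and scaled
so realized PVE equals the target *identically* — which makes
`var(y) = var(Xβ) + var(ε)` an exact identity and recovery tests
deterministic given the seed. (Whether one rescales by realized or
expected variance is a free choice; realized was chosen for exactness.)

What the simulator deliberately does **not** emulate: linkage
disequilibrium, MAF–effect-size coupling, population structure and
relatedness, genotyping error. Passing recovery and cross-validation tests
therefore demonstrates correctness of the inference machinery on
independent-SNP panels, not absolute accuracy levels on real genotype
data, where LD and structure change both PVE calibration and predictive
R².

## Evaluation

Prediction is the plug-in rule with posterior-mean coefficients. Accuracy
is squared Pearson correlation (R²) and MSE over repeated seeded 80/20
splits (default 20). A constant prediction vector reports R² = 0 with a
warning rather than NaN, so degenerate fits are visible but comparable.
The GRM is `X_s X_sᵀ/p` from standardized genotypes, and the effective
number of chromosome segments is the reciprocal variance of its
off-diagonal entries — on unrelated independent-SNP panels this
approximates p, and it shrinks with relatedness.

## Problem sizes

The test-suite and the acceptance script run at desk scale: panels up to
n = 1000 × p = 500 with 800–2,000 Gibbs sweeps, 5 CV splits, 5 recovery
seeds, and 1e5 sweeps for the brute-force assignment-enumeration oracle
(n = 6, p = 2). These sizes were chosen so every check is decisive for
correctness while the whole battery completes in minutes; production
defaults (50,000 sweeps, 20 splits) remain the recommended settings for
real analyses.

## Known limitations

* Case-control traits are not supported (the likelihood is Gaussian).
* The VB factorization ignores cross-SNP posterior correlation; use the
  Gibbs backend when accuracy at high heritability matters.
* PIP ranks association strength but is not calibrated against a point
  null: with every-SNP-causal architectures the "background" component is
  a modeling convention, not a null hypothesis.
* No LD-aware simulation; no reference-panel imputation or phasing (run
  external tools first and supply dosages).
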