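# Methods

This note records the statistical models implemented in `gxepred`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that a maintainer would otherwise
have to reverse-engineer.

## Mixed-model phenotype adjustment

Per water-management system, plot records are modeled as

    y_ijk = mu + year_i (+ rep-within-year) + g_j + gy_ij + e_ijk

with genotype and genotype-by-year random and year fixed (replicate nested in
year is added under `design="rcbd"`, matching a randomized complete block
layout; the default `"crd"` matches a completely randomized design). REML
maximizes the restricted log-likelihood over the variance ratios
`gamma_k = sigma_k^2/sigma_e^2` with the residual profiled out. Each
evaluation costs one Cholesky factorization of `I_Q + D^1/2 Z'Z D^1/2`
(Q = number of random-effect levels) via the Woodbury identity, so panels of
a few hundred genotypes fit in seconds. Optimization is L-BFGS-B on
`log gamma` from two starts, followed by a short Nelder-Mead polish (the
finite-difference gradient limits accuracy near flat directions); ratios
below 1e-8 are reported as exactly zero, so boundary estimates print as 0.
With a single year the genotype-by-year term and the year effect are dropped
and flagged rather than silently aliased.

Conventions that the data cannot decide and that are therefore fixed here:

* `fixed_var` is the population variance of the fitted fixed-effect linear
  predictor across plots — the conditional-R² convention. With it,
  conditional R² = (fixed_var + sigma_g² + sigma_gy²)/total.
* Adjusted means are `mean(X beta_hat) + BLUP(g_j)`, without the
  genotype-by-year deviations.
* `n_y` and `n_r` are harmonic means over genotypes of observed year and
  plot counts (2 and 6 for a complete two-year, three-replicate trial).
* Heritability standard errors use the delta method on a finite-difference
  REML information matrix; they are approximate and only computed on request.

The genotype-by-management test compares restricted likelihoods of the
combined two-system model with and without the `g×m` term; because the
component sits on the boundary, the p-value uses the 50:50 mixture of
chi-square(0) and chi-square(1). The full model is started from the reduced
optimum (among other starts), which guarantees the full fit never has a
worse restricted likelihood than the reduced one.

The outlier screen flags plots whose conditional residual exceeds
`threshold` (default 4) residual standard deviations; it is a deliberately
simple replacement for restricted-likelihood-distance diagnostics, and
removal is opt-in and logged.

## Response variables

The relative-performance index uses the control system (CF) as denominator;
genotypes with near-zero control means are excluded with a warning rather
than propagating unstable ratios. The joint-regression environment indexes
`theta_m` are left uncentered — the per-genotype intercept absorbs location —
and with two environments the per-genotype least-squares fit is exact, so the
slope is the two-point formula and the mean slope over genotypes is exactly 1.

The genetic correlation is reported two ways. The default is the Pearson
correlation of adjusted means (the convention of multi-environment trial
tables). Because entry means carry noise `sigma_gy²/n_y + sigma_e²/n_r`,
this estimator is attenuated toward `rho*sqrt(H2_1*H2_2)`; passing the two
entry-mean heritabilities disattenuates it (correlation is scale-free, so
BLUP shrinkage does not otherwise affect it). Parameter-recovery tests use
the disattenuated form, which is unbiased for the simulated correlation.
Confidence intervals use the Fisher transform with `1/sqrt(N-3)` standard
error. The correlated-response ratio is `r_G * sqrt(H2_CF/H2_AWD)`.

## Kernels and bandwidth

The linear kernel is `XX'` on column-centered codes, unscaled by default
(the model's genetic variance absorbs the scale; `scale=True` divides by the
mean diagonal). The Gaussian kernel is `exp(-h D²)` on squared Euclidean
distances of centered codes.

The bandwidth is estimated as the mode of (marginal likelihood × gamma
prior): the marginal likelihood of `y = mu + u + e`, `u ~ N(0, phi sigma_e²
K_h)`, is profiled over the signal-to-noise ratio `phi` on a 31-point log
grid (this plays the role of the form parameter in the empirical-Bayes
formulation), evaluated on a coarse bandwidth grid and refined by
golden-section search; the procedure is deterministic. The gamma prior uses
shape 3 and scale 1.5 in the shape/scale parameterization, mode
`(shape-1)*scale = 3` (a rate parameterization appears in parts of the
literature; the mode quoted here is the shape/scale one). With no genetic
signal the likelihood term is flat in `h` and the estimate falls back to the
prior mode.

A unit matters: a prior with mode 3 is only meaningful when squared
distances are O(1). `KernelSet.build` therefore divides D² by its
off-diagonal mean before bandwidth estimation and kernel construction, and
`bandwidth` is expressed on that normalized scale. On raw distances — which
grow linearly with marker count — a mode-3 bandwidth would collapse the
kernel to the identity. The standalone `gaussian_kernel` and
`squared_distances` functions keep the literal un-normalized convention,
with `normalize` as an explicit flag.

## Bayesian kernel models

All five model flavours are Gibbs samplers written in the eigenbasis of each
kernel: one spectral decomposition per fit (eigenvalues below 1e-8 of the
maximum dropped), after which every full conditional is diagonal — or, for
RKHS-2, block-diagonal in m×m blocks solved batched. A sweep is O(nm)
vector work, so the default 35,000-sweep chains take seconds at panel scale.

* **GBLUP / RKHS** — `y = mu + u + e`, `u ~ N(0, sigma_u² K)`.
* **GBLUP-G×E / RKHS-1** — `y = mu_e + u0 + uE_e + e`, the shared effect
  `u0 ~ N(0, sigma_u0² K0)` and independent per-environment deviations, each
  with its own variance. RKHS-1 is the same structure on Gaussian kernels
  (a per-environment kernel mapping is accepted); with the linear kernel it
  reproduces GBLUP-G×E exactly.
* **RKHS-2** — `y = mu_e + u + f + e` with `u ~ N(0, Sigma_u ⊗ K)` coupling
  environments through an m×m genetic covariance, and `f ~ N(0, Sigma_f ⊗ I)`
  catching genetic effects outside the kernel span. With one environment it
  delegates to the single-environment model.

Numerical and prior choices:

* Residual variances are environment-specific in every multi-environment
  model (the two managed systems genuinely differ in residual variance, and
  it makes the zero-shared-variance reduction factorize exactly into
  independent single-environment fits).
* Variance priors are scaled-inverse-chi-square with df 5; the scale is set
  so the prior mode equals an equal split of the sample phenotypic variance
  over the active random terms plus residual. `ModelSpec.prior_mode`
  overrides the split — used, e.g., to compare nested models under identical
  priors. RKHS-2's covariances get inverse-Wishart(m+2, I) priors;
  `diagonal_covariance=True` replaces them with independent per-environment
  scaled-inverse-chi-square updates and zero off-diagonals.
* Missing phenotype cells are handled by data augmentation: they are drawn
  from their conditional each sweep. The marginal posterior over parameters
  is identical to observed-data-likelihood inference, and the conditionals
  stay diagonal. Predictions for missing cells are
  `intercept_e + posterior-mean genetic components`.
* Posterior means of genetic values are accumulated from the
  full-conditional means (Rao-Blackwellized), posterior spreads from the
  draws. With fixed variances this makes the Gibbs/BLUP oracle agreement
  essentially exact.
* Chains derive their streams from `SeedSequence([seed, chain])`; the chain
  contract retains `(n_iter - burn_in)//thin` samples (3,000 by default).
* The Gelman-Rubin diagnostic is the classic PSRF; with a single chain the
  report says diagnostics are unavailable instead of passing silently. For
  literally identical chains the classic estimator gives
  `sqrt((n-1)/n)`, i.e. 1 up to O(1/n).

A real limitation, found while validating parameter recovery: in a panel of
*unrelated* inbreds the Gaussian kernel concentrates to `aI + bJ`, and the
off-diagonal genetic covariance of RKHS-2 is then barely identified against
the iid residual (the profile likelihood is flat for rho in roughly
[0.7, 1)). Identification comes from relatedness — families and structure
gradients — which real breeding panels have and the generator therefore
simulates. Even so the posterior mean correlation is mildly biased upward at
these scales, and the `f` term is only weakly separated from the residual
when each cell is observed once; `f`'s own variance should not be
over-interpreted.

## Validation designs

Partitions are uniformly random 80/20 splits (284 genotypes → 227/57); the
same splits are reused across schemes and models for paired comparisons, and
the M2 observed-environment assignment is balanced within each replicate and
drawn from a child RNG stream so it does not desynchronize the splits.
Failed fits are logged and recorded as missing rather than dropped silently.
Abilities are averaged arithmetically over replicates (mean ± SE); the
Fisher Z-transform is used only for the factorial ANOVA stage, which is an
ordinary fixed-effects OLS ANOVA (statsmodels) reporting DF/SS/MS/F/p plus
R², CV, RMSE and back-transformed level means.

CDmean selects a training set by accept-only-improving random exchanges on
the mean coefficient of determination `CD_i = K_iS P_S K_Si / K_ii` of
predicting non-selected individuals, where `P_S` projects out the intercept
from `(K_SS + lambda I)^-1`; `lambda = sigma_e²/sigma_g²` defaults to 1
(h² = 0.5) when no REML estimate is supplied. The objective trace is
non-decreasing by construction. Progeny scenarios: S1 trains on the named
parents, S2 on a CDmean-chosen subset (default 100), S3 on the whole
reference panel.

## Synthetic trial generator

The generator is the package's study system. Defaults mirror a reference
panel of 284 inbred genotypes, two managed environments (AWD stress, CF
control), two years, three replicated plots, genetic variances chosen to
give a cross-environment genetic correlation of 0.8 and entry-mean
heritability ≈ 0.85 (var_main 40, var_env_specific 10, var_gy 5,
var_residual 38), environment means 100.3/93.4 (a flowering-time scale) and
year effects ±1.5.

Genotypes: ancestral allele frequencies uniform on the MAF range; five
ancestral groups diverged by Balding-Nichols sampling at Fst 0.2; families
of six lines, with family frequencies drifted from their (Dirichlet-admixed)
base at Fst 0.35; individuals drawn from generalized Hardy-Weinberg
proportions with inbreeding F = 0.98. The het < 5% filter only makes sense
for inbred material — under strict Hardy-Weinberg equilibrium every marker
with MAF > 5% would fail it — and the family layer is what makes
cross-environment covariances identifiable (see above). Loci are unlinked;
there is no LD, no pedigree recombination, and no missing genotypes. Marker
effects are i.i.d. Gaussian, scaled against realized marker variances so the
genetic variances hit their targets exactly in expectation (infinitesimal
model). Genotype-by-year deviates are drawn independently per environment:
the two systems are physically separate trials.

What passing tests on these data do **not** show about real data: LD between
markers and QTL, non-Gaussian or sparse genetic architectures, spatial field
trends, genotype-specific missingness, and selection-induced structure are
all absent. Results here validate the estimators under their own
assumptions, not the assumptions themselves.

## Problem sizes used in the test suite

Closed-form checks run on published variance components directly. Sampler
oracles use 30-100 genotypes; parameter recovery uses 284-300 genotypes
with 400 markers and, for recovery and scheme-ordering experiments,
shortened chains (5,000-8,000 sweeps); the scheme-ordering experiment uses
150 genotypes and 30 replicates. These sizes were chosen so the full suite
exercises every pathway at panel-realistic shapes while remaining a
desk-scale computation.
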