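# Methods

This note documents the statistical models, the numerical choices behind
them, and what the synthetic-data generator does and does not emulate.

## Bayesian GBLUP reaction-norm model

The observation model for line *j* in year *i* is

    y_ij = μ + year_i + g_j + (year×g)_ij + Σ_l β_vg,l x_vg,jl
                                          + Σ_l β_gf,l x_gf,jl + ε_ij

* `g = (g_1..g_J) ~ N(0, σ_g² G)` with `G` the genomic relationship matrix;
* `(year×g) ~ N(0, σ_Yg² (I_I ⊗ G))` — the same relationship structure,
  independent across years;
* `ε_ij ~ N(0, σ²)` i.i.d.;
* flat priors on μ, the year contrasts and the NDVI coefficients;
* scaled-inverse-χ² priors on all three variances with `df0 = 5`
  degrees of freedom and scales set so each prior mode equals its share of
  an `R2 = 0.5` partition of the sample variance of the response (the
  genetic terms split R2 equally, the residual gets 1 − R2; the genetic
  scale is additionally divided by the mean diagonal of `G`). These are the
  default-prior conventions of standard Bayesian whole-genome regression
  software.

**Sampler.** `G` is eigendecomposed once (`G = Γ Λ Γᵀ`, eigenvalues floored
at 1e-10) and line effects are reparameterized as `g = Γ a` with
independent prior `a_k ~ N(0, σ_g² λ_k)`. Each Gibbs iteration performs
blocked multivariate-normal draws — fixed effects jointly (with a 1e-8
ridge on the cross-product for rank safety), the `a` block through one
J × J Cholesky solve, and one such block per year for the interaction —
followed by scaled-inverse-χ² draws for the variances. Blocked updates mix
far better than single-site scans and cost ~J³/3 flops per iteration,
which keeps a 300-line, 12,000-iteration chain in the tens of seconds.
Defaults: 12,000 iterations, 2,000 burn-in, thinning 5, all configurable;
variance components can be fixed (used by the mixed-model-equation
cross-checks in the test suite).

**Verification.** The sampler is checked three ways: (1) with all variances
fixed, its posterior means must solve the mixed-model equations, compared
against a direct linear solve; (2) on replicated null data (G = I, no
genetic signal) its posterior-mean heritability must match exact 2-D grid
integration of the marginal variance posterior — the two agree to < 0.01,
and that exact posterior is also why the null heritability does not collapse
to zero at small sample sizes: with 150 lines × 2 replicates the true
posterior mean under these priors is ≈ 0.19, dropping below 0.15 only around
300 lines × 4 replicates, which is the size the corresponding test uses;
(3) heritability recovery within ±0.15 on simulated trials with known h².

**Prediction.** Posterior means of all effects; unobserved lines borrow
information through `G` (their effects are sampled jointly). Under
leave-one-year-out validation the year main effect and interaction are
removed from the model, matching the fact that the held-out label is never
seen in training.

## Multimodal residual network

One tower per modality: year one-hot design, genomic features
`Z_L Lᵀ` (rows of the transposed upper-triangular Cholesky factor of `G`,
so row inner products reconstruct relationships), and NDVI columns.
Hidden widths follow `N_l = max(1, ⌊N1 / 2^(l−1)⌋)`; the floor at 1 keeps
deep, narrow towers well-defined. Consecutive hidden layers are paired into
residual blocks:

    dense(L2) → BN → relu → dense(L2) → BN → (+ skip) → relu → dropout

The skip is the identity when widths agree and a bias-free linear
projection otherwise (the projection kernel also carries the L2 penalty);
an odd trailing layer is a plain dense → BN → relu → dropout stack. Tower
outputs are concatenated into one linear output neuron with L2 on its
weights. Dropout and L2 are shared across layers; the output layer carries
only L2.

Numerical choices:

* Glorot-uniform initialization; Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7);
* learning rate `lr · exp(−wd · epoch)`;
* batch normalization with ε = 1e-3 and running-statistic momentum 0.9 —
  the lower momentum makes inference-mode statistics track training within
  the 128-epoch budget typical here; with 0.99 the running means lag badly
  on short runs;
* inverted dropout (scaling at train time), so inference is a plain pass;
* loss = batch MSE + L2 penalties; early stopping monitors the epoch-mean
  *training* loss with patience `Pat` (the 10% validation split is held out
  and its MSE recorded per epoch — it is the hyperparameter-tuning
  objective, not the stopping signal);
* mini-batches of 32, hard cap of 128 epochs, all randomness (validation
  split, shuffling, dropout masks) from a single integer seed, which makes
  two runs bit-identical on one thread.

The whole network — forward, backward, optimizer — is explicit numpy; the
backward pass is verified against central finite differences in the test
suite, and the parameter count against a closed-form formula.

When a modality is absent (leave-one-year-out drops the year tower) the
architecture simply omits that tower; only the fusion input width changes.
The evaluation adapter trains on the standardized response
(`(y − ȳ)/s_y`, training statistics) and back-transforms predictions: raw
agronomic trait scales (hundreds of g/m²) sit far from the
zero-initialized output neuron and would waste most of the epoch budget on
learning the intercept.

## Hyperparameter optimization

A Gaussian-process surrogate (constant × Matérn-5/2 anisotropic kernel +
white noise, inputs scaled to the unit cube, objective standardized)
with expected improvement, maximized at each step over a seeded
1,024-point random candidate set. Ten scrambled-Sobol points initialize
the design. Integer dimensions (layer counts, widths, patience) are
proposed continuously and rounded at evaluation; width lower bounds are
exclusive at 0, so the minimum rounded width is 1. Non-finite objective
values are recorded with a large finite penalty so the search continues.
The search domain is the network's full hyperparameter box (tower depths
1–4/1–6/1–6, first-layer widths up to 16/1024/64, λ ∈ (1e-8, 1e-2),
dropout ∈ (1e-4, 0.5), log decay ∈ (ln 4e-5, ln 4e-1), patience ≤ 64, log
learning rate ∈ (ln 1e-5, ln 1e-2)). A full tuning run uses 150 guided
iterations; the command-line default is capped at 20 for desk-scale runs.
A same-space random-search optimizer is included as the reference
baseline and is the comparison oracle in the tests.

## Gradient boosting and support-vector baselines

**GBM.** Squared-error stochastic gradient boosting with stumps:
`f₀ = mean(y)`; each iteration draws a without-replacement subsample
(fraction 0.5), fits a depth-1 tree to the residuals, and adds it with
shrinkage ν. For squared loss the per-leaf means solve the line search
exactly, so no separate step-size search is needed. The split finder is an
exhaustive variance-reduction search over all (feature, midpoint)
thresholds, vectorized across features, with ties broken toward the lowest
feature index then the lowest threshold, and a minimum terminal-node size
of 10. Defaults: 5,000 trees, ν = 0.001. The finder is verified against a
brute-force double loop in the tests.

**SVR.** Linear ε-insensitive regression (ε = 0.1, C = 1, tolerance 0.01)
solved in the dual over θ_i = α_i − α_i*:

    min ½ θᵀKθ − yᵀθ + ε‖θ‖₁   s.t.  Σθ = 0, |θ_i| ≤ C,  K = XXᵀ

The equality constraint carries the unregularized intercept. At each step
the maximal violating pair (largest gap between the per-point feasible
bias intervals) is optimized exactly along its one-dimensional restriction,
a piecewise quadratic whose candidate minimizers are enumerated. The
solution is verified against a generic convex-QP solve of the α/α*-split
dual and against local perturbation. The evaluation adapter standardizes
the response (so ε spans 0.1 response SD, matching common SVR defaults)
but deliberately not the feature columns: per-column scaling of the
Cholesky genomic features inflates the near-zero-variance trailing columns
and measurably destroys accuracy.

## Genotype QC and relationship matrices

QC order: heterozygote filter (AB fraction among non-missing calls > 10%
removes the marker; any AB call counts as heterozygous) → recode remaining
AB to the majority homozygote (ties → AA) → missingness filter (> 20% of
lines) → 0/1 B-allele dosage coding and MAF filter (< 0.05 on non-missing
values) → per-marker mean imputation. An all-missing marker is caught by
the missingness rule, never divided by. The GRM is
`G = MMᵀ / Σ_k p_k(1−p_k)` with `M = X − 1pᵀ` — the single-copy analogue
of the standard centered cross-product GRM for 0/1-coded inbred-line
genotypes; monomorphic columns are excluded from both numerator and
denominator. The Cholesky factor is computed with the upper-triangular
orientation `G = LᵀL`; a singular `G` (more lines than informative
markers, duplicated lines) gets escalating diagonal jitter
`1e-8 × 10^m` until factorization succeeds, and the jitter used is
recorded and carried through all reconstruction identities.

## Predictor assembly

NDVI covariates come in two layouts: `dates_aligned` keeps each of the 4
vegetative and 2 grain-filling timepoints as its own column (the same
timepoint is the same column across years), `average` collapses each
period to its within-period mean (1 + 1 columns). NDVI columns are
standardized with training-set statistics only; raw values are preserved
for export. The year design is full one-hot for the network; in GBLUP the
first label (alphabetically) is the reference absorbed by the intercept.
Environments are treated exactly like years for leave-one-out splitting.

## Synthetic trial generator

The generator emulates the statistical structure the models assume:
binary-coded biallelic SNPs with allele frequencies uniform on
[0.05, 0.5], independent across markers; line genetic values drawn with
covariance σ_g² G through the Cholesky factor of the *realized* GRM; one
fixed year effect and one G-correlated interaction deviation per year at
configurable variance shares (defaults 0.2 and 0.1 of a unit total
variance); residuals scaled so var(g)/(var(g)+var(ε)) equals the target
heritability (default 0.5); NDVI timepoints built as
`ρ·g̃ + √(1−ρ²)·noise` plus a (year, timepoint) offset with target genetic
correlation ρ = 0.5, mapped to a plausible reflectance range around 0.6;
phenotypes shifted and scaled to an agronomic range (mean 500, SD ~50
g/m²). Optional AB/NA injection dirties the call matrix for QC testing.
All latent components are returned for recovery tests.

What it does **not** emulate — and therefore what passing tests do not
establish about real data: linkage disequilibrium and population structure
(markers are independent), spatial field trends and design effects
(phenotypes arrive already design-adjusted), non-Gaussian residuals,
NDVI time-series autocorrelation beyond the shared genetic component, and
genotype-by-environment structure richer than a year-specific
G-correlated deviation.

## Problem sizes and runtime choices

The test suite and the acceptance script scale the study down to sizes
that one CPU handles in minutes while keeping every contract intact:
panels of 150–300 lines with 400–600 markers, Gibbs chains of 1,200–2,000
iterations (the mixed-model-equation agreement check uses 22,000 on a
20-line instance), 500-tree boosting ensembles, and Bayesian-optimization
budgets of 30–50 evaluations. These are the package's own desk-scale
defaults for simulation studies; full-scale analyses (thousands of
markers, 12,000-iteration chains, 5,000 trees, 150 tuning iterations)
use the same code paths through configuration only.

## Known limitations

* GBLUP predictions for lines absent from the GRM are impossible by
  construction (no marker path into `G` at prediction time); new lines
  must be in the relationship matrix when the model is fitted.
* The SVR pair solver is quadratic-kernel-matrix-based (n × n memory) —
  appropriate for trial-scale n, not for biobank-scale data.
* The network trains single-threaded for bit-reproducibility; there is no
  GPU path.
* NRMSEP divides by the mean of observed values and is undefined for
  mean-zero traits; the metric raises rather than silently switching
  normalization.
* Variance-component posteriors under the default priors carry prior mass
  away from zero; null-heritability estimates at small replication are
  bounded below by the exact posterior (~0.19 at 150 lines × 2 reps), not
  by sampler error.
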