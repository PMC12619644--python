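# Methods

## The problem

Differential co-expression analysis (DCA) asks whether the *correlation
structure* of a gene pathway depends on a risk factor — as opposed to
differential expression, which concerns means.  Pathways co-regulated under
stabilizing selection can be dysregulated by an environmental or genetic
exposure; the fingerprint of such dysregulation is a change in between-gene
correlations with the exposure, often without any mean shift.  Two practical
obstacles dominate: (i) most pairwise-correlation methods handle only
categorical group comparisons, and (ii) a risk factor that affects expression
*variance* (or batch structure correlated with it) mimics a co-expression
signal and produces false discoveries.

`kdca` implements a kernel association test that handles continuous,
discrete, categorical and multivariate risk factors, and removes mean and
variance effects before measuring co-expression.

## Model and statistic

For expression `Y` (n samples × r genes), risk factor(s) `X`, covariates `C`
and batch variables `M`:

1. **Residualization.** Per gene, fit the mean model
   `Y_jk = β_k X_j + Γ·C + Φ·M + e_jk` (least squares, intercept always
   included; categorical risk factors one-hot encoded with first-level
   reference).  Estimate the conditional SD `s_jk` and standardize
   `ẽ_jk = e_jk / s_jk`.
2. **Cross products.** For each of the `q = r(r−1)/2` gene pairs, the
   per-sample product `Z_ji = ẽ_jk ẽ_jk'` estimates that sample's
   contribution to the pair's correlation (the individual-specific gene
   correlation).  Under the null of no differential co-expression every
   cross-product column is independent of `X`.
3. **Kernels.** Sample-by-sample similarity matrices are built for the
   centered cross products (`K_Z`: linear `ZZ'`, projection `VV'` on the
   retained left singular vectors, Gaussian RBF `exp(−ν‖Z_j−Z_j'‖²)`) and
   for the centered, unit-variance risk factor columns (`K_X = XX'`,
   additive over multiple risk factors).
4. **HSIC statistic.** `T = tr(K_Z K_X)/n` measures the shared structure of
   the two similarity matrices.  For the linear kernel this equals
   `(1/n)Σ_i (Σ_j X_j Z_ji)²` — the statistic aggregates the association of
   *every* gene pair with the risk factor rather than testing pairs one at
   a time.

### Permutation null

Because the mean and variance adjustments are estimated, the null
distribution of `T` is not the textbook HSIC null.  The permutation scheme
preserves the estimated structure: draw a permutation `π`, rebuild
`Y(b)_jk = fitted_jk + s_jk ẽ_{π(j)k}`, and re-run the *entire* pipeline
(mean fit, variance fit, standardization, cross products, kernels) on
`Y(b)`.  Row-wise shuffling keeps gene–gene correlations intact while
severing any link between residual structure and `X`; refitting inside each
permutation reproduces the estimation noise that the observed statistic
contains.  The empirical p-value is `p = (#{T(b) ≥ T} + 1)/(B + 1)` with
ties counted as exceedances, so the smallest attainable p-value is
`1/(B+1)`.

A `refit=False` option recycles the observed fits (algebraically, a row
shuffle of the observed cross-product matrix).  It is faster, and it is
exactly the fixed-kernel null that the asymptotic approximation targets, but
it ignores the estimation effect: at n = 1500 the two nulls differ
substantially (we measured null mean 4.4 vs 7.0 on one instance), which is
why the full refit is the default.

### Variance models

* `groupwise` (default when every risk column is categorical): per-gene
  sample variance within each level (unbiased `n_g − 1` denominator); with
  several categorical risk columns the interaction defines the groups.
* `dglm` (default otherwise): alternate (i) weighted least squares for the
  mean with weights `1/σ̂²` and (ii) a gamma GLM with log link regressing
  `e²` on `[1, variance covariates]`, until the relative change in gamma
  deviance falls below `1e-6` (max 25 iterations, homoscedastic
  initialization, non-convergence returns the last iterate with a flag).
  The variance covariates default to the risk-factor columns; covariate or
  batch columns can be added.  The log link makes fitted variances positive
  by construction; no small-sample correction is applied to the gamma fit —
  the permutation null absorbs the residual bias.
* `constant`: single pooled variance per gene (denominator `n − p`), for
  data known to be free of variance effects; used as the negative control
  in the calibration experiments.

### Kernel combination

Per-kernel empirical p-values are combined with Fisher's method,
`T' = −2 Σ_d log p_d`, and `T'` is itself calibrated against the joint
permutation stream: within permutation `b`, `p_d(b)` is the self-inclusive
rank of `T_d(b)` in kernel `d`'s own null vector (so `p_d(b) ≥ 1/B` and the
logarithm is finite), and `p_combined` applies the same add-one formula to
`T'(b)`.  Because the null combination inherits whatever dependence the
kernels have, the combined test remains calibrated even for identical
kernels (verified in the acceptance suite).

### The Gaussian kernel form

The cross-product Gaussian kernel is sometimes written with a squared
*inner product* in the exponent, `exp(−ν(Z_j·Z_j')²)`.  Taken literally, that kernel
rates orthogonal samples maximally similar: its statistic *decreases* under
genuine differential co-expression (≈0 power where the linear kernel is near
1), and the matrix is not positive semidefinite.  The package therefore uses
the standard RBF form `exp(−ν‖Z_j − Z_j'‖²)` as its Gaussian kernel.  At the
default bandwidth `ν = 1e-4` the exponent is small for typical cross-product
magnitudes, so the kernel operates near its linear regime
`1 − ν‖Z_j − Z_j'‖²`; its HSIC is then a monotone transform of the linear
statistic plus higher-order terms — matching the observation that this
bandwidth "performs well" across settings while larger `ν` targets
non-linear patterns.  The literal squared-inner-product variant is available
as kernel name `gaussian_inner` for comparison; `ν` is a fixed configuration
value, never data-adaptive.

### Eigengene baseline

The comparator tests only the top component: the statistic is `n R²` of the
top left singular vector of the centered cross-product matrix regressed on
the risk-factor column(s), calibrated by the *identical* full-refit
permutation scheme, so the two methods differ only in the statistic.  For a
two-gene pathway (a single cross-product column) the two tests coincide
exactly — a property the test suite checks.

### Asymptotic mode

For large samples a moment-matched Gamma approximation to the weighted-χ²
HSIC null is available (`mode="asymptotic"`): with doubly-centered kernels
`A` and `B`, `E[T] = tr(A)tr(B)/n²` and `Var[T] = 2‖A‖_F²‖B‖_F²/n⁴`.  It is
validated against the exact rank-1 scaled-χ²₁ limit, a spectral Monte-Carlo
oracle, and the `refit=False` permutation null (agreement ~0.01–0.05 in the
central p-range).  It deliberately refuses n < 1000: at expression-study
sample sizes the refit effect described above makes the permutation mode the
only calibrated choice.  Its Fisher combination uses the χ²₆ reference and
therefore assumes near-independent kernels; it is a screening tool, not a
substitute for the permutation test.

## Synthetic data

Two generators define the simulation conditions; their defaults are the
study conditions and are not tuned per experiment.

**Multivariate-normal pathway.**  n = 300, r = 10 (or 50); risk factor
Bernoulli(0.5) (categorical) or Uniform(0, 2) (continuous); covariate
C ~ U(0, 2); per-gene intercepts α_k ~ N(0, 1); mean `α_k + X + C`;
log-variance `1 + δ_k X` with δ_k ~ U(0, δ′), δ′ ∈ {0, 0.1, 0.25, 0.5};
per-*individual* baseline correlation ρ_j ~ U(0.25, 0.50) shared by all
pairs of that individual; correlation shift `ρ_j + τX_j` with
τ ~ U(0.1, 0.2) applied to pairs whose two genes both carry signal
(`null_fraction` controls sparsity; τ = 0 is the global null).  The shift is
interpreted on the *correlation* scale (values in (0.25, 0.5) are
correlation-sized; variances are `exp(·) ≥ e`) and converted to covariance
via the per-gene SDs.  With `sign_scheme="mixed"` each pair draws ±τ once
per replicate; the resulting per-individual correlation matrix may leave the
PSD cone and is repaired by eigenvalue clipping at 1e-8 followed by
rescaling to unit diagonal (the repair count is reported; with the positive
scheme and ρ + τ < 1 repairs never trigger, asserted in tests).  Correlation
parameters outside (−1, 1) raise with the offending sample and pair.  With
three risk factors (each Bernoulli(0.5)) the model uses the scaled sum
`(2/3) Σ_l X_jl`.  Each call draws a fresh risk factor (independent
replicates); `X`/`C` can be passed in to share them across the pathways of
one study.

**Negative-binomial counts.**  10 000 genes with
α_k ~ Lognormal(meanlog 5.54, sdlog 0.697), risk/covariate effects
β_k, γ_k ~ N(0, sd 0.1), latent interaction `δ_k X_j U_jk` with
U_jk ~ N(0, 1) *independent per gene* and δ_k ~ N(0, sd 0.025); NB
dispersion 0.25 (variance μ + 0.25 μ²); each sample multinomially resampled
to a library size drawn from {2×10⁶, 10⁷}.  Because the latent factor is not
shared between genes these pathways satisfy the DCA null, yet after
`log2(count + 2)` the interaction surfaces as a risk-factor variance effect
— the adversarial input for variance adjustment.  The "N(0, 0.01)" /
"N(0, 6.25e-4)" effect scales are read as variances (SDs 0.1 / 0.025); the
SDs are configuration fields, so the alternative reading is one line away.

What the generators do *not* emulate: latent batch structure correlated with
the risk factor, gene-length/GC biases, zero inflation, or realistic pathway
overlap.  Passing tests therefore demonstrate calibration and power under
the stated models, not robustness to unmodelled confounding — for real data
the batch matrix `M` must carry known or estimated confounders.

## Study driver and defaults

`run_study` iterates a GMT pathway collection (pathways with fewer than 5
genes excluded by default, fewer than 2 matched genes skipped with a logged
reason), derives a per-pathway sub-seed by hashing (master seed, pathway
name) — so adding or removing pathways never changes other pathways'
p-values — and attaches Benjamini–Hochberg q-values to the combined
p-values (Storey's q-value is available behind a flag).  Default B = 1000
with a warning when B < R/α for R pathways at level α; an opt-in early-stop
mode abandons pathways with p > 0.1 after 1000 permutations and otherwise
extends the identical permutation stream, so stopped and unstopped runs
agree wherever both report.  Raw counts are transformed as `log2(count + 2)`
with the log library size appended as a fixed mean covariate.

Determinism: every permutation draws its index vector from a counter-based
substream `(seed, b)`, so results are bit-identical across reruns and
independent of execution order or worker count; parallelism over pathways
(joblib) preserves outputs exactly.

## Numerical choices

* Mean-model rank is checked by pivoted QR; collinear columns are named in
  the error.
* Projection kernel retains singular values above `1e-8 × σ_max`; inside the
  permutation engine the equivalent Gram-matrix solve adds a relative
  eigenvalue floor of `1e-12` against float noise (behaviorally identical
  for non-degenerate pathways, verified against the SVD route).
* Gamma-GLM linear predictors are clipped at ±60 (log-variance scale);
  squared residuals are floored at 1e-30 before the gamma fit.
* A permutation whose refit fails (e.g. zero within-group variance after
  reconstruction) is redrawn once from substream `(seed, b, 1)`; a second
  failure aborts with diagnostics.

## Problem sizes used in the checks

The acceptance script runs 200 pathways per null design with B = 1000
permutations (binomial SE of a 5% rate at 200 pathways: ±1.5 points); the
test suite's calibration checks use 150 pathways with B = 400 and the
power-ordering checks 150 replicates with B = 199, sizes chosen so the whole
suite completes on a laptop-class single core while keeping two-binomial-SE
resolution.

## Known limitations

* In single-component ("positive" sign) architectures the eigengene summary
  captures essentially the entire signal; there the Fisher combination pays
  for carrying the projection kernel (near-α power when the signal occupies
  one eigenvector) and can trail the eigengene baseline by a few points of
  power, while gaining large margins whenever the signal is dispersed.  The
  acceptance suite records this honestly.
* The asymptotic mode approximates the *unadjusted* null and is refused
  below n = 1000.
* Latent confounding correlated with the risk factor is out of scope; the
  batch matrix is the user's responsibility.
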