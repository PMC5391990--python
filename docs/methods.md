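# Methods

## Setting and assumptions

We observe `n` subjects with features `g_i ∈ R^dG`, confounds `c_i ∈ R^dC`
and a scalar target `y_i`.  The population of interest is one in which the
confound and the target are independent; a *biased* sample is one whose
empirical `y`–`c` association differs from that.  Throughout, the operative
assumption for instance weighting is that the conditional law of the
features given `(c, y)` is the same in the sample and the population — the
sample differs only in the joint law of `(c, y)`.  Two-level discrete
confounds are encoded as a single {0, 1} column, because the linear ARD
kernel over confounds is appropriate only for continuous or binary
variables; a squared-exponential kernel over one-hot encodings is available
for more levels but is outside the evaluated model family.

## Model family

Every predictor is a zero-mean Gaussian process with a Gaussian likelihood.
With kernel matrix `K(θ)`, noise scale `σ` and (for instance weighting) a
diagonal `W` with entries `1/w_i`, the predictive mean is the weighted
kernel ridge solution `f(x*) = k*(K + σ²W)⁻¹y` and the predictive variance
is `k(x*, x*) − k*(K + σ²W)⁻¹k*ᵀ + σ²`.  The heterogeneous likelihood is
parameterised as per-subject noise variance `σ²/w_i`; a point with integer
weight `m` is then exactly equivalent to `m` unit-weight replicas in the
predictive mean, which ties the weighted GP to the weighted
empirical-risk-minimisation view of instance weighting.  (The equivalence
holds at given hyperparameters; under free evidence maximisation the
replicated and weighted models have marginal likelihoods differing by a
σ-dependent constant, so their optima need not coincide exactly.)

Hyperparameters `(θ, σ)` maximise the log evidence
`log Z = −½ yᵀA⁻¹y − ½ log|A| − (n/2) log 2π`, `A = K + σ²W`.  Gradients
use the standard identity `∂ log Z/∂p = ½ tr((ααᵀ − A⁻¹) ∂A/∂p)` with
`α = A⁻¹y`, written against log-parameters so positivity needs no
constraints; the same identity covers the heterogeneous likelihood through
`∂A/∂(log σ) = 2σ²W`.  Gradient correctness is verified against central
finite differences in the test suite for both likelihoods.

### Numerical choices

* **Initialisation** (data-driven): linear scale `l₀ = √(mean ‖x‖²)`, bias
  `b₀ = sd(y)`, per-column ARD scales from the column RMS, `σ₀ = sd(y)/2`.
* **Optimisation**: L-BFGS-B in log space, box `|log h| ≤ 15`, up to three
  restarts offset by 0 and ±1.5 in log space; the best final evidence wins
  and a restart never returns a point worse than its start.  The procedure
  is deterministic: repeated fits are bit-identical.
* **Factorisation**: Cholesky with adaptive jitter starting at
  `1e-10 × mean diag(A)`, doubled at most ten times before a numerical
  error is raised.
* **Standardization** uses the sample (n−1) variance convention, training
  rows only; constant training columns map to all-zero columns (kept, not
  dropped, so weight-map indexing is stable).  The choice of variance
  convention only rescales features by a constant, which the kernel scale
  hyperparameter absorbs.

## Strategies

* **images_only** — linear-plus-bias kernel on standardized features.
* **adjusted_images** — features first residualized on the
  intercept-augmented confounds, `G^A = G − Ĉ(Ĉ_Sᵀ Ĉ_S)⁻¹ Ĉ_Sᵀ G_S`.  In
  the evaluation protocol the fitting subset `S` pools training and test
  rows (transductive adjustment), the configuration the protocol evaluates;
  a train-only mode exists for deployment settings where test data is
  unavailable at training time.  Features are adjusted first and then
  standardized with training-row statistics — the two operations do not
  commute and the ordering is a documented package choice.
* **images_confounds** — confounds appended to the features; the kernel sum
  separates a linear-plus-bias term over features from a linear ARD term
  over confounds, so each confound's contribution is controlled by its own
  relevance scale.  Continuous confound columns are standardized; {0, 1}
  encodings are left unscaled (their scale is absorbed by the ARD
  hyperparameter, and keeping the encoding raw preserves interpretability
  of the fitted scale).
* **instance_weighted** — weights `w_i = P̂(y_i)/P̂(y_i|c_i)` from two
  auxiliary GPs (below), then a heterogeneous-likelihood GP on the
  standardized features.  The predictive function does not use the
  confounds; the weighting alone refocuses training on the
  confound-independent population.  A weighted images+confounds variant is
  deliberately not provided.

Predictions for bounded integer scores can be rounded to the nearest whole
number inside configured bounds (e.g. 0–30 for a dementia screening score).
For linear kernels the primal weight map `v = Xᵀα/l²` over the feature
block is recoverable, with `f(x*) = x*·v + b²Σα`.

## Instance weights and balance

The marginal density `P̂(y)` comes from a GP whose kernel is a pure bias
term — effectively fitting a normal distribution to `y` — and the
conditional `P̂(y|c)` from a bias + linear-ARD-on-confounds kernel, a linear
confound→target model with uncertainty.  Both are evidence-maximised and
evaluated as posterior predictive densities at the training points
themselves; this in-sample evaluation is deliberate (the weights are
needed exactly at the training points) and carries the usual in-sample
optimism.  Raw ratios are rescaled to mean one by default so the fitted
noise scale stays comparable with the unweighted model; raw ratios and an
optional quantile clip are available but off by default.  The support
condition behind density-ratio weighting (numerator support contained in
denominator support) is not verified analytically; a finite-positive-ratio
guard stands in.

Balance of the weighted sample is diagnosed with the weighted standardized
difference `(m₀ − m₁)/√((s₀² + s₁²)/2)`, with frequency-weighted means and
the unbiased frequency-weighted sample variance
`s² = Σw/((Σw)² − Σw²) · Σ wᵢ (yᵢ − m)²`.  Constant weight vectors reduce
to the classical formula bit-exactly.

## Evaluation protocol

The pool is half-split into folds `F₁, F₂`; from each fold, `J` training
samples are drawn and the opposite fold is predicted, giving `2J` runs.
Biased draws sample without replacement with probabilities
`∝ exp(λ·z(y)·c̃)` (`z` the within-fold standardized target, `c̃ ∈ {−1,+1}`
the group sign, `λ = 1.5` by default and 0 for unbiased draws), redrawing
until a two-sided equal-variance t-test of `y` across groups gives
`p < 0.05` (biased) or `p ≥ 0.05` (unbiased).  The exponential tilt is the
package's concrete mechanism for "prefer one group at high target values":
it is smooth, direction-controllable and reduces to uniform sampling at
`λ = 0`.  An optional stratified mode fixes the group ratio of the drawn
sample (for populations with unequal group sizes); it is off by default.

Folds are partitioned at the pool median of the target (ties to the low
subset).  Reported metrics per run: plain MSE; group-balanced MSE (within
each subset, the unweighted mean of the two group-specific MSEs, subsets
recombined in proportion to size — the fixed denominators of the original
two-dataset design generalise to the fold size); and signed group-difference
errors (level-0 minus level-1 MSE per subset), summarised by the
size-weighted mean of absolute values.  Stratified metrics are reported as
NaN for runs whose subset × group cell is empty rather than aborting the
plain MSE.

The restricted permutation test shuffles targets within confound level,
separately within each fold, in both training and test data; this preserves
the confound–target association while breaking any feature–target link, so
it tests conditional independence of features and target given the
confound.  The identity labelling is counted, `p ≥ 1/n_perm`, 500
permutations by default, and a p-value is computed per metric.  All
randomness flows from one seed through named substreams (split, draws,
permutations), so any stage is replayable.

Cross-validation is intentionally absent: with a biased sample, held-out
folds share the bias, so cross-validated accuracy does not estimate
performance on the population of interest.

## Synthetic data

`generate_population` draws `y ~ N(μ, τ²)` independent of a Bernoulli(½)
group, and features `G = y·aᵀ + c̃·dᵀ + ε` with `ε ~ N(0, σ_g²)` i.i.d.
The signal loadings `a` are sparse (10% density by default) with entries
`~ N(0, (signal_strength·σ_g)²)`; the confound loadings `d` are dense with
entries `~ N(0, (confound_effect·σ_g)²)`, so both effect sizes are in units
of the per-feature noise sd and the default confound effect is one feature
sd.  The family is linear-Gaussian to match the linear-kernel model class;
a nonlinear confound→feature map can be injected but is untested surface.
What this generator does *not* emulate: spatial covariance and smoothness
of real images, site-specific variance differences, non-Gaussian score
distributions, or hidden confounds — so passing tests demonstrate
correctness of the machinery and the direction of the studied effects, not
performance on real imaging data.

`generate_conditional_null` gives the null of the permutation test: the
group shifts both the target (`y = shift·c̃ + noise`) and the features
(`G = c̃·dᵀ + noise`), with no feature–target link given the group.

`generate_misspecification_demo` is the single-feature demonstration of why
covariate shift is harmless under correct specification and harmful under
misspecification.  A latent score `t` drives the feature `g = t + γ·c̃` and
the target `y = t + ν·t³ + ε`.  Biased training samples shift the latent
mean per group (`t = z + δ·c̃`, `z ⟂ c̃`, δ = 1 by default) rather than
selecting on the observed `y`: selection on the observed target would tilt
the noise term and alter `E[y | g, c]` itself, whereas the latent shift
leaves the conditional law of `y` given `(g, c)` untouched and makes the
biased design an exact linear reparametrisation of the unbiased one.  With
`ν = 0` a linear model in `(g, c)` is therefore exactly specified and
biased and unbiased training attain identical expected test error; with
`ν > 0` the best linear approximation depends on the training design and
biased training degrades unbiased-test accuracy.  Setting the nonlinearity
to zero reproduces the correct regime exactly.

## Problem sizes used in the automated studies

The acceptance studies run at sizes chosen to exercise the
high-dimensional (`dG > n`) regime the framework targets while remaining
desk-scale: protocol populations of n = 400 with 300 features and J = 2
(training samples of 100 per draw), 50-replicate balance studies at n = 100
per sample, 100-replicate misspecification demonstrations at n = 200, and
permutation calibration over 100 datasets of n = 60 with 30 features, 100
permutations each, with hyperparameters fixed at their data-driven
initial values.  `scripts/acceptance.py` re-runs the same studies (three
protocol replicates, 20 balance samples, 50 calibration datasets) and
writes every measured quantity to JSON.

## Known limitations

* Dense Cholesky solves limit `n` to a few thousand subjects; there are no
  sparse or inducing-point approximations.
* Density-ratio weights rely on the Gaussian/linear model class of the two
  auxiliary GPs; strongly non-Gaussian targets or nonlinear confound–target
  relationships will produce miscalibrated weights.
* The adjustment model is linear; when the confound acts nonlinearly on the
  features, residualization can worsen rather than remove bias.
* Multi-level discrete confounds are supported only through the optional
  one-hot squared-exponential kernel, which is outside the evaluated
  family.
* The evaluation presumes a two-level confound for its stratified metrics;
  continuous confounds are supported by the models and the weighting but
  not by the balance/difference diagnostics.
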