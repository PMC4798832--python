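# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `ncii`, in the order the pipeline applies them.

## The generative model (design_sim)

The simulator produces one row per singly raised embryo in a full-factorial
NC II design: `n_dams × n_sires` families, each contributing a uniformly
drawn number of replicates (default 5–7) to each of nine raw treatment
groups. The three control groups (untreated plus two citrate-dispersant
doses) are pooled to a single control before any analysis, giving seven
analysis groups; pooling happens once, in the allocation, and the pooled
label is used everywhere downstream.

Each Gaussian trait t follows

    y = μ_t + τ_t[group] + s_i + d_j + (sd)_ij + e,

with independent zero-mean normal effects at variances (σ²_s, σ²_d, σ²_sd,
σ²_e). Sire effects are drawn **jointly across analysis groups** from
N(0, σ²_s · R_G): R_G = 𝟙𝟙ᵀ (all ones) makes a sire's effect literally
identical in every environment (no G×E); R_G = I reshuffles sire rankings
freely. The square root of R_G is taken by eigendecomposition so the
perfectly correlated (singular) case works. Dam and sire×dam effects are
constant across environments; the simulator's G×E dial is the sire term,
matching the quantity the reaction-norm tests target.

Larval length and log yolk volume add a linear term b·(hatch − mean hatch):
b_length = +0.010 mm/DD (late hatchers are longer), b_logyolk = −0.004 /DD
(late hatchers have consumed more yolk). Survival is Bernoulli with logit
mean logit(1 − p_mort) plus optional logit-scale random effects (default
variance 0, since observed mortality in this system is rare and
treatment-independent). Dead embryos carry no trait values. Size traits are
observed only on a random fraction (default 0.12) of survivors per analysis
group, emulating the measurement subsample of the source design.

Yolk volume is reported as a prolate spheroid, V = (π/6)·L·W², the standard
salmonid yolk-sac formula; the coefficient is configurable. The simulator
draws the volume on the log scale and back-computes the two axes from a
noisy aspect ratio (default 1.35), so every record is exactly consistent
with the declared formula. Hatching time stays on the degree-day scale
(6.5 °C × days); records must exceed the 240.5 DD treatment start, and a
validator enforces all record invariants on every simulated or loaded set.

**Default parameters are synthetic.** They are chosen once to emulate the
study system qualitatively — hatching time: μ = 360 DD, (σ²_s, σ²_d, σ²_sd,
σ²_e) = (20, 25, 5, 50) so h² = 4·20/100 = 0.8; dam-dominated variance for
length and log yolk volume; earlier hatching under high-dose silver
(−25 DD for ionic silver, −8…−10 DD for high-dose nanoparticles, ≈0 at low
dose) and larger yolk under high-dose AgNO₃; compound-symmetric R_G with
ρ = 0.95 (near-unity cross-environment genetic correlation); p_mort =
0.005. They are not estimates of any real data set. Consequently, passing
tests demonstrate that the estimators recover *this* structure — balanced
Gaussian components, homoscedastic residuals, missingness completely at
random — not that real embryo data satisfy those assumptions.

## REML/ML engine (reml_lmm)

All Gaussian models share the form y = Xβ + Σ_k Z_k u_k + e with
independent scalar variance components (diagonal random-effects covariance,
including for the group-crossed interaction terms — the variance-component
reading of a random slope–intercept model). Writing σ²_k = γ_k σ²_e and
H(γ) = I + Σ γ_k Z_k Z_kᵀ, β and σ²_e have closed forms given γ, so the
optimizer searches only over log γ (bounded in [−30, 10]), starting from
γ = 1 (equal partition of the response variance). All linear algebra runs
through the Woodbury identity on the q×q matrix I + G^{1/2}Z'ZG^{1/2},
which stays well conditioned as components approach zero. The response is
centred internally (the likelihood is invariant because X contains the
intercept); without this, quadratic forms in y lose ~6 significant digits
at hatching-time magnitudes and the optimum wanders by ~1e−4 relative.
Optimization is Nelder–Mead followed by a Powell polish (both derivative
free, deterministic); on balanced data the result matches the
expected-mean-squares closed form to better than 1e−6 relative. Estimates
below 1e−8 × var(y) are reported as exact zeros and flagged as boundary
terms; non-convergence is flagged, never silent.

The balanced-design oracle (`anova_ncii_oracle`) equates observed mean
squares to expectations (σ̂²_e = MS_E; σ̂²_sd = (MS_SD − MS_E)/r; σ̂²_s =
(MS_S − MS_SD)/(r·n_dams); σ̂²_d = (MS_D − MS_SD)/(r·n_sires)) and
deliberately reports negative solutions rather than truncating — it is a
verification tool, not an estimator.

Likelihood-ratio tests use the χ² reference with df = number of dropped
parameters (one per scalar variance term, one per fixed coefficient). For
a single variance term the point-mass/χ²(1) 50:50 boundary mixture p-value
is reported alongside; the naive p is conservative, which the null
simulations confirm. Convention: random-term tests compare REML fits with
identical fixed structure; fixed-term tests compare ML fits. Each interaction
term contributes exactly one variance parameter, so the three-way
(sire×dam×treatment) test has df = 1 under this parameterization; the df
used is always reported with the statistic rather than assumed.

Pairwise treatment contrasts take all C(g,2) differences of treatment-level
means from one fitted model and adjust them by the single-step max-|Z|
method: adjusted p_i = P(max_j |Z_j| ≥ |z_i|) under the joint normal with
the contrast estimators' correlation, evaluated by seeded Monte Carlo
(default 10⁵ draws; the seed is an explicit argument recorded in the
output). Adjusted values are floored at the raw p to respect the
familywise ≥ per-comparison ordering despite Monte Carlo noise.

Mortality uses a binomial-logit GLMM estimated by Laplace approximation:
an inner penalized Newton solve for the joint (β, u) mode (random effects
reparameterized as u = √σ²·v so the zero boundary is smooth), an outer
derivative-free search over log variances. Linear predictors are capped at
|η| = 30; hitting the cap (complete separation, all-survive subsets) flags
the fit as a boundary case with finite estimates instead of raising.

## Variance decomposition (quantgen)

V_A = 4σ²_s, V_Dam = σ²_d, V_NA = 4σ²_sd, V_Res = σ²_e, and V_P is the sum
of the four *raw* components, so h² = 4σ²_s / V_P ∈ [0, 4]. The raw-sum
denominator is the only reading under which strong-heritability systems
can show h² near or above 1, as this one does; the alternative (inflated
components in the denominator) is not used. The reported V_Res still
contains ½V_A and ¾ of the dominance variance; the decomposition carries
that caveat as an annotation rather than attempting a subtraction.
Epistasis is assumed negligible. The decomposition applies draw-wise to
posterior chains, which is how HPD intervals for V_A and h² are obtained.

## Bayesian machinery (mcmc_bayes)

The Gibbs sampler alternates (i) a joint multivariate-normal draw of all
location effects (fixed coefficients under a vague N(0, 10⁸) prior,
random effects under their component variances) and (ii) scaled
inverse-gamma draws for each variance. The prior "inverse-gamma(ν, V)"
follows the animal-model convention: shape ν/2, scale νV/2 — at the
default (ν = 0.002, V = 1) essentially flat on the variance. This
parameterization choice changes the prior and is therefore fixed and
documented here.

Chain defaults are desk-scale (50,000 iterations, 5,000 burn-in, thin 10);
the pipeline uses 20,000/2,000/10 per model. Run length affects Monte
Carlo error only; heavyweight regimes (millions of iterations, thinning
1000) are supported through `ChainSettings` but not default. With only 4
dam levels the dam-variance posterior is strongly right-skewed, so its
posterior mean can sit well above the REML point estimate while the
posterior mode agrees — this is a property of the model, and the reason
both mode and mean are reported with the HPD bounds.

HPD intervals are the shortest contiguous window over the sorted draws
containing ⌈prob·n⌉ of them; ties resolve to the lowest lower bound.
Posterior modes are the argmax of a Silverman-bandwidth Gaussian KDE on a
512-point grid. DIC uses the conditional-deviance convention: deviance
per draw is −2 log N(y | Xβ + Zu, σ²_e I) at that draw's location effects,
pD = mean deviance − deviance at the posterior means, and a ΔDIC ≥ 10
(boundary inclusive) is called a significant difference in fit.

The Heidelberger–Welch diagnostic estimates the spectral density at zero
from the second half of the chain by an AR fit with AIC order selection,
then applies the Cramér–von Mises test to the standardized cumulative-sum
process, discarding initial 10% increments (up to 50%) until it stops
rejecting at α = 0.05; the halfwidth test passes when half the 95% CI of
the mean is ≤ 0.1·|mean| (α and ε are the conventional defaults). The CvM
limiting CDF is computed by the classical Bessel-K series for statistics
≤ 1.2 with the principal-eigenvalue exponential tail (rate π²/2) spliced
on above. Known limitation: the AR-based normalization absorbs
near-deterministic trends (the fitted AR root approaches 1 and inflates
the variance estimate), so an almost noise-free drift can pass; drifts and
mean shifts of realistic size relative to the chain's noise are caught.
The diagnostic is always reported, never used to gate results.

## G×E analysis (gxe)

Interaction tests subset to the pooled control plus one treatment and
compare the base REML model {sire, dam, sire×dam} against base + one
group-crossed interaction term at a time. Paternal sibgroup means (per
sire per analysis group, pooled over dams, surviving measured offspring
only) feed pairwise-complete Pearson correlations with t-based two-sided
p-values and a Bonferroni threshold of 0.05/21 for seven groups, reported
at three decimals (0.002) with full precision used internally. The
family-mean estimator is conservative: within-family sampling noise
attenuates the correlation toward zero, shrinking as offspring per sire
per environment grow — the tests verify this monotonicity at r ∈
{2, 10, 50}. Cells with fewer than three complete sire pairs yield a
missing correlation with a warning; effective counts are reported so users
see the n behind each coefficient.

## Pipeline

Stage order: validate → pool controls → mortality GLMM + treatment LRT →
hatching LMM + contrasts → size-trait LMMs with the hatching covariate
(yolk volume log-transformed) → per-treatment variance models and
LRT ladder (full vs no-interaction; then sire and dam tests against the
sire+dam reference, mirroring the model-selection policy of deferring to
the smaller model when the interaction does not improve fit) → Gibbs
chains with HPD/mode/DIC/HW → interaction suites (control vs each of the
six silver treatments) → sire-mean correlations. Every stage logs to
stderr and emits its table even at boundary estimates; a failure writes an
`INCOMPLETE` marker naming the stage and re-raises. All child seeds derive
from the single config seed via `SeedSequence`, so a config plus seed
determines every emitted number; tables are written as plain CSV with a
`run_metadata.json` carrying the seed, config hash, versions and
timestamp.

## Problem sizes used in tests and the acceptance script

Simulation suites run at the design scale (4 dams × 12 sires, 3–6
replicates per cell): 200 replicates for parameter recovery, 1000 (tests)
or 400 (acceptance script) for null LRT calibration, and 15,000-iteration
chains for cross-engine agreement on a 10 × 30 × 6 layout where the
posterior concentrates. These sizes keep Monte Carlo error well below the
tolerances being checked while completing in minutes; they are the
package's own desk-scale choices.

## Known limitations

- Random-effects covariances are diagonal; full slope–intercept covariance
  matrices and factor-analytic G structures are out of scope.
- No Satterthwaite/Kenward–Roger df corrections; fixed-effect inference
  beyond LRTs and normal-theory contrasts is not provided.
- The GLMM handles binary responses only, by Laplace approximation (no
  adaptive quadrature); rare-event variance components are weakly
  identified and often sit at the boundary.
- Heritability above 1 is reported as computed; users comparing across
  studies should note the 4×-sire estimator convention.
- The simulator's missingness is completely at random within groups; real
  measurement subsampling may not be.
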