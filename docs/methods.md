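# Methods

## Data model and filtering

The unit of observation is one annual N₂O flux measurement from a
fertilization experiment: publication id, applied-N dose (kg N ha⁻¹),
replicate index and emission (kg N₂O-N ha⁻¹ yr⁻¹), plus metadata flags.
Six exclusion criteria restrict the analysis to fertilized agricultural
mineral soils: natural areas, NO-only measurements, organic soils,
nitrification inhibitors, grazing systems, and doses strictly above
500 kg N ha⁻¹ yr⁻¹ (a dose of exactly 500 is retained). The criteria are
applied in that fixed order and the audit attributes each dropped record
to the first criterion it violates, so the audit counts always sum to the
input size regardless of how many criteria a record violates. Flags are
interpreted per record; if a source encodes them per experiment, the
caller should propagate them to rows before reading.

## Response models

Thirteen structures cross four choices: linear vs exponential mean,
presence of the applied-N term, fixed vs random intercept, fixed vs random
N effect (a random slope requires the N term), and ML vs Bayesian
estimation for the two all-random variants. Random effects and residuals
are independent Gaussians. Emissions are modelled on the natural scale
even for the exponential mean, so the response is *not* lognormal — the
exponential enters the mean only, and simulated emissions can be negative.

Emission *due to N* at dose X is the mean response minus the zero-dose
(background) response with random effects at zero; for exponential models
the background is $e^{\mu_0}$. The marginal EF is the dose-derivative of
the mean response. Threshold doses where the marginal EF reaches a target
(default the IPCC constant 0.01) use the closed form
$X^*=(\ln(t/\mu_1)-\mu_0)/\mu_1$ and are reported rounded to the nearest
10 kg, matching the granularity at which such thresholds are usually
quoted. The threshold deliberately uses the *marginal* EF: it is the
definition under which the published threshold doses for the all-random
and random-slope exponential models (220 and 240 kg N ha⁻¹) are
reproduced; the average-EF definition gives different values.

## Maximum-likelihood estimation

Linear mixed models have an exact marginal likelihood; it is evaluated
per publication through the low-rank (Woodbury) identity on
$\tau^2 I + V V^\top$ with $V$ holding the $\sigma_0$ and $\sigma_1 x$
columns, vectorized across publications. For exponential models the
random effects are integrated out numerically by adaptive Gauss–Hermite
quadrature: per publication the conditional mode is found by a damped
Newton ascent (analytic gradient and Hessian, ridge regularization,
backtracking), and the quadrature grid is recentred at the mode and scaled
by the Cholesky factor of the negative Hessian. One node per dimension
reduces to the Laplace approximation; the default is 9 nodes per
dimension (81 points for two random effects), which agrees with dense-grid
brute-force integration to well below 10⁻⁵ relative error on test
instances. Modes are cached across likelihood evaluations to warm-start
the inner Newton iterations.

The optimizer is BFGS on $(\mu_0[,\mu_1][,\log\sigma_0][,\log\sigma_1],
\log\tau)$; the log transform enforces positivity, and log-SDs below −10
are flagged as boundary estimates. Starting values come from OLS (linear)
or a log-scale regression with emissions clipped below at 0.05 (an
arbitrary small positive floor; only the start is affected). Fixed-effects
linear models (`L-0-F`, `L-N-FF`) use the exact closed-form MLE
(OLS with $\hat\tau^2=\mathrm{RSS}/n$) — identical to the optimizer's
optimum and much faster, which matters for the bootstrap. Standard errors
for $\mu_0,\mu_1$ come from the inverse observed information
(central finite-difference Hessian of the full parameter vector). BFGS
occasionally stops with a "precision loss" status while already at the
optimum (finite-difference gradients); a final gradient below 1 in
absolute value is therefore accepted as converged. AIC $=-2\ell+2k$ and
BIC $=-2\ell+k\ln n$ use $n$ = number of observations (not publications).
The `%AIC`/`%BIC` columns of the selection table are percentage increases
relative to the best model *within each family* (linear, nonlinear), so
each family's best scores zero.

This estimator is an adaptive-quadrature maximum likelihood; tools that
use linearization-based approximations (Lindstrom–Bates) can give slightly
different estimates on identical data. Published estimates are therefore
used here as generating truths for simulation, never as exact targets for
refits of other datasets.

## Bayesian estimation

The two Bayesian models get priors $\mu_0,\mu_1\sim N(0,1000)$ (variance
1000, prior SD ≈ 31.6, conventionally reported as 32) and
$\tau,\sigma_0,\sigma_1\sim U(0,100)$. The sampler is
Metropolis-within-Gibbs: scalar random walks on $\mu_0,\mu_1$ and the
log-SDs (with the log-transform Jacobian), a vectorized joint random-walk
update of each publication's $(\alpha_{0i},\alpha_{1i})$ block
(conditionally independent across publications), and two
likelihood-invariant *shift* moves that translate a mean and its latent
deviations in opposite directions ($\mu\to\mu+\delta$,
$\alpha_i\to\alpha_i-\delta$). The shift moves cost almost nothing (the
data likelihood is unchanged) and are essential: without them the chains
crawl along the ridge between a population mean and its random effects and
the slope's Gelman–Rubin statistic stays far above 1.1. Proposal scales
adapt toward acceptance 0.44 (scalars) / 0.30 (latent blocks) during
burn-in only; after burn-in they are frozen, preserving detailed balance.
Chains start overdispersed from distinct seed streams.

Defaults for test-scale runs are 3 chains × 20 000 iterations, 50%
burn-in, thinning 10 — a scaled-down stand-in for production runs of
3 × 100 000. Convergence is summarized by the potential scale reduction
factor computed on the second half of each stored chain; the estimator is
clamped below at 1 (the finite-sample formula can dip slightly under 1).

DIC is $\bar D + p_D$ with $p_D=\bar D-D(\hat\theta)$, where the deviance
*conditions on the latent random effects* (the convention of the BUGS
family) and the plug-in uses posterior means of parameters and latents.
This choice changes $p_D$ materially (here $p_D$ is close to the number of
latent effects) and is stated because the marginal-deviance alternative
would give different absolute DIC values; model *comparisons* between the
linear and exponential variants are unaffected in our experiments.
Credibility bands evaluate the population-level mean response at each
posterior $(\mu_0,\mu_1)$ draw and take pointwise 2.5/50/97.5 percentiles.

## Uncertainty bands and the ensemble

Bootstrap bands resample whole publications with replacement (cluster
bootstrap). The resampling unit is a deliberate choice: the mixed models
treat the publication as the exchangeable unit, and observation-level
resampling would destroy the within-publication correlation; an
observation-level mode remains available behind a flag. Each of the B
(default 500) resamples is refitted warm-started at the full-data
estimates; refits that fail are dropped and counted, and more than 10%
failures aborts the band. The band's point curve is the pointwise median
of the resampled predictions (guaranteeing lower ≤ point ≤ upper); bands
are background-subtracted by default so every band is exactly zero at
dose 0.

The ensemble keeps every model whose AIC *and* BIC are within 10% of its
family's best, then adds the two Bayesian members; on the published
ranking this selects exactly the three best models of each family plus the
two Bayesian counterparts (eight members). The ensemble range is the
pointwise envelope: min of member lower limits to max of member upper
limits (best/worst-case scenarios), with the envelope of member point
predictions giving the equation-only uncertainty. The IPCC comparison
reports, per dose, the constant-EF point (1%) and range (0.3%–3%) next to
the ensemble envelope, with containment flags.

Predictive percentiles describe between-experiment spread: Monte-Carlo
draws of the random effects (optionally plus a residual) pushed through
the mean response. Whether a residual is included and whether the
background is subtracted are exposed as switches, since both readings are
defensible and they change the percentiles; the defaults (no residual, no
subtraction) describe the experiment-specific *total* emission level.

## Synthetic data

The generator emulates the hierarchical structure the models assume:
publication-level random effects drawn exactly as specified, per-
publication dose lists, replicate-level residuals. The default world
design has 203 publications × 3 dose slots × 2 replicates (1218 records —
the same order as the ~1000-measurement compilations the models target).
Each dose slot is 0 (an unfertilized control) with probability 1/3,
otherwise lognormal(meanlog 5.08, sdlog 0.70) truncated at 500 by
rejection; this calibration gives large-sample dose medians near 100 and
means near 124 kg N ha⁻¹, matching the marginal summaries of the global
compilation. Real replicate counts are not reported in such compilations;
2 per dose is a configurable default. Simulated emissions keep their
Gaussian tails (including negative values) because the likelihoods assume
untruncated normals; real measurements are positive and right-skewed, so
parameter-recovery success here shows correctness of the estimators under
the assumed model, not robustness to real-data misspecification (no
covariate structure, no heteroscedasticity, no measurement-method
effects are emulated).

## Problem sizes used in the test suite

Recovery and model-comparison experiments run at the study scale of 203
publications; the bootstrap coverage experiment uses 50 replicate datasets
of 60 publications with B = 200 and the fast closed-form fixed-effects
model; MCMC checks use 3 × 8 000–20 000 iterations. These sizes were
chosen as the smallest at which the corresponding statistical statements
are comfortably stable.

## Known limitations

* Correlated random effects are not implemented (the independent-effects
  variants are the scope; correlated fits add little on such data).
* REML and experiment-length weighting are out of scope.
* The AGQ estimator is deterministic but approximate; likelihood values
  carry quadrature error that shrinks rapidly with the node count.
* Bootstrap bands for exponential mixed models are computationally heavy
  (each resample is a full AGQ fit); the default B = 500 is practical for
  linear members and small node counts, and can be reduced per model.
* Country/continent-scale averaging over national dose distributions is
  not provided; the nonlinear response means averages must be taken over
  dose distributions, not at the average dose.
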