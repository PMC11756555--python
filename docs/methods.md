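# Methods

`driftsem` implements a computational pipeline for dot-probe attention data:
trial-level reaction times and accuracies are cleaned, described by a Wiener
diffusion model fitted per participant and condition with population MCMC,
and the resulting parameters enter structural equation models alongside
performance- and questionnaire-based social-cognition measures to predict
perceived (PSI) and objective (OSI) social isolation. A synthetic-study
generator with a fully known latent structure makes every stage testable
without access to human data.

## Decision model

A two-choice trial is modelled as a Wiener diffusion with unit diffusion
coefficient between absorbing boundaries 0 and `a`, starting at `z = a/2`.
The upper boundary represents a correct response, the lower an error; with
the start point fixed at the midpoint there is no response bias, which is the
natural parameterisation when boundaries are defined by accuracy rather than
stimulus identity. Five parameters are free:

| parameter | meaning | unit | default population mean (baseline / angry) |
|---|---|---|---|
| `v` | drift rate (processing efficiency) | evidence/s | 4.098 / 4.003 |
| `a` | boundary separation (caution) | evidence | 1.2 |
| `t0` | nondecision time (encoding + motor) | s | 0.347 / 0.343 |
| `st0` | width of uniform `t0` variability | s | 0.15 |
| `sv` | SD of Gaussian drift variability | evidence/s | 1.0 |

The diffusion coefficient is fixed at `s = 1`; the drift and boundary scales
above are on that convention (drift means near 4, nondecision time near
0.35 s). The condition-specific means for `v` and `t0` are the observed
condition averages this kind of dot-probe task produces; the remaining
defaults are chosen once as typical values for a fast two-choice detection
task — `a = 1.2` puts predicted accuracy near 0.98, `st0 = 0.15 s` and
`sv = 1.0` are mid-range for simple perceptual tasks. Between-person SDs
default to 0.443/0.483 (`v`), 0.039 (`t0`), and 0.15/0.04/0.25 for
`a`/`st0`/`sv`.

### First-passage-time density

The defective density of hitting the lower boundary at decision time `t_d`
is evaluated with the standard small-time and large-time series expansions
of the Wiener first-passage problem, switching to whichever representation
needs fewer terms for an absolute truncation error of 1e-7. Gaussian drift
variability is integrated in closed form (it multiplies the zero-drift
series by a normal-mixture factor); uniform nondecision-time variability is
integrated with 10-point Gauss-Legendre quadrature over the part of the
`t0` window compatible with the observed RT — integrating only up to `t`
avoids quadrature across the kink where the decision-time density vanishes,
which would otherwise corrupt the leading edge of the predicted RT
distribution. Correct responses use the mirrored process (drift `-v`). The
per-trial likelihood is floored at 1e-29 before taking logs so that sampler
excursions outside the data support stay finite. The density core is
compiled with numba.

### Simulator

Trials are simulated by an Euler scheme with exact Brownian-bridge
crossing probabilities inside each step: after every increment the
probability that the path touched either boundary within the step,
conditional on the endpoints, is `exp(-2 d1 d2 / dt)` per boundary, and a
uniform deviate decides whether an unobserved crossing occurred. Because
this bridge correction is exact given the endpoints, the remaining bias is
limited to double-boundary events within one step (negligible for
`a >> sqrt(dt)`) and the placement of the crossing time inside the step
(uniform; at most one step width). The default step is 0.5 ms, at which
10^6-trial histograms agree with the analytic density bin by bin within
Monte-Carlo error (a 1-ms step leaves a barely detectable residual bias at
that trial count). Steps far from both
boundaries skip the bridge computation (crossing probability below e^-18).

## Preprocessing

Within each participant and condition, in one pass: trials without a
response are removed, then responses faster than 200 ms, then reaction
times outside mean ± 2 SD, the moments being computed on the trials that
survived the first two rules. The window is closed (values exactly at the
boundary are kept) and the rule is not iterated — a single pass is
deterministic and order-independent. The 2-SD trim operates on raw RTs, not
log-RTs. Participants responding on fewer than 50% of all presented trials
(both runs pooled) are removed entirely; exactly 50% is kept. Input CSVs
carry RTs in milliseconds; everything internal is in seconds.

## DE-MCMC estimation

Each participant x condition block is fitted independently with all five
parameters free, by differential-evolution MCMC: 15 chains (three per
parameter), 2000 iterations, 1000 discarded as burn-in. The proposal for
chain `k` is `x_k + gamma (x_m - x_n) + U(-0.001, 0.001)` with `m != n != k`
drawn without replacement and `gamma = 2.38 / sqrt(2 d)`; acceptance is
Metropolis on the log posterior. Priors are bounded flats — `v` in (-10,
10), `a` in (0.2, 5), `t0` in (0.05, 1), `st0` in (0, 0.5), `sv` in (0, 5),
with the joint constraint `t0 - st0/2 > 0.05` — wide enough to be
noninformative at these data sizes while keeping the posterior proper.
During burn-in only, a migration step fires with probability 0.1 per
iteration: a random subset of chains passes states along a cycle with
Metropolis acceptance. Pure DE proposals scale with the current population
spread, so a chain stranded far from the mode after random initialisation
can take very long to travel; migration hands it a good state and is
discarded with the burn-in. Chains are initialised from the prior.

Convergence is summarised by the multivariate potential scale reduction
factor in its large-sample form, `R = sqrt(1 + (m+1)/m * lambda_max(W^-1
B_n))`, with `W` the pooled within-chain covariance and `B_n` the
covariance of chain means. This form equals 1 exactly when chains are
indistinguishable and is always >= 1, which makes the convergence rule
(`R < 1.15`) monotone; it converges to the classic finite-sample statistic
as the chain length grows. Univariate factors per parameter use the same
form. Point estimates are posterior means pooled across post-burn-in
samples; means were chosen over modes because they are stable under MCMC
noise (kernel-free), at the cost of sensitivity to posterior skew (see
Limitations).

A fit requires at least 40 retained trials; blocks whose responses all fall
on one boundary are fitted but flagged, since accuracy then carries no
information about drift direction.

## Reliability

Odd-even split-half reliability splits trials by the parity of the original
presentation index, so trial exclusions cannot move a trial between halves,
refits each half, and computes ICC(2,1) — the two-way random-effects,
single-measure, absolute-agreement intraclass correlation — from the
standard two-way ANOVA decomposition. Half-fits may use a reduced iteration
budget (the pipeline halves it) since each half holds half the data.

## Descriptive layer

Pearson correlations with two-sided p-values (pairwise complete cases),
paired t-tests for condition contrasts, Cronbach's alpha with unbiased
variances, and a Fisher-z power analysis for a correlation: `power =
Phi(atanh(r) sqrt(n-3) - z_crit)`, two-sided at alpha = .05 by default,
ignoring the vanishing opposite-tail mass; the inverse solves for `r` by
bracketed root-finding. With n = 271 the smallest correlation detectable at
80% power is 0.17.

## Structural models

Models are declared as latents-with-indicators (first loading fixed to 1),
regressions, and free covariances, and estimated by minimising the ML
discrepancy `F = log|Sigma(theta)| + tr(S Sigma^-1) - log|S| - p` over a
RAM parameterisation, with L-BFGS-B from a deterministic start (loadings 1,
paths 0, residual variances at half the observed variances) and an analytic
gradient. Optimisation runs in a unit-variance metric — estimates are
mapped back afterwards — because the observed variables span four orders of
magnitude in variance (nondecision times vs questionnaire totals) and a
raw-metric quasi-Newton run can stall. If a warm start fails to converge,
the default start is tried before reporting failure.

`chi^2 = (n-1) F` (Wishart convention; users preferring `n F` can rescale),
`RMSEA = sqrt(max(chi^2 - df, 0) / (df (n-1)))`, and CFI uses the
independence baseline. Standard errors come from the inverse expected
information with `Sigma`-derivatives by central differences; the
standardized solution rescales by model-implied SDs. Indirect effects are
products of two path coefficients with delta-method standard errors
(including the parameter covariance); suppression is flagged when direct
and indirect effects are individually significant with opposite signs.

The two standard specifications are built in: the overt two-factor model
(capacity: MiniPONS, PENN ER-40, RMET, Hinting; bias: DACOBS AB, AIHQ BS;
both regressed on PSI and OSI with a PSI-OSI residual covariance; 8
observed variables, 16 df) and the extended model adding correlated
observed `t0` and `v` with paths to both latents and both outcomes (10
observed variables, 24 df). Exogenous diffusion variables get free
variances and covariance. Estimation is complete-case; no FIML.

## Synthetic-study generator

Participants receive latent capacity and bias scores from a bivariate
standard normal with correlation -0.32 (the magnitude such measures show).
Observed indicators are loading x latent + Gaussian residual with unit
total variance; default loadings are 0.55-0.75. Outcomes are built on a
standardized scale from structural paths — defaults SCB→PSI 0.56, SCB→OSI
0.31, SCC→OSI -0.26, SCC→PSI 0 — plus residuals with correlation 0.30, then
mapped linearly onto the questionnaire total scales. Diffusion parameters
are drawn around the population means with optional linear coupling to the
latents (the coupling coefficient is the correlation-scale weight) and a
cross-condition residual correlation (default 0.7, matching the
parameter-stability such tasks show across runs). Draws violating `a > 0.2`
or `t0 - st0/2 > 0.05` are redrawn up to 1000 times, then clipped, keeping
the likelihood well-defined. Trials are simulated from the exact-bridge
simulator; responses slower than 1.5 s are recorded as misses, which gives
the preprocessing stage realistic non-responses. Item-level matrices (20
UCLA-R-like, 6 SNS-like items) come from a one-factor model per
questionnaire with loadings set to reproduce alphas of 0.94 and 0.84.

What the generator does not emulate: sequential effects, practice and
fatigue drifts, contaminant (non-decision) responses, discretised Likert
items (items are continuous), and any attentional-cueing micro-mechanism
beyond condition-specific parameter shifts. Passing tests therefore show
that the pipeline recovers the structures it assumes, not that those
structures describe any particular human sample.

## Verification design and problem sizes

Every statistical operation is checked against an independent route:
the density against 10^6-trial simulations (20 random parameter regimes,
0.5-ms simulator steps, quantile-binned histograms compared bin by bin at 3
Monte-Carlo SEs — across the ~600 resulting bins, up to three chance
exceedances below 4.5 SE are tolerated, since the expected maximum of 600
null z-scores exceeds 3, while a genuine density defect at this trial count
produces deviations of tens of SEs); the sampler against an analytic
Gaussian target; ICC and alpha against pingouin; paired t and Pearson r
against scipy; the power analysis against a 100k-replicate Monte-Carlo
rejection rate; the SEM optimiser against a Nelder-Mead run from a
perturbed start (agreement to 1e-4 on F) and against the perfect-fit limit;
delta-method SEs against a 200-replicate bootstrap. Recovery studies use
2000 participants for the SEM layer, 30 participants x 160 trials for the
diffusion layer (reduced sampler budget of 1200 iterations), and 20
replicates of n = 500 for the qualitative dissociation pattern. The
credible-interval calibration check uses 400 trials per participant so that
the likelihood, not the bounded flat prior, dominates the posterior.

## Known limitations

- At 160 trials and ~98% accuracy the drift rate is weakly identified: the
  likelihood is nearly flat along a `v`-`a`-`sv` ridge, so posterior means
  of `v` are biased towards the interior of the prior ridge and
  person-level `v` recovery is noise-limited (correlation with truth ~0.65
  under the default generator; the maximum-likelihood estimator does no
  better, so this is an information limit of the design, not a sampler
  defect). Nondecision time is robust (person-level absolute error
  ~0.02-0.03 s). Designs wanting tight `v` estimates need more trials or a
  harder task with a real error rate.
- Each condition is fitted independently with all five parameters free;
  sharing `a`, `st0`, `sv` across conditions would halve their variance at
  the cost of a joint fit, and is not implemented.
- The SEM engine covers ML with complete cases; no robust/categorical
  estimators, no missing-data integration, no multigroup models.
- The MPSF uses the large-sample form (see above); at very short chains it
  is slightly more liberal than the finite-sample statistic (the omitted
  factor is `(n-1)/n`).
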