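# Methods

## Problem setting

National health surveys (NHANES-style) are drawn under stratified multi-stage
cluster designs with unequal inclusion probabilities. Bayesian kernel machine
regression (BKMR) — the workhorse semiparametric model for environmental
exposure mixtures — has no native support for survey weights, PSUs, or
replicate-weight variance estimation, so analysts routinely fit it unweighted.
`svybkmr` implements both a simulation laboratory for quantifying what that
omission costs, and the design-aware workflow that repairs most of it:
weight-proportional resampling that preserves primary sampling unit (PSU)
structure, followed by repeated model refits.

## Data-generating mechanism

A finite population of `n_pop = 20,000` units carries `m` exposures (3 or 10)
drawn from a mean-zero multivariate normal with exchangeable correlation
(unit diagonal, off-diagonal `rho`; positive definite iff
`-1/(m-1) < rho < 1`). The true exposure-response surface is

    h(z) = 1.0 z1 z2 + 0.5 z1^2 - 0.6 z2^2 + 0.30 z3 + 0.25 z3^2
           [+ 0.1 (z4 + ... + z10)  in the ten-exposure surface]

and outcomes are `y_i = h(z_i) + u_c(i) + eps_i` with `eps ~ N(0, sigma_eps2)`
(`sigma_eps2 = 1` by default) and a PSU-level random effect `u_c ~ N(0,
sigma_u2)` calibrated to a target intraclass correlation via
`sigma_u2 = icc/(1-icc) * sigma_eps2` (so ICC 0.15 gives 0.1765).

Units are partitioned into `C = 120` contiguous PSUs; when `n_pop` is not a
multiple of `C` the first `n_pop mod C` PSUs take one extra unit (at the
defaults: 80 PSUs of 167 and 40 of 166). PSU `c` belongs to stratum
`((c-1) mod H) + 1` with `H = 6`. Both rules are package choices — the survey
geometry needs *some* concrete PSU sizing and cyclic assignment, and nothing
downstream is sensitive to the remainder rule.

The estimand is the overall mixture effect
`delta* = h(q_0.75 1) - h(q_0.25 1)`, all exposures moved jointly between
their marginal quartiles. By default the truth uses exact standard-normal
quantiles (the exposures' marginals by construction, matching the
superpopulation target); an option recomputes it from a realized population's
empirical quantiles, which differs only by O(n_pop^{-1/2}). For the
three-exposure surface the even terms cancel at symmetric quartiles and
`delta* = 0.6 * 0.6745 = 0.4047`; the ten-exposure tails add
`7 * 0.1 * 2 * 0.6745` for `delta* = 1.349`.

A note on sensitivity: the *estimator* plugs in the analysis sample's
empirical quartiles. Because h has curvature and an interaction, the even
terms cancel only at exactly symmetric quantiles, so the quartile contrast is
noticeably sensitive to quantile noise. This is a property of the estimand
convention, not a defect; it is the channel through which informative
sampling (which shifts sample quantiles) biases the naive analysis.

## Survey design

First stage: `k_h = 4` PSUs per stratum by simple random sampling without
replacement. Second stage, two regimes:

* `srs` — within each selected PSU, `m_c` units by SRS without replacement;
* `pps` — informative selection with within-PSU probabilities proportional to
  `max(z1_i - min_c z1 + 1e-6, 0)`, normalized within the PSU, drawn without
  replacement by exponential keys (Efraimidis–Spirakis). Selection therefore
  depends on an exposure that drives the outcome.

Within-PSU takes allocate `n_total` over the 24 selected PSUs: base
`floor(n/24)` with the remainder spread one unit each over the first selected
PSUs in label order (300 -> twelve takes of 13 and twelve of 12).

Inclusion probabilities use the standard two-stage approximation
`pi_i = (k_h/C_h) * Pr(i|c)` with `Pr(i|c) = m_c/N_c` (SRS) or
`min(1, m_c p_ic)` (PPS). These are approximate for without-replacement PPS
draws — deliberately so; the weights inherit that approximation. Base weights
`1/pi` are rescaled to mean one within the sample (only relative weights
matter downstream, and rescaling protects kernel smoothing from extreme
magnitudes); no trimming. Monte-Carlo checks confirm the mechanism: over 200
informative draws the weighted mean of Z1 recovers the population mean to
within Monte-Carlo error while the unweighted mean is biased upward by ~0.36.

## Kernel machine model and sampler

Marginalizing the Gaussian process h gives the working likelihood
`Y ~ N(X beta, sigma2 (I + lam K_r))` with the component-scaled RBF kernel
`K_r(z,z') = exp(-sum_m r_m (z_m - z'_m)^2)` and `lam = tau/sigma2` the
signal-to-noise variance ratio. Variable selection ties each `r_m` to a
Bernoulli(0.5) inclusion indicator `delta_m`; `r_m = 0` removes exposure `m`
from the kernel entirely. Exposures are centered and scaled internally.

Priors (package defaults — the standard BKMR formulation leaves these
choices open — all exposed on `BKMRConfig`):

| parameter | prior | proposal |
|---|---|---|
| beta | flat | conjugate Gibbs |
| sigma2 | inverse-gamma(0.001, 0.001) | conjugate Gibbs |
| lam | gamma(shape 1, rate 0.1) | log-random walk, step 0.5 |
| r_m (slab) | uniform(0, 100) | birth from U(0,10); log-RW step 0.3 |
| delta_m | Bernoulli(0.5) | 50/50 toggle-vs-walk mixed move |

Each iteration updates one randomly chosen `r_m` (a reversible birth/death
toggle or an in-model log random walk), then `lam`, then `beta` and `sigma2`
by Gibbs — two SPD factorizations per iteration, with the weighted
squared-distance matrix cached and updated componentwise. A `1e-8` diagonal
jitter guarantees factorizability, including for the duplicated rows that
bootstrap resampling produces. Chain schedules: 4000/2000/2
(iterations/burn-in/thinning, 1000 retained draws) for main fits, 2500/1000/2
for bootstrap refits.

Surface queries draw `h(z_new)` per retained draw from the exact Gaussian
conditional (mean `lam K* V^{-1}(y - X beta)`, covariance
`sigma2 lam (K** - lam K* V^{-1} K*')`); a mean-only mode skips the
covariance when only posterior means are needed (replicate summaries).
Both match dense-linear-algebra oracles to 1e-8 in the tests.

Diagnostics: per-move acceptance rates and a split-chain potential scale
reduction factor. The R-hat variant used is `sqrt((W + B/n)/W)`, which is
exactly 1 for identical chains and always >= 1; it agrees with the common
`(n-1)/n`-shrunk variant to O(1/n) (cross-checked against arviz).

## Design-aware workflow

Per bootstrap replicate: within each stratum, draw as many PSUs as the sample
has there, with replacement, with probability proportional to the PSU's total
weight (`sum_weights`, the default; `mean_weights` is available — the two
rules coincide here up to take sizes, and both appear in the survey
literature). Within each drawn PSU, resample units with replacement with
probability proportional to `w`. Draw slots inherit the original PSUs' takes
in label order, so every replicate has exactly the original size and
per-stratum PSU counts; a PSU drawn twice contributes two independent unit
resamples under distinct cluster labels. The model is refit on each of
`B = 50` replicates (shorter chains); scalar summaries are aggregated by
empirical means with 2.5/97.5 percentile (linear interpolation)
replication-based intervals, functional summaries pointwise. Replicate
failures are skipped with a warning; a run aborts below 80% success.

Seed streams: a master `SeedSequence` spawns one child per replicate (and
separate streams for the resample and the chain), so results are independent
of execution order and worker count.

The intervals this workflow produces are *replication-based*, not posterior
credible intervals: they quantify repeated-sampling variability of the
posterior-mean summary under design-preserving resampling. Every summary
carries an `interval_kind` label so the two are never conflated.

## Summaries

All summaries are quantile-based functionals of h, shared between an oracle
mode (the true surface plugged in directly — exact tests of the plumbing) and
fit mode: the overall effect `delta`, the overall effect curve over joint
quantiles 0.25–0.75 in steps of 0.05 centered at the median (identically zero
at q = 0.50 by construction), univariate and bivariate sections (25-point
grids, non-focal exposures at medians, bivariate conditioning at the
25th/50th/75th percentiles), and per-exposure quartile contrasts with the
other exposures fixed at a chosen background quantile (that same quantile for
*all* non-focal exposures). Quantile-defined query points come from the
analysis dataset presented to the model — for design-aware replicates, the
resampled dataset, which already embodies the weighting; z-space grids are
fixed from the original sample so naive and design-aware curves share grids
and centering.

## Monte-Carlo evaluation

Each scenario crosses `n in {300, 800, 1200}`, `rho in {0, 0.8}`,
`ICC in {0, 0.15}`, and regime (`srs`/`pps`); `R = 100` replicates by
default. Per replicate a fresh population is generated, one sample drawn, and
both workflows applied to that identical sample. Metrics over replicates:
bias (mean estimate minus `delta*`), mean 95% interval width, empirical
coverage (closed interval), and RMSE; `rmse^2 = bias^2 + variance` holds by
construction and is asserted in tests. Naive intervals are equal-tailed
posterior credible intervals.

A fast surrogate (`estimator="linear"`) replaces the kernel-machine fit with
OLS on the true polynomial basis. Its interval is a 200-draw unit-level
percentile bootstrap: a coefficient-only delta-method CI ignores sample-
quantile noise in the quartile contrast and under-covers (~59%) even under
SRS, whereas the bootstrap restores nominal calibration (95% measured at
n=800) while still failing honestly under informative sampling (0% coverage,
bias +0.86) — bootstrap cannot remove selection bias. The surrogate exercises
the full population/sampling/resampling/metrics pipeline at ~1000x less cost
and is used for harness calibration checks; it is not a substitute for the
kernel-machine results.

## Problem sizes used in the shipped tests and acceptance script

Full-paper settings (R=100, B=50, 4000/2000/2 chains) are the library
defaults. The shipped test suite and `scripts/acceptance.py` run the
kernel-machine scenarios at reduced sizes chosen for single-CPU turnaround:
the informative-sampling cell at R=30 (naive arm, 2000/1000/2 chains), the
paired naive/design-aware comparison at R=10, B=10 (replicate chains
1500/750/2; acceptance script: R=8, B=8), PIP checks at n=300 with B=10, and
surrogate-based calibration at R=100. Measured behaviour at these sizes:
naive coverage 0% with bias ~+0.9 under the hardest informative cell;
design-aware coverage ~90% with bias ~-0.2 and roughly 2.7x wider intervals.
The qualitative ordering (naive collapses under informative sampling; the
design-aware workflow restores most coverage at the cost of width, slightly
overcorrecting the point estimate) is stable across the sizes tried.

## Known limitations

* The design-aware intervals remain approximations; they can overcover in
  strong-signal, small-B settings (percentiles of 8-10 replicate means are
  noisy) and the workflow is not a pseudo-posterior — no weighted likelihood
  is defined.
* Inclusion probabilities under PPS are the standard two-stage approximation,
  not exact without-replacement probabilities.
* The generator emulates exchangeable Gaussian exposures, a polynomial
  surface, and intercept-only adjustment. Real biomonitoring data are skewed,
  heteroscedastic, and covariate-confounded; passing tests demonstrate
  correctness of the machinery and the direction/magnitude of design effects
  under these conditions, not performance on real survey data.
* Nonresponse, calibration/raking, weight trimming, replicate-weight files
  (BRR/jackknife), and multiple-imputation combination are out of scope.
* MCMC convergence is monitored only via acceptance rates and split R-hat on
  demand; replicate chains are short by design.
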