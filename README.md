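# svybkmr

Bayesian kernel machine regression (BKMR) under complex survey designs:
a simulation laboratory and a practical design-aware analysis workflow.

## The problem

Population health surveys (NHANES and kin) are drawn with stratification,
multi-stage clustering through primary sampling units (PSUs), and unequal
inclusion probabilities. BKMR — the standard semiparametric model for
nonlinear, interacting exposure mixtures — has no native support for survey
weights or clustering, so it is routinely fit unweighted. When inclusion
probabilities depend on exposures that drive the outcome (informative
sampling), the unweighted fit learns the wrong empirical distribution:
point estimates are biased and nominal 95% intervals can cover the truth
almost never.

`svybkmr` provides, for biostatisticians and environmental epidemiologists:

* a finite-population simulator with a known nonlinear exposure-response
  surface `h(z) = z1 z2 + 0.5 z1² − 0.6 z2² + 0.3 z3 + 0.25 z3²` (plus small
  linear tails in the 10-exposure variant), exchangeable exposure correlation
  ρ, and ICC-calibrated PSU random effects;
* a stratified two-stage sampler with non-informative (SRS) and informative
  (PPS-like, probability ∝ shifted Z1) within-PSU selection, approximate
  inclusion probabilities π ≈ (k_h/C_h)·Pr(i|c), and mean-one rescaled
  weights w = 1/π;
* a from-scratch BKMR core: Gaussian-process MCMC with a component-scaled
  RBF kernel and spike-and-slab variable selection (PIPs, group PIPs,
  conditional PIPs, split-R̂ diagnostics);
* the **design-aware workflow**: stratum-wise PSU resampling with
  replacement ∝ PSU weight totals, within-PSU unit resampling ∝ w, B
  model refits, and replication-based (percentile) uncertainty intervals;
* a Monte-Carlo harness measuring bias, interval width, empirical 95%
  coverage, and RMSE of the overall mixture effect
  Δ\* = h(q₀.₇₅·1) − h(q₀.₂₅·1) against the known truth
  (Δ\* = 0.4047 for three exposures).

## Worked example

```python
import numpy as np
from svybkmr import (BKMRConfig, PopulationConfig, SamplingDesign,
                     ResamplePlan, FitEvaluator, draw_sample,
                     generate_population, mcmc_fit, compute_pips,
                     estimate_delta, estimate_delta_replicates,
                     make_replicate_summarizer, run_design_aware,
                     true_overall_effect, h_spec_for, EstimandSpec)

# informative sampling: inclusion depends on Z1, which drives the outcome
pop = generate_population(PopulationConfig(n_pop=20_000, m=3, rho=0.8,
                                           icc=0.15, seed=1))
sample = draw_sample(pop, SamplingDesign(n_total=300, regime="pps", seed=2))
truth = true_overall_effect(h_spec_for(3), EstimandSpec())

y, z = sample.data["y"].to_numpy(), sample.z_matrix()
draws = mcmc_fit(y, z, config=BKMRConfig(iters=2000, burnin=1000, thin=2,
                                         seed=3))
naive = estimate_delta(FitEvaluator(draws, y, z, seed=4), z)

plan = ResamplePlan(b=20, replicate_config=BKMRConfig(iters=1500, burnin=750,
                                                      thin=2), seed=5)
reps = run_design_aware(sample, plan,
                        summarize=make_replicate_summarizer(("delta",)))
aware = estimate_delta_replicates(reps)

print(f"truth          {truth:.3f}")
print(f"naive          {naive.point:.3f}  [{naive.lo:.3f}, {naive.hi:.3f}]"
      f"  ({naive.interval_kind})")
print(f"design-aware   {aware.point:.3f}  [{aware.lo:.3f}, {aware.hi:.3f}]"
      f"  ({aware.interval_kind})")
print("PIPs:", np.round(compute_pips(draws), 2))
```

Output:

```
truth          0.405
naive          1.668  [1.278, 2.046]  (posterior-credible)
design-aware   0.553  [-0.578, 2.469]  (replication-based)
PIPs: [1.   0.06 1.  ]
```

The naive credible interval sits far above the truth and excludes it — the
informative design has shifted the sample's exposure distribution upward and
the unweighted fit inherits that bias. The design-aware estimate re-centers
near the truth with an honest, wider replication-based interval that covers
it. Note the PIP for Z2: with ρ = 0.8 the highly correlated Z1 absorbs most
of Z2's contribution to the kernel, so its inclusion probability is
attenuated — exactly the competition effect that makes PIPs an inclusion
diagnostic rather than an importance measure (at ρ = 0, all three PIPs
saturate at 1).

A command-line interface mirrors the library
(`svybkmr simulate | sample | fit | evaluate | plot`); every output is paired
with a config echo and manifest for bit-for-bit reproducibility.

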