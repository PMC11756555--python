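"""Fit the five-parameter diffusion model to one simulated participant.

Simulates 160 trials at the population-mean parameters of the baseline
(neutral-neutral) condition, samples the posterior with the DE-MCMC sampler,
checks convergence with the multivariate potential scale reduction factor
(criterion: MPSF < 1.15) and prints posterior-mean estimates next to the
generating values.
"""

from driftsem import (DDMParams, SamplerConfig, compute_mpsf,
                      point_estimates, run_demc, simulate_trials)

truth = DDMParams(v=4.098, a=1.2, t0=0.347, st0=0.15, sv=1.0)
rt, correct = simulate_trials(truth, 160, seed=7)
print(f"simulated 160 trials: accuracy {correct.mean():.3f}, "
      f"median RT {sorted(rt)[80]:.3f} s")

chains = run_demc((rt, correct), SamplerConfig(seed=1))
report = compute_mpsf(chains)
print(f"MPSF = {report.mpsf:.3f} (converged: {report.converged})")

est, warnings = point_estimates(chains)
for name in ("v", "a", "t0", "st0", "sv"):
    print(f"  {name:>3}: estimate {getattr(est, name):6.3f}   "
          f"true {getattr(truth, name):6.3f}")
# At 160 trials and ~98% accuracy the drift rate is only weakly identified
# (the likelihood is nearly flat along a v-a-sv ridge), so v and sv carry
# wide posteriors; t0 is pinned tightly by the leading edge of the RT
# distribution.
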