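"""Determine the replication sample size for a set of identified SNPs.

All SNPs passing the primary threshold are carried into the design,
weighted by their local true discovery rate (the posterior probability
of a genuine association), and the smallest replication size whose
ltdr-weighted average EB predictive power reaches 80% is found by
bisection.
"""

import numpy as np

from replipower import (
    AlleleCountTable,
    SimulationConfig,
    fit_prior_arrays,
    is_primary_significant,
    required_sample_size,
    simulate_two_stage,
    wald_summary,
)

config = SimulationConfig(m=10_000)
data = simulate_two_stage(config, rng_seed=42)
mu_hat, sigma, z = data.primary_stats()
prior = fit_prior_arrays(z, sigma)

keep = [i for i in range(config.m) if is_primary_significant(z[i], config.alpha1)]
tables = [AlleleCountTable(*data.primary[i]) for i in keep]
summaries = [wald_summary(t, f"snp{i}") for i, t in zip(keep, tables)]
print(f"{len(keep)} SNPs identified at alpha1 = {config.alpha1}")

res = required_sample_size(
    tables, summaries, prior, target_power=0.80, ratio=1.0, alpha2=config.alpha2
)
print(f"required replication size: {res.n_cases} cases + {res.n_controls} controls")
print(f"achieved average power: {res.achieved_power:.4f} (target 0.80)")
print("power curve (total size -> average power):")
for total, power in res.curve[:: max(1, len(res.curve) // 8)]:
    print(f"  {total:7d}  {power:.3f}")
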