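"""Fit the two-component effect-size prior from genome-wide summaries.

Simulates a primary case-control study whose log-OR effects follow
0.9*delta_0 + 0.1*N(0, 0.04) and recovers the hyperparameters from the
Wald statistics alone: pi0 by Storey's spline-smoothed p-value census,
sigma0^2 by the moment estimator on the marginal z distribution.
"""

from replipower import SimulationConfig, fit_prior_arrays, simulate_two_stage

config = SimulationConfig(m=10_000)  # 1000/1000 primary, MAF U(0.05,0.5), prevalence 1%
data = simulate_two_stage(config, rng_seed=42)
mu_hat, sigma, z = data.primary_stats()

prior = fit_prior_arrays(z, sigma)
print(f"estimated pi0       = {prior.pi0:.3f}   (true 0.900: fraction of null SNPs)")
print(f"estimated sigma0^2  = {prior.sigma0_sq:.4f}  (true 0.0400: effect-size variance)")
print(f"shrinkage at SE=0.09: lambda = {1/(1+(0.09**2/prior.sigma0_sq)):.3f}")
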