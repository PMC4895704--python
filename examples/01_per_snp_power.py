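"""Estimate one identified SNP's replication power four ways.

A SNP with an exaggerated-looking primary effect is pushed through the
naive plug-in, the conditional-MLE plug-in, the Empirical-Bayes
effect-size plug-in and the closed-form EB predictive power.  The
spread between the naive and the EB predictive value is the winner's
curse at work: conditioning on primary significance inflates the
observed effect, so power computed from it is optimistic.
"""

from replipower import (
    AlleleCountTable,
    MixturePrior,
    cmle_effect,
    eb_effect,
    eb_predictive_power,
    plugin_power,
    replication_se,
    wald_summary,
)

ALPHA1, ALPHA2 = 5e-5, 5e-3

# primary study: 1000 cases / 1000 controls, effect allele enriched in cases
table = AlleleCountTable(n00=1400, n01=600, n10=1260, n11=740)
summary = wald_summary(table, "rs0001")
print(f"primary log-OR = {summary.mu_hat:.4f}, SE = {summary.sigma:.4f}, z = {summary.z:.2f}")

# replication design: 500 / 500; SE projected from primary allele frequencies
sigma2 = replication_se(table, n0_rep=500, n1_rep=500)
print(f"projected replication SE = {sigma2:.4f}")

# genome-wide prior (here given; normally fitted with fit_prior)
prior = MixturePrior(pi0=0.9, sigma0_sq=0.04)
sign = 1 if summary.z > 0 else -1

naive = plugin_power(summary.mu_hat, sign, sigma2, ALPHA2)
cmle = plugin_power(cmle_effect(summary, ALPHA1), sign, sigma2, ALPHA2)
eb_plug = plugin_power(eb_effect(summary, prior), sign, sigma2, ALPHA2)
eb_pred = eb_predictive_power(summary, prior, sigma2, ALPHA2)

print(f"naive plug-in power        = {naive:.3f}   (winner's-curse inflated)")
print(f"CMLE plug-in power         = {cmle:.3f}   (selection-corrected effect)")
print(f"EB plug-in power           = {eb_plug:.3f}   (shrunken effect)")
print(f"EB predictive power        = {eb_pred:.3f}   (posterior-averaged; design value)")
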