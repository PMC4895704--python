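"""Per-SNP estimators of replication-study power.

Four estimators are compared throughout the package:

* naive plug-in: the observed primary log-OR plugged into the power
  function — upward biased among selected SNPs (winner's curse);
* CMLE plug-in: the conditional MLE of the effect given selection,
  plugged in — overcorrects downward;
* EB plug-in: the posterior-mean (shrunken) effect plugged in;
* EB predictive power: the posterior expectation of the power function
  itself, which is the Bayes-risk-optimal estimator under squared error
  conditional on selection.

The posterior of the effect size under the Gaussian non-null component
is N(lambda * mu_hat, lambda * sigma1^2) with shrinkage factor
lambda = 1 / (1 + (sigma1 / sigma0)^2), which makes the predictive
power available in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .assoc_core import AssociationSummary, replication_power
from .prior_estimation import MixturePrior

__all__ = [
    "PosteriorEffect",
    "shrinkage_lambda",
    "posterior_effect",
    "eb_predictive_power",
    "eb_predictive_power_arrays",
    "cmle_effect",
    "cmle_effect_z",
    "eb_effect",
    "plugin_power",
]


@dataclass(frozen=True)
class PosteriorEffect:
    """Posterior N(mean, variance) of the log-OR under the non-null component."""

    mean: float
    variance: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


def shrinkage_lambda(sigma1, sigma0: float):
    """Shrinkage factor lambda = 1 / (1 + (sigma1 / sigma0)^2).

    0 when the prior is a point mass (sigma0 = 0), 1 when the prior is
    flat (sigma0 = inf); accepts scalar or array sigma1.
    """
    sigma1 = np.asarray(sigma1, dtype=float)
    if np.any(sigma1 <= 0):
        raise ValueError("sigma1 must be positive")
    if sigma0 < 0:
        raise ValueError("sigma0 must be >= 0")
    if math.isinf(sigma0):
        out = np.ones_like(sigma1)
    elif sigma0 == 0.0:
        out = np.zeros_like(sigma1)
    else:
        out = 1.0 / (1.0 + (sigma1 / sigma0) ** 2)
    return float(out) if out.ndim == 0 else out


def posterior_effect(summary: AssociationSummary, prior: MixturePrior) -> PosteriorEffect:
    """Conjugate-normal posterior of the effect size given z, under H1."""
    lam = shrinkage_lambda(summary.sigma, prior.sigma0)
    return PosteriorEffect(mean=lam * summary.mu_hat, variance=lam * summary.sigma**2, lam=lam)


def eb_predictive_power_arrays(mu_hat, sigma1, lam, sigma2, alpha2):
    """Closed-form Bayesian predictive power, vectorised over SNPs.

    Phi((sgn(z) z* - z_alpha2) / sigma*) with z* = lambda mu_hat / sigma2
    and sigma* = sqrt(1 + lambda (sigma1 / sigma2)^2).
    """
    mu_hat = np.asarray(mu_hat, dtype=float)
    sigma1 = np.asarray(sigma1, dtype=float)
    lam = np.asarray(lam, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(mu_hat == 0):
        raise ValueError("primary z is zero: sign of the replication test undefined")
    z_star = lam * np.abs(mu_hat) / sigma2  # sgn(z) z* = lambda |mu_hat| / sigma2
    sigma_star = np.sqrt(1.0 + lam * (sigma1 / sigma2) ** 2)
    out = stats.norm.cdf((z_star - stats.norm.isf(alpha2)) / sigma_star)
    return float(out) if out.ndim == 0 else out


def eb_predictive_power(
    summary: AssociationSummary, prior: MixturePrior, sigma2: float, alpha2: float
) -> float:
    """Posterior expectation of the replication power function (closed form).

    Integrates the one-sided power function over the posterior
    N(lambda mu_hat, lambda sigma1^2) of the effect size.  With a
    point-mass prior (sigma0 = 0) this degenerates to alpha2; with the
    infinite-variance sentinel, lambda = 1 exactly.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    lam = shrinkage_lambda(summary.sigma, prior.sigma0)
    return eb_predictive_power_arrays(summary.mu_hat, summary.sigma, lam, sigma2, alpha2)


def _cmle_negloglik(t: np.ndarray, z: float, c: float) -> np.ndarray:
    """Negative conditional log-likelihood on the standardised scale t = mu/sigma."""
    # log P(select | t) = log(Phi(t - c) + Phi(-t - c)), computed stably in logs
    log_sel = np.logaddexp(stats.norm.logcdf(t - c), stats.norm.logcdf(-t - c))
    return -(stats.norm.logpdf(z - t) - log_sel)


def cmle_effect_z(z: float, alpha1: float) -> float:
    """Conditional MLE of the standardised effect t = mu/sigma given selection.

    Maximises phi(z - t) / [Phi(t - c) + Phi(-t - c)] with c =
    z_{alpha1/2}: the likelihood of z conditioned on |Z| > c under the
    two-sided primary test.  The objective can be nearly flat around 0
    for z just past the threshold, so a coarse grid over [-2|z|, 2|z|]
    augmented with the restart points {0, z/2, z} locates the basin and
    a bounded Brent search refines it; near-ties resolve toward the
    sign of z.
    """
    c = float(stats.norm.isf(alpha1 / 2.0))
    if abs(z) <= c:
        raise ValueError(f"z = {z} did not pass the primary threshold {c:.4f}")
    lo, hi = -2.0 * abs(z), 2.0 * abs(z)
    step = (hi - lo) / 800.0
    grid = np.unique(np.concatenate([np.linspace(lo, hi, 801), [0.0, z / 2.0, z]]))
    vals = _cmle_negloglik(grid, z, c)
    best = float(grid[int(np.argmin(vals))])
    # bracket a full coarse step on both sides of the best point so the basin
    # minimum cannot fall outside (inserted restart points may nearly
    # duplicate grid nodes)
    a = max(lo, best - step)
    b = min(hi, best + step)
    res = optimize.minimize_scalar(
        lambda t: float(_cmle_negloglik(np.asarray(t), z, c)),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"CMLE optimisation failed for z={z}, alpha1={alpha1}: {res.message}")
    t_hat = float(res.x)
    # flat-ridge tie near 0: keep the solution on the side of the data
    if t_hat != 0.0 and np.sign(t_hat) != np.sign(z):
        t_mirror = -t_hat
        if float(_cmle_negloglik(np.asarray(t_mirror), z, c)) <= float(
            _cmle_negloglik(np.asarray(t_hat), z, c)
        ) + 1e-12:
            t_hat = t_mirror
    # selection shrinks: the conditional MLE magnitude never exceeds |z|
    if abs(t_hat) > abs(z):
        t_hat = math.copysign(abs(z), t_hat)
    return t_hat


def cmle_effect(summary: AssociationSummary, alpha1: float) -> float:
    """Conditional MLE of the log-OR, correcting the selection (winner's curse) bias."""
    return cmle_effect_z(summary.z, alpha1) * summary.sigma


def eb_effect(summary: AssociationSummary, prior: MixturePrior) -> float:
    """Empirical-Bayes effect-size estimate: the posterior mean lambda * mu_hat."""
    return shrinkage_lambda(summary.sigma, prior.sigma0) * summary.mu_hat


def plugin_power(mu_estimate, sign1, sigma2, alpha2):
    """Plug an effect-size estimate into the replication power function.

    Used with the observed effect (naive), the CMLE-corrected effect and
    the EB posterior-mean effect.
    """
    return replication_power(mu_estimate, sign1, sigma2, alpha2)
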