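"""Credible intervals for per-SNP and average replication power.

The power function is nonlinear and bounded in [0, 1], so the
distribution of power induced by a Gaussian posterior on the effect
size is skewed; normal-theory intervals are inappropriate.  Intervals
are therefore built by Monte-Carlo sampling from the effect-size
posterior.  Because the prior hyperparameters (pi0, sigma0_sq) are
themselves estimated with error, a pure Monte-Carlo interval
under-covers; combining it with a nonparametric bootstrap over the
genome-wide primary statistics — re-estimating the hyperparameters in
each resample and pooling all N1 x N2 power draws — restores coverage
close to the nominal level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .assoc_core import AssociationSummary
from .power_estimators import eb_predictive_power_arrays, shrinkage_lambda
from .prior_estimation import MixturePrior, fit_prior_arrays
from .study_design import average_power_eb, ltdr_arrays

__all__ = [
    "IntervalEstimate",
    "power_posterior_samples",
    "credible_interval_power",
    "credible_interval_average_power",
    "bootstrap_priors",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with equal-tailed credible bounds.

    ``n_samples`` is the pooled number of Monte-Carlo draws: N2 for the
    pure Monte-Carlo interval, N1 x N2 for the bootstrap-combined one.
    """

    point: float
    lower: float
    upper: float
    level: float
    n_samples: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError(f"invalid interval [{self.lower}, {self.upper}]")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("level must lie in [0, 1]")


def _power_draws(rng, mu_hat, sigma1, lam, sign1, sigma2, alpha2, size) -> np.ndarray:
    """Draw effects from N(lam*mu_hat, lam*sigma1^2), map through the power function."""
    mu = rng.normal(lam * mu_hat, np.sqrt(lam) * sigma1, size=size)
    return stats.norm.cdf(sign1 * mu / sigma2 - stats.norm.isf(alpha2))


def power_posterior_samples(
    summary: AssociationSummary,
    prior: MixturePrior,
    sigma2: float,
    alpha2: float,
    n_draws: int,
    rng_seed,
) -> np.ndarray:
    """Monte-Carlo draws of the replication power under the effect posterior.

    The sample mean converges to the closed-form predictive power; with
    a point-mass prior every draw equals alpha2.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if summary.z == 0:
        raise ValueError("sign of the replication test undefined for z = 0")
    rng = np.random.default_rng(rng_seed)
    lam = shrinkage_lambda(summary.sigma, prior.sigma0)
    return _power_draws(
        rng, summary.mu_hat, summary.sigma, lam, np.sign(summary.z), sigma2, alpha2, n_draws
    )


def _equal_tailed(draws: np.ndarray, level: float) -> tuple[float, float]:
    lo, hi = np.quantile(draws, [(1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0])
    return float(lo), float(hi)


def bootstrap_priors(
    z, sigma, n_boot: int, rng: np.random.Generator
) -> list[MixturePrior]:
    """Re-fit the mixture prior on ``n_boot`` with-replacement resamples of (z, sigma)."""
    z = np.asarray(z, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    m = z.size
    priors = []
    for _ in range(n_boot):
        idx = rng.integers(0, m, size=m)
        priors.append(fit_prior_arrays(z[idx], sigma[idx]))
    return priors


def credible_interval_power(
    summary: AssociationSummary,
    all_summaries: Sequence[AssociationSummary] | tuple[np.ndarray, np.ndarray] | None,
    sigma2: float,
    alpha2: float,
    level: float = 0.95,
    n1: int = 100,
    n2: int = 100,
    use_bootstrap: bool = True,
    rng_seed=None,
    *,
    prior: MixturePrior | None = None,
    boot_priors: Sequence[MixturePrior] | None = None,
) -> IntervalEstimate:
    """Equal-tailed credible interval for one SNP's replication power.

    Without bootstrap: ``n2`` posterior draws under the prior fitted to
    the full summary set.  With bootstrap: ``n1`` study-level resamples
    of the genome-wide (z, sigma) pairs, prior re-fitted per resample
    (both pi0 and sigma0_sq), ``n2`` draws per resample, all n1 x n2
    values pooled.  The point estimate is the closed-form predictive
    power under the original prior.  Precomputed ``boot_priors`` may be
    supplied to share one set of resamples across many SNPs.
    """
    rng = np.random.default_rng(rng_seed)
    if all_summaries is None:
        z_all = sg_all = None
    elif isinstance(all_summaries, tuple):
        z_all, sg_all = (np.asarray(a, dtype=float) for a in all_summaries)
    else:
        z_all = np.array([s.z for s in all_summaries])
        sg_all = np.array([s.sigma for s in all_summaries])
    if prior is None:
        if z_all is None:
            raise ValueError("either a fitted prior or the full summary set is required")
        prior = fit_prior_arrays(z_all, sg_all)
    point = float(
        eb_predictive_power_arrays(
            summary.mu_hat,
            summary.sigma,
            shrinkage_lambda(summary.sigma, prior.sigma0),
            sigma2,
            alpha2,
        )
    )
    sign1 = np.sign(summary.z)
    if not use_bootstrap:
        lam = shrinkage_lambda(summary.sigma, prior.sigma0)
        draws = _power_draws(rng, summary.mu_hat, summary.sigma, lam, sign1, sigma2, alpha2, n2)
    else:
        if boot_priors is None:
            if z_all is None:
                raise ValueError("bootstrap requires the full summary set")
            boot_priors = bootstrap_priors(z_all, sg_all, n1, rng)
        chunks = []
        for bp in boot_priors:
            lam = shrinkage_lambda(summary.sigma, bp.sigma0)
            chunks.append(
                _power_draws(rng, summary.mu_hat, summary.sigma, lam, sign1, sigma2, alpha2, n2)
            )
        draws = np.concatenate(chunks)
    lo, hi = _equal_tailed(draws, level)
    return IntervalEstimate(point=point, lower=lo, upper=hi, level=level, n_samples=draws.size)


def credible_interval_average_power(
    summaries: Sequence[AssociationSummary],
    all_summaries: Sequence[AssociationSummary] | tuple[np.ndarray, np.ndarray],
    sigma2s,
    alpha2: float,
    level: float = 0.95,
    n1: int = 100,
    n2: int = 100,
    rng_seed=None,
    *,
    prior: MixturePrior | None = None,
    unnormalized_ltdr: bool = False,
) -> IntervalEstimate:
    """Credible interval for the ltdr-weighted average replication power.

    Per bootstrap resample of the genome-wide statistics: re-fit the
    prior, recompute the ltdr weights of the identified SNPs, draw
    ``n2`` coherent sets of per-SNP powers (one posterior effect draw
    per SNP per set) and form the weighted average of each set; pool
    the n1 x n2 averages.  The point estimate is the closed-form
    weighted average under the original prior.
    """
    if len(summaries) == 0:
        raise ValueError("identified set is empty")
    rng = np.random.default_rng(rng_seed)
    if isinstance(all_summaries, tuple):
        z_all, sg_all = (np.asarray(a, dtype=float) for a in all_summaries)
    else:
        z_all = np.array([s.z for s in all_summaries])
        sg_all = np.array([s.sigma for s in all_summaries])
    if prior is None:
        prior = fit_prior_arrays(z_all, sg_all)
    mu = np.array([s.mu_hat for s in summaries])
    sg = np.array([s.sigma for s in summaries])
    signs = np.sign(mu)
    sigma2s = np.broadcast_to(np.asarray(sigma2s, dtype=float), mu.shape)
    point = average_power_eb(summaries, prior, sigma2s, alpha2, unnormalized_ltdr=unnormalized_ltdr)

    z_a2 = stats.norm.isf(alpha2)
    pooled = np.empty((n1, n2))
    for b, bp in enumerate(bootstrap_priors(z_all, sg_all, n1, rng)):
        w = ltdr_arrays(mu / sg, sg, bp, unnormalized=unnormalized_ltdr)
        wsum = float(np.sum(w))
        if wsum == 0.0:
            logger.warning("bootstrap resample %d: all ltdr weights zero; resample retained", b)
            pooled[b] = np.nan
            continue
        lam = shrinkage_lambda(sg, bp.sigma0)
        # n2 coherent sets: one effect draw per SNP per set
        mu_draws = rng.normal(lam * mu, np.sqrt(lam) * sg, size=(n2, mu.size))
        powers = stats.norm.cdf(signs * mu_draws / sigma2s - z_a2)
        pooled[b] = powers @ w / wsum
    draws = pooled[np.isfinite(pooled)].ravel()
    if draws.size == 0:
        raise ValueError("no usable bootstrap draws (all resamples degenerate)")
    lo, hi = _equal_tailed(draws, level)
    return IntervalEstimate(point=point, lower=lo, upper=hi, level=level, n_samples=draws.size)
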