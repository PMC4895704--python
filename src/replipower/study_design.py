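"""Average replication power and sample-size determination.

A replication study is sized against a single summary number: the
average power over the SNPs identified in the primary study.  Because
the identified set contains false positives, each SNP's estimated power
is weighted by its local true discovery rate (ltdr) — the posterior
probability of a genuine association given its primary statistic —
which discounts likely false positives.  Setting the weighted average
power above a threshold (conventionally 80 %) determines the
replication sample size via the monotone dependence of power on the
replication group sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .assoc_core import AlleleCountTable, AssociationSummary, replication_power
from .power_estimators import eb_predictive_power_arrays, shrinkage_lambda
from .prior_estimation import MixturePrior

__all__ = [
    "DesignResult",
    "ltdr",
    "ltdr_arrays",
    "average_power_eb",
    "true_average_power",
    "required_sample_size",
    "TargetPowerUnreachable",
]


@dataclass(frozen=True)
class DesignResult:
    """Outcome of the replication sample-size search.

    ``n_cases`` is the smallest number of replication cases (controls =
    ratio x cases) whose ltdr-weighted average power reaches the
    target; ``curve`` holds (total replication size, average power)
    pairs for reporting.
    """

    n_cases: int
    n_controls: int
    target_power: float
    achieved_power: float
    curve: list[tuple[int, float]] = field(default_factory=list)


class TargetPowerUnreachable(RuntimeError):
    """Raised when the target average power cannot be reached below n_max."""

    def __init__(self, target: float, n_max: int, power_at_max: float):
        self.target = target
        self.n_max = n_max
        self.power_at_max = power_at_max
        super().__init__(
            f"target average power {target:.3f} unreachable: power at n_max={n_max} "
            f"cases is {power_at_max:.4f}"
        )


def ltdr_arrays(z, sigma1, prior: MixturePrior, *, unnormalized: bool = False) -> np.ndarray:
    """Local true discovery rate for parallel (z, sigma1) arrays.

    Posterior probability of H1 given z under the marginal mixture
    Z ~ pi0 N(0,1) + pi1 N(0, s^2), s^2 = 1 + (sigma0/sigma1)^2,
    computed in log space.  By default the non-null component density is
    properly normalised (phi(z/s)/s); ``unnormalized=True`` reproduces
    the variant without the 1/s factor for comparison with software that
    uses it.
    """
    z = np.asarray(z, dtype=float)
    sigma1 = np.asarray(sigma1, dtype=float)
    if prior.pi0 == 1.0:
        return np.zeros(np.broadcast(z, sigma1).shape)
    if prior.pi0 == 0.0:
        return np.ones(np.broadcast(z, sigma1).shape)
    if math.isinf(prior.sigma0_sq):
        # lambda = 1 limit: the non-null marginal is infinitely dispersed and
        # its density vanishes pointwise
        return np.zeros(np.broadcast(z, sigma1).shape)
    s = np.sqrt(1.0 + (prior.sigma0 / sigma1) ** 2)
    log_alt = math.log(prior.pi1) + stats.norm.logpdf(z / s)
    if not unnormalized:
        log_alt = log_alt - np.log(s)
    log_null = math.log(prior.pi0) + stats.norm.logpdf(z)
    out = 1.0 / (1.0 + np.exp(log_null - log_alt))
    return out


def ltdr(summary: AssociationSummary, prior: MixturePrior, *, unnormalized: bool = False) -> float:
    """Local true discovery rate of one SNP in the primary study."""
    return float(ltdr_arrays(summary.z, summary.sigma, prior, unnormalized=unnormalized))


def average_power_eb(
    summaries: Sequence[AssociationSummary],
    prior: MixturePrior,
    sigma2s,
    alpha2: float,
    *,
    unnormalized_ltdr: bool = False,
) -> float:
    """ltdr-weighted average of the EB predictive powers over identified SNPs.

    sum_i ltdr_i * eta_i / sum_i ltdr_i for i in the identified set T;
    the weights discount probable false positives in T.
    """
    if len(summaries) == 0:
        raise ValueError("identified set is empty")
    mu = np.array([s.mu_hat for s in summaries])
    sg = np.array([s.sigma for s in summaries])
    sigma2s = np.broadcast_to(np.asarray(sigma2s, dtype=float), mu.shape)
    w = ltdr_arrays(mu / sg, sg, prior, unnormalized=unnormalized_ltdr)
    if np.all(w == 0):
        raise ValueError("all ltdr weights are zero; cannot form a weighted average")
    lam = shrinkage_lambda(sg, prior.sigma0)
    eta = eb_predictive_power_arrays(mu, sg, lam, sigma2s, alpha2)
    return float(np.sum(w * eta) / np.sum(w))


def true_average_power(mu_true, sigma2s, signs, alpha2: float) -> float:
    """Unweighted mean true power over identified truly associated SNPs.

    Simulation-context quantity: requires the true effect sizes.
    ``signs`` are the primary-study signs defining the one-sided
    replication tests.
    """
    mu_true = np.asarray(mu_true, dtype=float)
    if mu_true.size == 0:
        raise ValueError("identified true set is empty")
    return float(np.mean(replication_power(mu_true, signs, sigma2s, alpha2)))


def _avg_power_at(
    mu, sg, w, lam, a0, a1, n_cases: int, ratio: float, alpha2: float
) -> float:
    # per-SNP sigma2 at candidate size, from primary counts: sigma2^2 = a0/n0_rep + a1/n1_rep
    n1_rep = n_cases
    n0_rep = max(ratio * n_cases, 1.0)
    sigma2 = np.sqrt(a0 / n0_rep + a1 / n1_rep)
    eta = eb_predictive_power_arrays(mu, sg, lam, sigma2, alpha2)
    return float(np.sum(w * eta) / np.sum(w))


def required_sample_size(
    tables: Sequence[AlleleCountTable],
    summaries: Sequence[AssociationSummary],
    prior: MixturePrior,
    target_power: float = 0.80,
    ratio: float = 1.0,
    alpha2: float = 5e-6,
    n_max: int = 10**6,
    *,
    unnormalized_ltdr: bool = False,
    curve_points: int = 40,
) -> DesignResult:
    """Smallest replication size whose weighted average power reaches the target.

    ``tables`` are the primary-study allele-count tables of the
    identified SNPs (aligned with ``summaries``); each candidate size
    recomputes the per-SNP replication SE from primary allele
    frequencies with controls = ratio x cases.  Power is strictly
    increasing in the group sizes, so bisection on the case count
    applies.  Raises :class:`TargetPowerUnreachable` if even ``n_max``
    cases fall short.
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must lie in (0, 1)")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if len(tables) != len(summaries) or len(tables) == 0:
        raise ValueError("tables and summaries must be aligned and non-empty")
    mu = np.array([s.mu_hat for s in summaries])
    sg = np.array([s.sigma for s in summaries])
    w = ltdr_arrays(mu / sg, sg, prior, unnormalized=unnormalized_ltdr)
    if np.all(w == 0):
        raise ValueError("all ltdr weights are zero")
    lam = shrinkage_lambda(sg, prior.sigma0)
    # SE decomposition sigma2^2(n) = a0/n0_rep + a1/n1_rep with coefficients
    # frozen from the primary counts (continuity-corrected if a cell is zero)
    from .assoc_core import apply_continuity_correction

    n00, n01, n10, n11 = apply_continuity_correction(
        np.array([t.n00 for t in tables]),
        np.array([t.n01 for t in tables]),
        np.array([t.n10 for t in tables]),
        np.array([t.n11 for t in tables]),
    )
    n0 = np.array([t.n0 for t in tables], dtype=float)
    n1 = np.array([t.n1 for t in tables], dtype=float)
    a0 = n0 * (1.0 / n00 + 1.0 / n01)
    a1 = n1 * (1.0 / n10 + 1.0 / n11)

    def power_at(n: int) -> float:
        return _avg_power_at(mu, sg, w, lam, a0, a1, n, ratio, alpha2)

    p_lo = power_at(1)
    if p_lo >= target_power:
        n_star, achieved = 1, p_lo
    else:
        p_hi = power_at(n_max)
        if p_hi < target_power:
            raise TargetPowerUnreachable(target_power, n_max, p_hi)
        lo, hi = 1, n_max  # invariant: power(lo) < target <= power(hi)
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if power_at(mid) >= target_power:
                hi = mid
            else:
                lo = mid
        n_star, achieved = hi, power_at(hi)

    sizes = np.unique(
        np.clip(np.geomspace(1, max(2 * n_star, 10), num=curve_points).astype(int), 1, None)
    )
    per_group_total = 1.0 + ratio  # total replication size counts cases + controls
    curve = [(int(round(n * per_group_total)), power_at(int(n))) for n in sizes]
    return DesignResult(
        n_cases=n_star,
        n_controls=int(math.ceil(ratio * n_star)),
        target_power=target_power,
        achieved_power=achieved,
        curve=curve,
    )
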