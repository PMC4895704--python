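"""Empirical-Bayes hyperparameter estimation for the effect-size prior.

Genome-wide, per-SNP log-odds ratios are modelled by a two-component
mixture prior: a point mass at zero with weight ``pi0`` (null SNPs) and
a zero-mean Gaussian with variance ``sigma0_sq`` for the associated
SNPs.  Both hyperparameters are estimated from the primary-study
summary statistics alone: ``pi0`` by Storey's p-value census with an
automatic spline extrapolation, ``sigma0_sq`` by a method-of-moments
estimator derived from the marginal distribution of the Wald
statistics,

    Z ~ pi0 N(0, 1) + (1 - pi0) N(0, 1 + (sigma0 / sigma_i)^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import interpolate, stats

from .assoc_core import AssociationSummary

__all__ = [
    "MixturePrior",
    "two_sided_pvalues",
    "estimate_pi0_fixed_gamma",
    "estimate_pi0_spline",
    "estimate_sigma0_sq",
    "fit_prior",
    "fit_prior_arrays",
    "PI0_GAMMA_GRID",
    "MIN_SNPS_FOR_SPLINE",
]

logger = logging.getLogger(__name__)

#: gamma grid for the Storey census, 0 to 0.90 in steps of 0.05
PI0_GAMMA_GRID = np.arange(0.0, 0.9001, 0.05)

#: below this many SNPs the spline fit is unstable; fall back to gamma = 0.5
MIN_SNPS_FOR_SPLINE = 100


@dataclass(frozen=True)
class MixturePrior:
    """Two-component effect-size prior pi0*delta_0 + (1-pi0)*N(0, sigma0_sq).

    ``sigma0_sq`` may be ``math.inf``: the sentinel for the degenerate
    case pi0 = 1 with over-dispersed statistics, in which downstream
    shrinkage disappears (lambda = 1).
    """

    pi0: float
    sigma0_sq: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError(f"pi0 must lie in [0, 1], got {self.pi0}")
        if not (self.sigma0_sq >= 0.0):  # also rejects NaN
            raise ValueError(f"sigma0_sq must be >= 0 (or inf), got {self.sigma0_sq}")

    @property
    def pi1(self) -> float:
        """Prior weight of the associated (non-null) component."""
        return 1.0 - self.pi0

    @property
    def sigma0(self) -> float:
        return math.sqrt(self.sigma0_sq)


def two_sided_pvalues(z_values) -> np.ndarray:
    """Two-sided normal p-values, p_i = 2 * (1 - Phi(|z_i|))."""
    z = np.asarray(z_values, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z values must be finite")
    return 2.0 * stats.norm.sf(np.abs(z))


def estimate_pi0_fixed_gamma(pvalues, gamma: float) -> float:
    """Storey's fixed-threshold estimator: #{p > gamma} / (m (1 - gamma)).

    Uniform null p-values give an unbiased census above any threshold
    gamma; the raw ratio is clamped into (0, 1] with floor 1/m.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must lie in (0, 1), got {gamma}")
    raw = np.count_nonzero(p > gamma) / (p.size * (1.0 - gamma))
    return _clamp_pi0(raw, p.size)


def _clamp_pi0(raw: float, m: int) -> float:
    if raw > 1.0:
        return 1.0
    floor = 1.0 / m
    if raw < floor:
        logger.warning("pi0 estimate %.3g clamped to floor 1/m = %.3g", raw, floor)
        return floor
    return raw


@lru_cache(maxsize=8)
def _smoothing_penalty_for_df(grid: tuple, target_df: float = 3.0) -> float:
    """Penalty lambda giving a natural cubic smoothing spline ``target_df``
    effective degrees of freedom on the fixed gamma grid.

    The smoother matrix depends only on the abscissae and the penalty, so
    its trace (the effective df) is found once per grid by bisection on a
    log scale; the hat-matrix trace is accumulated column-by-column by
    smoothing unit vectors.
    """
    x = np.asarray(grid, dtype=float)

    def edf(lam: float) -> float:
        tr = 0.0
        for i in range(x.size):
            e = np.zeros_like(x)
            e[i] = 1.0
            tr += float(interpolate.make_smoothing_spline(x, e, lam=lam)(x[i]))
        return tr

    lo, hi = 1e-10, 1e4  # edf(lo) ~ n, edf(hi) ~ 2
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        if edf(mid) > target_df:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def estimate_pi0_spline(pvalues) -> float:
    """Storey's automatic pi0: spline of pi0_hat(gamma) evaluated at gamma = 1.

    The fixed-gamma census is evaluated on the grid gamma = 0, 0.05,
    ..., 0.90 and smoothed by a natural cubic smoothing spline with 3
    effective degrees of freedom; the smooth is carried to gamma = 1 by
    the natural boundary condition (linear continuation beyond the last
    grid point), trading off the bias of small gamma against the
    variance of large gamma.  Fewer than ``MIN_SNPS_FOR_SPLINE``
    p-values fall back to the fixed gamma = 0.5 estimator.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if p.size < MIN_SNPS_FOR_SPLINE:
        logger.warning(
            "only %d p-values (< %d): falling back to fixed gamma = 0.5",
            p.size,
            MIN_SNPS_FOR_SPLINE,
        )
        return estimate_pi0_fixed_gamma(p, 0.5)
    gammas = PI0_GAMMA_GRID
    # raw (unclamped) census values; clamping is applied to the final estimate
    raw = np.array([np.count_nonzero(p > g) / (p.size * (1.0 - g)) for g in gammas])
    lam = _smoothing_penalty_for_df(tuple(gammas))
    spl = interpolate.make_smoothing_spline(gammas, raw, lam=lam)
    g_max = float(gammas[-1])
    at_one = float(spl(g_max)) + float(spl.derivative()(g_max)) * (1.0 - g_max)
    return _clamp_pi0(at_one, p.size)


def estimate_sigma0_sq(z_values, sigmas, pi0: float) -> float:
    """Moment estimator of the non-null effect-size variance.

    Under the two-component marginal, E(sum z_i^2) = m pi0 +
    (1 - pi0)(m + sigma0^2 sum 1/sigma_i^2), inverted to

        sigma0_sq = max(0, ((sum z^2 - m pi0)/(1 - pi0) - m) / sum(1/sigma_i^2)).

    Two degenerate regimes: mean z^2 <= 1 (no over-dispersion beyond the
    null) returns 0; pi0 = 1 with mean z^2 > 1 returns +inf, the
    no-shrinkage sentinel.
    """
    z = np.asarray(z_values, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if z.shape != s.shape:
        raise ValueError(f"shape mismatch: z {z.shape} vs sigmas {s.shape}")
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError(f"pi0 must lie in [0, 1], got {pi0}")
    m = z.size
    sum_z2 = float(np.sum(z**2))
    if sum_z2 / m <= 1.0:
        return 0.0
    if pi0 == 1.0:
        return math.inf
    raw = ((sum_z2 - m * pi0) / (1.0 - pi0) - m) / float(np.sum(1.0 / s**2))
    return max(0.0, raw)


def fit_prior_arrays(z_values, sigmas, *, pi0_override: float | None = None) -> MixturePrior:
    """Fit the mixture prior from parallel (z, sigma) arrays.

    pi0 via the Storey spline (unless overridden), then sigma0_sq via
    the moment estimator using that pi0.
    """
    z = np.asarray(z_values, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if pi0_override is None:
        pi0 = estimate_pi0_spline(two_sided_pvalues(z))
    else:
        pi0 = pi0_override
    return MixturePrior(pi0=pi0, sigma0_sq=estimate_sigma0_sq(z, s, pi0))


def fit_prior(summaries: Sequence[AssociationSummary], *, pi0_override: float | None = None) -> MixturePrior:
    """Fit the mixture prior from a genome-wide set of association summaries."""
    if len(summaries) == 0:
        raise ValueError("no summaries provided")
    z = np.array([su.z for su in summaries])
    s = np.array([su.sigma for su in summaries])
    if pi0_override is None and z.size < MIN_SNPS_FOR_SPLINE:
        raise ValueError(
            f"{z.size} SNPs is below the minimum ({MIN_SNPS_FOR_SPLINE}) for a stable "
            "genome-wide prior fit"
        )
    return fit_prior_arrays(z, s, pi0_override=pi0_override)
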