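"""Association statistics for allele-based case-control tables.

A single SNP in a case-control GWAS is summarised by a 2x2 allele-count
table (controls x cases vs non-effect x effect allele).  The log odds
ratio and its Woolf standard error give a Wald z statistic; the primary
study uses a two-sided test, the replication study a one-sided test that
must agree in sign with the primary result.  This module also provides
the replication-study power function and the approximation of the
replication-stage standard error from primary-stage allele frequencies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "AlleleCountTable",
    "AssociationSummary",
    "StudyDesign",
    "log_odds_ratio",
    "woolf_se",
    "wald_summary",
    "is_primary_significant",
    "replication_power",
    "replication_se",
    "counts_log_odds_ratio",
    "counts_woolf_se",
    "counts_replication_se",
    "apply_continuity_correction",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlleleCountTable:
    """Allele-based 2x2 contingency table of one SNP in one study.

    ``n00``/``n01`` are control non-effect/effect allele counts,
    ``n10``/``n11`` the case counts.  Each subject contributes two
    alleles, so both margins must be even; ``n0``/``n1`` are the implied
    numbers of control/case subjects.
    """

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        for name in ("n00", "n01", "n10", "n11"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"{name}={v!r}: counts must be non-negative integers")
        if (self.n00 + self.n01) % 2 or (self.n10 + self.n11) % 2:
            raise ValueError(
                "allele-count margins must be even (two alleles per subject): "
                f"controls {self.n00 + self.n01}, cases {self.n10 + self.n11}"
            )

    @property
    def n0(self) -> int:
        """Number of control subjects."""
        return (self.n00 + self.n01) // 2

    @property
    def n1(self) -> int:
        """Number of case subjects."""
        return (self.n10 + self.n11) // 2

    def cells(self) -> tuple[int, int, int, int]:
        return (self.n00, self.n01, self.n10, self.n11)

    def swapped_alleles(self) -> "AlleleCountTable":
        """Table with the effect / non-effect allele columns exchanged."""
        return AlleleCountTable(self.n01, self.n00, self.n11, self.n10)


@dataclass(frozen=True)
class AssociationSummary:
    """Per-SNP summary statistics of the primary study: (mu_hat, sigma, z)."""

    snp_id: str
    mu_hat: float
    sigma: float
    z: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"{self.snp_id}: sigma must be positive, got {self.sigma}")
        if not math.isclose(self.z, self.mu_hat / self.sigma, rel_tol=1e-12, abs_tol=1e-300):
            raise ValueError(f"{self.snp_id}: z != mu_hat/sigma")

    @classmethod
    def from_estimate(cls, snp_id: str, mu_hat: float, sigma: float) -> "AssociationSummary":
        return cls(snp_id, float(mu_hat), float(sigma), float(mu_hat) / float(sigma))


@dataclass(frozen=True)
class StudyDesign:
    """Group sizes and significance level of one study stage.

    The primary stage rejects two-sided at level ``alpha``; the
    replication stage rejects one-sided in the direction of the primary
    effect.
    """

    n0: int
    n1: int
    alpha: float
    stage: Literal["primary", "replication"] = "primary"

    def __post_init__(self) -> None:
        if self.n0 < 1 or self.n1 < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 < self.alpha < 0.5:
            raise ValueError(f"alpha must lie in (0, 0.5), got {self.alpha}")
        if self.stage not in ("primary", "replication"):
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def critical_value(self) -> float:
        """Normal critical value: z_{alpha/2} (primary) or z_alpha (replication)."""
        if self.stage == "primary":
            return float(stats.norm.isf(self.alpha / 2.0))
        return float(stats.norm.isf(self.alpha))


def apply_continuity_correction(
    n00: np.ndarray, n01: np.ndarray, n10: np.ndarray, n11: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Haldane-Anscombe correction: add 0.5 to every cell of tables with a zero.

    Operates on parallel count arrays; rows without zeros are untouched.
    """
    n00, n01, n10, n11 = (np.asarray(a, dtype=float) for a in (n00, n01, n10, n11))
    zero = (n00 == 0) | (n01 == 0) | (n10 == 0) | (n11 == 0)
    if np.any(zero):
        logger.warning(
            "continuity correction (+0.5 to all cells) applied to %d table(s) with a zero cell",
            int(np.count_nonzero(zero)),
        )
        n00 = np.where(zero, n00 + 0.5, n00)
        n01 = np.where(zero, n01 + 0.5, n01)
        n10 = np.where(zero, n10 + 0.5, n10)
        n11 = np.where(zero, n11 + 0.5, n11)
    return n00, n01, n10, n11


def _cells(table: AlleleCountTable, continuity: bool, context: str) -> tuple[float, float, float, float]:
    cells = table.cells()
    if 0 in cells:
        if not continuity:
            raise ValueError(
                f"{context}: zero cell in table {cells}; enable the continuity "
                "correction or drop the SNP"
            )
        logger.warning("%s: zero cell in %s, applying +0.5 continuity correction", context, cells)
        return tuple(c + 0.5 for c in cells)  # type: ignore[return-value]
    return tuple(float(c) for c in cells)  # type: ignore[return-value]


def log_odds_ratio(table: AlleleCountTable, *, continuity: bool = True) -> float:
    """Log of the observed allele-based odds ratio.

    ``log n00 - log n01 - log n10 + log n11``; antisymmetric under
    swapping the effect and non-effect allele columns.
    """
    n00, n01, n10, n11 = _cells(table, continuity, "log_odds_ratio")
    return math.log(n00) - math.log(n01) - math.log(n10) + math.log(n11)


def woolf_se(table: AlleleCountTable, *, continuity: bool = True) -> float:
    """Woolf's asymptotic standard error of the log odds ratio.

    ``sqrt(1/n00 + 1/n01 + 1/n10 + 1/n11)``; invariant under the
    allele-column swap.
    """
    n00, n01, n10, n11 = _cells(table, continuity, "woolf_se")
    return math.sqrt(1.0 / n00 + 1.0 / n01 + 1.0 / n10 + 1.0 / n11)


def wald_summary(table: AlleleCountTable, snp_id: str = "", *, continuity: bool = True) -> AssociationSummary:
    """Bundle log-OR, Woolf SE and the Wald statistic z = mu_hat / sigma."""
    mu = log_odds_ratio(table, continuity=continuity)
    se = woolf_se(table, continuity=continuity)
    return AssociationSummary(snp_id, mu, se, mu / se)


def is_primary_significant(z: float, alpha1: float) -> bool:
    """Two-sided primary-study test: |z| strictly exceeds z_{alpha1/2}."""
    if not 0 < alpha1 < 0.5:
        raise ValueError(f"alpha1 must lie in (0, 0.5), got {alpha1}")
    return bool(abs(z) > stats.norm.isf(alpha1 / 2.0))


def replication_power(mu, sign1, sigma2, alpha2):
    """Power of the sign-consistent one-sided replication test.

    Phi(sign1 * mu / sigma2 - z_{alpha2}): the probability that the
    replication Wald statistic exceeds z_{alpha2} in the direction of
    the primary-study effect, for true log-OR ``mu`` and replication
    standard error ``sigma2``.  At mu = 0 this equals alpha2, the type-I
    error rate.  Accepts scalars or broadcastable arrays.
    """
    mu = np.asarray(mu, dtype=float)
    sign1 = np.asarray(sign1, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sign1 == 0):
        raise ValueError("sign1 must be +1 or -1 (replication is defined only for a nonzero primary effect)")
    if np.any(np.abs(sign1) != 1):
        raise ValueError("sign1 must be +1 or -1")
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be positive")
    if not 0 < alpha2 < 0.5:
        raise ValueError(f"alpha2 must lie in (0, 0.5), got {alpha2}")
    out = stats.norm.cdf(sign1 * mu / sigma2 - stats.norm.isf(alpha2))
    return float(out) if out.ndim == 0 else out


def replication_se(primary: AlleleCountTable, n0_rep: int, n1_rep: int, *, continuity: bool = True) -> float:
    """Replication-stage SE approximated from primary-stage allele frequencies.

    ``sqrt((n0_1/n0_2)(1/n00 + 1/n01) + (n1_1/n1_2)(1/n10 + 1/n11))``
    with all counts from the primary table.  Equals the primary Woolf SE
    when the replication group sizes match the primary ones, and scales
    as 1/sqrt(size) in each group.
    """
    if n0_rep < 1 or n1_rep < 1:
        raise ValueError("replication group sizes must be >= 1")
    n00, n01, n10, n11 = _cells(primary, continuity, "replication_se")
    return math.sqrt(
        (primary.n0 / n0_rep) * (1.0 / n00 + 1.0 / n01)
        + (primary.n1 / n1_rep) * (1.0 / n10 + 1.0 / n11)
    )


# ---------------------------------------------------------------------------
# Vectorised variants over parallel count arrays (used by the simulator and
# the experiment harness, where per-row Python objects would be too slow).

def counts_log_odds_ratio(n00, n01, n10, n11, *, continuity: bool = True) -> np.ndarray:
    if continuity:
        n00, n01, n10, n11 = apply_continuity_correction(n00, n01, n10, n11)
    else:
        arrs = [np.asarray(a, dtype=float) for a in (n00, n01, n10, n11)]
        if any(np.any(a == 0) for a in arrs):
            raise ValueError("zero cell encountered with continuity correction disabled")
        n00, n01, n10, n11 = arrs
    return np.log(n00) - np.log(n01) - np.log(n10) + np.log(n11)


def counts_woolf_se(n00, n01, n10, n11, *, continuity: bool = True) -> np.ndarray:
    if continuity:
        n00, n01, n10, n11 = apply_continuity_correction(n00, n01, n10, n11)
    else:
        n00, n01, n10, n11 = (np.asarray(a, dtype=float) for a in (n00, n01, n10, n11))
    return np.sqrt(1.0 / n00 + 1.0 / n01 + 1.0 / n10 + 1.0 / n11)


def counts_replication_se(n00, n01, n10, n11, n0_rep, n1_rep, *, continuity: bool = True) -> np.ndarray:
    n00r, n01r, n10r, n11r = apply_continuity_correction(n00, n01, n10, n11) if continuity else (
        np.asarray(n00, float), np.asarray(n01, float), np.asarray(n10, float), np.asarray(n11, float)
    )
    n0 = (np.asarray(n00, float) + np.asarray(n01, float)) / 2.0
    n1 = (np.asarray(n10, float) + np.asarray(n11, float)) / 2.0
    return np.sqrt(
        (n0 / n0_rep) * (1.0 / n00r + 1.0 / n01r) + (n1 / n1_rep) * (1.0 / n10r + 1.0 / n11r)
    )
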