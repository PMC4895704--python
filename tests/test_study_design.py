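"""ltdr, weighted average power, and replication sample-size determination."""

import math

import numpy as np
import pytest
from scipy import stats

from replipower.assoc_core import AlleleCountTable, replication_power, wald_summary
from replipower.power_estimators import shrinkage_lambda
from replipower.prior_estimation import MixturePrior
from replipower.study_design import (
    TargetPowerUnreachable,
    average_power_eb,
    ltdr,
    required_sample_size,
    true_average_power,
)

from .conftest import make_summary


def mixture_posterior_oracle(z, sigma1, pi0, sigma0_sq):
    """Independent Bayes-rule arithmetic on the two-component marginal of z."""
    s2 = 1.0 + sigma0_sq / sigma1**2
    f_null = stats.norm.pdf(z)
    f_alt = stats.norm.pdf(z, scale=math.sqrt(s2))
    return (1 - pi0) * f_alt / (pi0 * f_null + (1 - pi0) * f_alt)


class TestLtdr:
    def test_degenerate_priors(self):
        s = make_summary(0.4, 0.1)
        assert ltdr(s, MixturePrior(1.0, 0.04)) == 0.0
        assert ltdr(s, MixturePrior(0.0, 0.04)) == 1.0

    def test_hand_value_normalized_density(self):
        # pi0=0.9, (sigma0/sigma1)^2 = 4, z = 3
        s = make_summary(0.3, 0.1)
        val = ltdr(s, MixturePrior(0.9, 0.04))
        expected = (0.1 * stats.norm.pdf(3 / math.sqrt(5)) / math.sqrt(5)) / (
            0.9 * stats.norm.pdf(3.0) + 0.1 * stats.norm.pdf(3 / math.sqrt(5)) / math.sqrt(5)
        )
        assert val == pytest.approx(expected, rel=1e-10)
        assert val == pytest.approx(0.646, abs=1e-3)

    def test_matches_independent_mixture_oracle(self, rng):
        for _ in range(50):
            sigma1 = rng.uniform(0.05, 0.2)
            z = rng.normal(0, 3)
            pi0 = rng.uniform(0.05, 0.99)
            s0sq = rng.uniform(0.001, 0.3)
            s = make_summary(z * sigma1, sigma1)
            assert ltdr(s, MixturePrior(pi0, s0sq)) == pytest.approx(
                mixture_posterior_oracle(z, sigma1, pi0, s0sq), rel=1e-10, abs=1e-12
            )

    def test_increasing_in_abs_z(self):
        prior = MixturePrior(0.9, 0.04)
        vals = [ltdr(make_summary(z * 0.1, 0.1), prior) for z in (1, 2, 3, 5, 8)]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_unnormalized_compatibility_variant_differs(self):
        s = make_summary(0.3, 0.1)
        prior = MixturePrior(0.9, 0.04)
        assert ltdr(s, prior, unnormalized=True) > ltdr(s, prior)


class TestAveragePower:
    def test_hand_weighted_mean(self):
        # directly check the weighting arithmetic on fixed weights/powers
        w = np.array([0.2, 0.8])
        eta = np.array([0.5, 0.9])
        assert float(np.sum(w * eta) / np.sum(w)) == pytest.approx(0.82)

    def test_single_snp_returns_its_power(self):
        from replipower.power_estimators import eb_predictive_power

        s = make_summary(0.5, 0.11)
        prior = MixturePrior(0.9, 0.04)
        avg = average_power_eb([s], prior, 0.1, 5e-3)
        assert avg == pytest.approx(eb_predictive_power(s, prior, 0.1, 5e-3), rel=1e-12)

    def test_between_min_and_max_per_snp_power(self):
        prior = MixturePrior(0.9, 0.04)
        snps = [make_summary(m, 0.1, f"s{i}") for i, m in enumerate((0.42, 0.5, 0.65))]
        from replipower.power_estimators import eb_predictive_power

        etas = [eb_predictive_power(s, prior, 0.1, 5e-3) for s in snps]
        avg = average_power_eb(snps, prior, 0.1, 5e-3)
        assert min(etas) <= avg <= max(etas)

    def test_all_null_prior_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            average_power_eb([make_summary(0.5, 0.11)], MixturePrior(1.0, 0.0), 0.1, 5e-3)

    def test_true_average_power_is_elementwise_mean(self):
        mu = np.array([0.1, 0.2, -0.3])
        signs = np.array([1.0, 1.0, -1.0])
        s2 = np.array([0.08, 0.1, 0.12])
        expected = np.mean([replication_power(m, sg, s, 5e-3) for m, sg, s in zip(mu, signs, s2)])
        assert true_average_power(mu, s2, signs, 5e-3) == pytest.approx(expected, rel=1e-12)
        # degenerate all-null identified set: power equals the type-I rate
        assert true_average_power([0.0, 0.0], 0.1, 1.0, 5e-3) == pytest.approx(5e-3, rel=1e-9)


class TestRequiredSampleSize:
    @staticmethod
    def single_snp_setup():
        table = AlleleCountTable(1400, 600, 1200, 800)
        summary = wald_summary(table, "rs1")
        prior = MixturePrior(0.9, 0.04)
        return table, summary, prior

    def test_single_snp_matches_closed_form_inversion(self):
        """Algebraic oracle: invert the closed-form predictive power in the
        replication SE, then map to the case count via the SE decomposition."""
        table, summary, prior = self.single_snp_setup()
        target, alpha2, ratio = 0.8, 5e-6, 1.0
        res = required_sample_size([table], [summary], prior, target, ratio, alpha2)

        lam = shrinkage_lambda(summary.sigma, prior.sigma0)
        q = stats.norm.ppf(target)
        z_a2 = stats.norm.isf(alpha2)
        a = lam * abs(summary.mu_hat)
        b = lam * summary.sigma**2
        # solve (a x - z_a2)^2 = q^2 (1 + b x^2) for x = 1/sigma2, taking the
        # root on the increasing branch
        A = a**2 - q**2 * b
        B = -2 * a * z_a2
        C = z_a2**2 - q**2
        x = (-B + math.sqrt(B**2 - 4 * A * C)) / (2 * A)
        coef = table.n0 * (1 / table.n00 + 1 / table.n01) / ratio + table.n1 * (
            1 / table.n10 + 1 / table.n11
        )
        n_exact = coef * x**2
        assert abs(res.n_cases - math.ceil(n_exact)) <= 1

    def test_trivial_boundary_target_already_met(self):
        table, summary, prior = self.single_snp_setup()
        res = required_sample_size([table], [summary], prior, target_power=0.001, alpha2=0.05)
        assert res.n_cases == 1

    def test_higher_target_never_needs_fewer_cases(self):
        table, summary, prior = self.single_snp_setup()
        n_low = required_sample_size([table], [summary], prior, 0.4, alpha2=5e-6).n_cases
        n_high = required_sample_size([table], [summary], prior, 0.8, alpha2=5e-6).n_cases
        assert n_high >= n_low

    def test_monotone_in_alpha2_and_sigma0(self):
        table, summary, prior = self.single_snp_setup()
        n_strict = required_sample_size([table], [summary], prior, 0.8, alpha2=5e-8).n_cases
        n_loose = required_sample_size([table], [summary], prior, 0.8, alpha2=5e-4).n_cases
        assert n_strict >= n_loose
        n_small_prior = required_sample_size(
            [table], [summary], MixturePrior(0.9, 0.01), 0.8, alpha2=5e-6
        ).n_cases
        n_large_prior = required_sample_size(
            [table], [summary], MixturePrior(0.9, 0.16), 0.8, alpha2=5e-6
        ).n_cases
        assert n_small_prior >= n_large_prior

    def test_curve_is_monotone_and_reaches_target(self):
        table, summary, prior = self.single_snp_setup()
        res = required_sample_size([table], [summary], prior, 0.8, alpha2=5e-6)
        powers = [p for _, p in res.curve]
        sizes = [n for n, _ in res.curve]
        assert sizes == sorted(sizes)
        assert all(x <= y + 1e-12 for x, y in zip(powers, powers[1:]))
        assert res.achieved_power >= 0.8

    def test_unreachable_target_raises_with_diagnostics(self):
        # a weakly-shrunk small effect cannot reach 99.9% power below n_max
        table = AlleleCountTable(1100, 900, 1000, 1000)
        summary = wald_summary(table, "weak")
        prior = MixturePrior(0.9, 0.0005)
        with pytest.raises(TargetPowerUnreachable) as err:
            required_sample_size([table], [summary], prior, 0.999, alpha2=5e-8, n_max=10_000)
        assert 0.0 < err.value.power_at_max < 0.999
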