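"""Association statistics: log-OR, Woolf SE, Wald test, replication power/SE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import Table2x2

from replipower.assoc_core import (
    AlleleCountTable,
    AssociationSummary,
    StudyDesign,
    is_primary_significant,
    log_odds_ratio,
    replication_power,
    replication_se,
    wald_summary,
    woolf_se,
)

cell_counts = st.integers(min_value=1, max_value=5000)


def even_table(a, b, c, d):
    """Force even margins by doubling every cell."""
    return AlleleCountTable(2 * a, 2 * b, 2 * c, 2 * d)


class TestTableValidation:
    def test_rejects_negative_and_fractional_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            AlleleCountTable(-1, 3, 2, 2)

    def test_rejects_odd_margins(self):
        with pytest.raises(ValueError, match="even"):
            AlleleCountTable(1, 2, 2, 2)

    def test_subject_counts_derived_from_margins(self):
        t = AlleleCountTable(100, 50, 40, 110)
        assert (t.n0, t.n1) == (75, 75)


class TestLogOddsRatio:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((100, 100, 100, 100), 0.0),
            ((100, 50, 50, 100), math.log(4.0)),
        ],
    )
    def test_hand_values(self, cells, expected):
        assert log_odds_ratio(AlleleCountTable(*cells)) == pytest.approx(expected, abs=1e-12)

    @given(a=cell_counts, b=cell_counts, c=cell_counts, d=cell_counts)
    @settings(max_examples=50, derandomize=True)
    def test_antisymmetric_under_allele_swap(self, a, b, c, d):
        t = even_table(a, b, c, d)
        assert log_odds_ratio(t.swapped_alleles()) == pytest.approx(-log_odds_ratio(t), abs=1e-12)

    def test_zero_cell_without_correction_raises(self):
        t = AlleleCountTable(0, 2, 2, 2)
        with pytest.raises(ValueError, match="zero cell"):
            log_odds_ratio(t, continuity=False)

    def test_zero_cell_with_correction_adds_half_to_all_cells(self):
        t = AlleleCountTable(0, 2, 2, 2)
        expected = math.log(0.5) - math.log(2.5) - math.log(2.5) + math.log(2.5)
        assert log_odds_ratio(t) == pytest.approx(expected, abs=1e-12)


class TestWoolfSE:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((100, 100, 100, 100), 0.2),
            ((400, 400, 400, 400), 0.1),
            ((100, 50, 50, 100), math.sqrt(0.06)),
        ],
    )
    def test_hand_values(self, cells, expected):
        assert woolf_se(AlleleCountTable(*cells)) == pytest.approx(expected, abs=1e-12)

    @given(a=cell_counts, b=cell_counts, c=cell_counts, d=cell_counts)
    @settings(max_examples=50, derandomize=True)
    def test_invariant_under_allele_swap(self, a, b, c, d):
        t = even_table(a, b, c, d)
        assert woolf_se(t.swapped_alleles()) == pytest.approx(woolf_se(t), abs=1e-15)


class TestWaldSummary:
    def test_balanced_table_gives_zero_z(self):
        assert wald_summary(AlleleCountTable(100, 100, 100, 100)).z == 0.0

    def test_hand_value(self):
        s = wald_summary(AlleleCountTable(100, 50, 50, 100), "rs1")
        assert s.z == pytest.approx(math.log(4.0) / math.sqrt(0.06), rel=1e-10)
        assert s.z == pytest.approx(5.660, abs=1e-3)

    @given(a=cell_counts, b=cell_counts, c=cell_counts, d=cell_counts)
    @settings(max_examples=50, derandomize=True)
    def test_matches_independent_2x2_wald_computation(self, a, b, c, d):
        t = even_table(a, b, c, d)
        oracle = Table2x2(np.array([[t.n00, t.n01], [t.n10, t.n11]]))
        s = wald_summary(t)
        assert s.mu_hat == pytest.approx(oracle.log_oddsratio, rel=1e-12, abs=1e-12)
        assert s.sigma == pytest.approx(oracle.log_oddsratio_se, rel=1e-12)
        assert s.z == pytest.approx(oracle.log_oddsratio / oracle.log_oddsratio_se, rel=1e-12)

    def test_summary_invariant_enforced(self):
        with pytest.raises(ValueError, match="z != mu_hat/sigma"):
            AssociationSummary("bad", 0.3, 0.1, 1.0)
        with pytest.raises(ValueError, match="sigma"):
            AssociationSummary("bad", 0.3, -0.1, -3.0)


class TestPrimarySignificance:
    @pytest.mark.parametrize(
        "z, alpha1, expected",
        [
            (0.0, 0.05, False),
            (4.05, 5e-5, False),  # threshold z_{2.5e-5} = 4.05563; strict inequality
            (4.06, 5e-5, True),
            (-10.0, 5e-8, True),
        ],
    )
    def test_rejection_region(self, z, alpha1, expected):
        assert is_primary_significant(z, alpha1) is expected

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            is_primary_significant(1.0, 0.7)


class TestReplicationPower:
    def test_null_effect_gives_type_one_error_rate(self):
        assert replication_power(0.0, 1, 0.05, 5e-3) == pytest.approx(5e-3, rel=1e-9)

    def test_normal_prior_scenario_value(self):
        # mu = 0.15, sigma2 = 0.05, alpha2 = 5e-3: Phi(3 - 2.5758)
        assert replication_power(0.15, 1, 0.05, 5e-3) == pytest.approx(0.664, abs=1e-3)

    def test_limits_and_monotonicity(self):
        assert replication_power(50.0, 1, 0.05, 5e-3) == pytest.approx(1.0, abs=1e-12)
        mus = np.linspace(-0.3, 0.5, 101)  # away from floating-point saturation
        p = replication_power(mus, 1, 0.05, 5e-3)
        assert np.all(np.diff(p) > 0)
        # sign-flip symmetry: power(mu, +1) == power(-mu, -1)
        assert replication_power(0.3, -1, 0.05, 5e-3) == pytest.approx(
            replication_power(-0.3, 1, 0.05, 5e-3), rel=1e-12
        )

    def test_zero_sign_rejected(self):
        with pytest.raises(ValueError, match="sign1"):
            replication_power(0.1, 0, 0.05, 5e-3)


class TestReplicationSE:
    def test_matching_designs_recover_woolf(self):
        t = AlleleCountTable(300, 100, 250, 150)
        assert replication_se(t, t.n0, t.n1) == pytest.approx(woolf_se(t), rel=1e-12)

    def test_quarter_size_doubles_se(self):
        t = AlleleCountTable(400, 400, 400, 400)
        assert replication_se(t, 100, 100) == pytest.approx(2 * woolf_se(t), rel=1e-12)

    def test_hand_value(self):
        t = AlleleCountTable(500, 500, 500, 500)
        assert replication_se(t, 250, 250) == pytest.approx(0.1265, abs=5e-4)

    def test_decreasing_in_replication_sizes(self):
        t = AlleleCountTable(300, 100, 250, 150)
        ses = [replication_se(t, n, n) for n in (50, 100, 500, 5000, 50000)]
        assert all(x > y for x, y in zip(ses, ses[1:]))
        assert ses[-1] < 0.05 * ses[0]  # -> 0 as sizes grow


class TestStudyDesign:
    def test_critical_values(self):
        primary = StudyDesign(1000, 1000, 0.05, "primary")
        rep = StudyDesign(500, 500, 0.05, "replication")
        assert primary.critical_value == pytest.approx(1.959964, abs=1e-5)
        assert rep.critical_value == pytest.approx(1.644854, abs=1e-5)

    def test_validation(self):
        with pytest.raises(ValueError):
            StudyDesign(0, 10, 0.05)
        with pytest.raises(ValueError):
            StudyDesign(10, 10, 0.6)
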