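"""50:50 chi-squared testing, pooling, Fisher exact and clinical association."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from asikit import asi_stats
from asikit.asi_stats import (NotTestableError, assoc_age, assoc_sex,
                              assoc_stage, bonferroni, chi2_5050,
                              combine_counts, fisher_exact_2xk, meta_combine,
                              screen_for_validation, evaluate_counts)


class TestChi2_5050:
    def test_pooled_cohort_counts(self):
        # 15 vs 33 losses: chi2 = 6.75, p just below 0.01
        chi2, p = chi2_5050(15, 33)
        assert chi2 == pytest.approx(6.75)
        assert round(p, 2) == 0.01

    @pytest.mark.parametrize("k", [1, 5, 50])
    def test_perfect_balance(self, k):
        chi2, p = chi2_5050(k, k)
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_large_imbalance_closed_form(self):
        chi2, p = chi2_5050(49, 100)
        assert chi2 == pytest.approx(2 * 650.25 / 74.5)
        assert p == pytest.approx(2.94e-5, rel=2e-3)

    def test_zero_counts_not_testable(self):
        with pytest.raises(NotTestableError):
            chi2_5050(0, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 200), st.integers(0, 200))
    def test_equals_squared_two_proportion_z(self, a, b):
        """chi2 equals z^2 of the two-sided normal test of a binomial
        proportion against 1/2, and the p-values agree."""
        if a + b == 0:
            return
        chi2, p = chi2_5050(a, b)
        n = a + b
        z = (a - n / 2) / math.sqrt(n * 0.25)
        assert chi2 == pytest.approx(z * z)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_agrees_with_binomial_oracle_ordering(self):
        """Chi-squared p decreases as the split gets more extreme, matching
        the exact binomial tail ordering."""
        ps = [chi2_5050(a, 30 - a)[1] for a in range(15, 31)]
        binom = [2 * stats.binom.sf(a - 1, 30, 0.5) for a in range(15, 31)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))
        assert all(x >= y for x, y in zip(binom, binom[1:]))


class TestBonferroni:
    def test_meta_adjustment(self):
        assert bonferroni(2.94e-5, 7) == pytest.approx(2.06e-4, rel=5e-3)

    def test_combined_adjustment_renders_as_printed(self):
        assert round(bonferroni(0.0094, 3), 2) == 0.03

    def test_capped_at_one(self):
        assert bonferroni(0.9, 7) == 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 50),
           st.integers(1, 50))
    def test_monotone_in_p_and_n(self, p1, p2, n1, n2):
        lo_p, hi_p = sorted([p1, p2])
        lo_n, hi_n = sorted([n1, n2])
        assert bonferroni(lo_p, lo_n) <= bonferroni(hi_p, lo_n) <= 1.0
        assert bonferroni(lo_p, lo_n) <= bonferroni(lo_p, hi_n) <= 1.0


class TestScreening:
    def test_discovery_screen_selects_three_snps(self, discovery_counts):
        results = evaluate_counts(discovery_counts)
        screened = screen_for_validation(results)
        assert set(screened) == {"rs16892766", "rs6983267", "rs7136702"}

    def test_all_null_gives_empty_list(self):
        counts = pd.DataFrame({"snp_id": ["rs1"], "n_het": [20],
                               "n_loss_risk": [5], "n_loss_nonrisk": [5]})
        assert screen_for_validation(evaluate_counts(counts)) == []

    def test_boundary_p_excluded(self):
        results = pd.DataFrame({"snp_id": ["rs1"], "p": [0.10]})
        assert screen_for_validation(results) == []


class TestCombineCounts:
    def test_cohort_sums(self, discovery_counts, validation_counts):
        disc = discovery_counts[discovery_counts["snp_id"] == "rs6983267"]
        val = validation_counts[validation_counts["snp_id"] == "rs6983267"]
        out = combine_counts(disc, val).iloc[0]
        assert (out["n_loss_risk"], out["n_loss_nonrisk"], out["n_het"]) \
            == (15, 33, 192)

    def test_zero_table_is_identity(self, discovery_counts):
        zero = discovery_counts.copy()
        zero[["n_het", "n_loss_risk", "n_loss_nonrisk"]] = 0
        out = combine_counts(discovery_counts, zero)
        merged = out.merge(discovery_counts, on="snp_id",
                           suffixes=("_sum", "_orig"))
        assert (merged["n_het_sum"] == merged["n_het_orig"]).all()

    def test_associative_and_commutative(self, discovery_counts):
        a = discovery_counts
        b = a.assign(n_het=a["n_het"] + 1)
        c = a.assign(n_loss_risk=a["n_loss_risk"] + 2)
        left = combine_counts(combine_counts(a, b), c)
        right = combine_counts(a, combine_counts(c, b))
        pd.testing.assert_frame_equal(left, right)

    def test_snp_mismatch_rejected(self, discovery_counts):
        other = discovery_counts.iloc[:5]
        with pytest.raises(ValueError, match="SNP"):
            combine_counts(discovery_counts, other)


class TestMetaCombine:
    def _own(self, discovery_counts, validation_counts):
        disc = discovery_counts.copy()
        val = validation_counts.copy()
        snps = set(val["snp_id"])
        combined = combine_counts(disc[disc["snp_id"].isin(snps)], val)
        own = pd.concat([combined,
                         disc[~disc["snp_id"].isin(snps)]], ignore_index=True)
        own.insert(0, "study_id", "this_study")
        return own[["study_id", "snp_id", "n_het", "n_loss_risk",
                    "n_loss_nonrisk"]]

    def test_pooled_loss_counts_and_p(self, discovery_counts,
                                      validation_counts,
                                      published_study_counts):
        own = self._own(discovery_counts, validation_counts)
        out = meta_combine(own[own["snp_id"].isin(
            set(published_study_counts["snp_id"]))],
            published_study_counts, n_tests=7)
        row = out.set_index("snp_id").loc["rs6983267"]
        assert (row["n_loss_risk"], row["n_loss_nonrisk"]) == (49, 100)
        assert row["p"] == pytest.approx(2.94e-5, rel=2e-3)
        assert row["p_adjusted"] == pytest.approx(2.06e-4, rel=5e-3)

    def test_single_study_reduces_to_plain_test(self, published_study_counts):
        out = meta_combine(published_study_counts, None, n_tests=7)
        row = out.set_index("snp_id").loc["rs6983267"]
        chi2, p = chi2_5050(34, 67)
        assert row["p"] == pytest.approx(p)

    def test_balanced_snp_stays_null(self, discovery_counts,
                                     validation_counts,
                                     published_study_counts):
        own = self._own(discovery_counts, validation_counts)
        out = meta_combine(own, published_study_counts, n_tests=7)
        row = out.set_index("snp_id").loc["rs9929218"]
        assert (row["n_loss_risk"], row["n_loss_nonrisk"]) == (6, 7)
        assert round(row["p"], 2) == 0.78


def _fraction_fisher_oracle(table):
    """Exact-arithmetic brute-force Fisher p: enumerate all tables with the
    observed margins via itertools and sum Fractions."""
    t = np.asarray(table, dtype=int)
    col_sums = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())

    def prob(row1):
        num = Fraction(1)
        for a, c in zip(row1, col_sums):
            num *= math.comb(c, a)
        return num / math.comb(n, r1)

    obs = prob(t[0])
    total = Fraction(0)
    for row1 in itertools.product(*(range(c + 1) for c in col_sums)):
        if sum(row1) != r1:
            continue
        p = prob(row1)
        if p <= obs:
            total += p
    return float(total)


class TestFisherExact:
    def test_two_by_two_diagonal(self):
        # both tables with these margins have probability 1/2
        assert fisher_exact_2xk([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_two_by_two_extreme(self):
        assert fisher_exact_2xk([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_matches_scipy_two_by_two(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            t = rng.integers(0, 10, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            expected = stats.fisher_exact(t)[1]
            assert fisher_exact_2xk(t) == pytest.approx(expected, rel=1e-9)

    def test_matches_fraction_oracle_2x3(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = rng.integers(0, 6, size=(2, 3))
            if t.sum(axis=1).min() == 0 or (t.sum(axis=0) > 0).sum() < 2:
                continue
            assert fisher_exact_2xk(t) == pytest.approx(
                _fraction_fisher_oracle(t), rel=1e-9)

    def test_zero_row_not_testable(self):
        with pytest.raises(NotTestableError):
            fisher_exact_2xk([[0, 0, 0], [3, 2, 1]])


class TestClinicalAssociation:
    def test_sex_independence(self):
        flags = [True] * 20 + [False] * 20
        sex = (["female"] * 10 + ["male"] * 10) * 2
        out = assoc_sex(flags, sex)
        assert out.statistic == pytest.approx(0.0)
        assert out.p == pytest.approx(1.0)

    def test_sex_perfect_separation(self):
        flags = [True] * 20 + [False] * 20
        sex = ["female"] * 20 + ["male"] * 20
        out = assoc_sex(flags, sex)
        assert out.statistic == pytest.approx(40.0)
        assert out.p < 1e-8

    def test_sex_empty_margin_not_testable(self):
        out = assoc_sex([True, False], ["female", "female"])
        assert not out.testable

    def test_stage_uses_fisher(self):
        flags = [True, False]
        stages = ["I", "II"]
        out = assoc_stage(flags, stages)
        assert out.test == "fisher_exact"
        assert out.p == pytest.approx(1.0)

    def test_stage_extreme_table(self):
        flags = [True] * 5 + [False] * 5
        stages = ["I"] * 5 + ["IV"] * 5
        out = assoc_stage(flags, stages)
        assert out.p == pytest.approx(2 / 252)

    def test_stage_degenerate_not_testable(self):
        out = assoc_stage([True, True], ["I", "II"])
        assert not out.testable

    def test_age_identical_groups(self):
        out = assoc_age([50, 60, 70], [50, 60, 70])
        assert out.statistic == pytest.approx(0.0)
        assert out.p == pytest.approx(1.0)

    def test_age_pooled_t_closed_form(self):
        out = assoc_age([50, 60, 70], [55, 65, 75])
        assert out.statistic == pytest.approx(-0.6124, abs=1e-4)
        assert out.p == pytest.approx(0.5731, abs=5e-3)

    def test_age_group_too_small_not_testable(self):
        out = assoc_age([50], [55, 60])
        assert not out.testable


def test_printed_table_p_values_reproduce(discovery_counts):
    """All 16 discovery-cohort p-values match the printed 2-decimal values."""
    from conftest import DISCOVERY_ROWS
    results = evaluate_counts(discovery_counts).set_index("snp_id")
    for snp, *_, printed in DISCOVERY_ROWS:
        assert f"{round(results.loc[snp, 'p'], 2):.2f}" == printed, snp
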