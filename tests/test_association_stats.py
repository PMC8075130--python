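"""Contingency tests, odds ratios, and summary comparisons.

Fisher's exact p is cross-checked against an independent hypergeometric
enumeration oracle; the chi-square p against a Monte-Carlo permutation null.
"""

import math

import numpy as np
import pytest
from scipy import stats as ss

from mitoscan.association_stats import (
    DegenerateTableError,
    benjamini_hochberg,
    bonferroni,
    cohens_d_summary,
    lineage_chi_square,
    odds_ratio_ci,
    t_from_summary,
    two_by_two_test,
)


def fisher_two_sided_enumeration(a, b, c, d):
    """Independent oracle: sum hypergeometric point masses <= P(observed)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {k: math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
           for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


class TestTwoByTwo:
    def test_flat_table_no_association(self):
        res = two_by_two_test(10, 10, 10, 10)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_reconstructed_association_table(self):
        """(25,4,35,24): expected counts all >= 5 so the chi-square branch
        runs; p lands at the printed 0.011."""
        res = two_by_two_test(25, 4, 35, 24)
        assert res.test == "chi_square"
        assert res.p_value == pytest.approx(0.011, abs=1e-3)
        assert res.odds_ratio == pytest.approx(4.286, abs=5e-4)

    def test_zero_cell_takes_fisher_branch(self):
        res = two_by_two_test(0, 10, 10, 0)
        assert res.test == "fisher_exact"
        assert res.p_value == pytest.approx(
            fisher_two_sided_enumeration(0, 10, 10, 0)
        )

    def test_expected_count_rule(self):
        # expected min = 2.5 < 5 -> Fisher
        assert two_by_two_test(1, 4, 4, 1).test == "fisher_exact"
        # all expected 10 -> chi-square
        assert two_by_two_test(10, 10, 10, 10).test == "chi_square"

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            two_by_two_test(0, 0, 5, 5)

    def test_fisher_matches_enumeration_exhaustively(self):
        """All non-degenerate tables with total <= 12."""
        for n in range(2, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        res = two_by_two_test(a, b, c, d, policy="fisher_exact")
                        oracle = fisher_two_sided_enumeration(a, b, c, d)
                        assert res.p_value == pytest.approx(oracle, abs=1e-10)

    def test_permutation_null_equals_fisher(self, rng):
        """Label permutation fixes both margins, so its Monte-Carlo p must
        agree with Fisher's exact p within 3 MC standard errors."""
        a, b, c, d = 18, 11, 25, 34
        p_fisher = two_by_two_test(a, b, c, d, policy="fisher_exact").p_value
        outcome = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        n1 = a + b
        stat_obs = ss.chi2_contingency([[a, b], [c, d]], correction=False)[0]
        m = 4000
        hits = 0
        for _ in range(m):
            perm = rng.permutation(outcome)
            aa = int(perm[:n1].sum())
            cc = int(perm[n1:].sum())
            stat = ss.chi2_contingency(
                [[aa, n1 - aa], [cc, (c + d) - cc]], correction=False
            )[0]
            hits += stat >= stat_obs - 1e-12
        p_mc = hits / m
        se = math.sqrt(p_mc * (1 - p_mc) / m)
        assert abs(p_mc - p_fisher) <= 3 * se

    def test_chi_square_p_matches_unconditional_bootstrap(self, rng):
        """The asymptotic chi-square p agrees, within 3 MC standard errors,
        with a Monte-Carlo null that redraws both groups from the pooled
        frequency (the sampling model the statistic assumes)."""
        a, b, c, d = 95, 105, 110, 90
        res = two_by_two_test(a, b, c, d, policy="chi_square")
        n1, n2 = a + b, c + d
        phat = (a + c) / (n1 + n2)
        m = 4000
        hits = 0
        for _ in range(m):
            aa = int(rng.binomial(n1, phat))
            cc = int(rng.binomial(n2, phat))
            if min(aa + cc, (n1 - aa) + (n2 - cc)) == 0:
                continue
            stat = ss.chi2_contingency(
                [[aa, n1 - aa], [cc, n2 - cc]], correction=False
            )[0]
            hits += stat >= res.statistic - 1e-12
        p_mc = hits / m
        se = math.sqrt(p_mc * (1 - p_mc) / m)
        assert abs(p_mc - res.p_value) <= 3 * se


class TestOddsRatio:
    def test_printed_odds_ratio(self):
        or_point, lo, hi = odds_ratio_ci(25, 4, 35, 24)
        assert round(or_point, 3) == 4.286
        assert 0 < lo < or_point < hi

    def test_unit_table_symmetric_on_log_scale(self):
        or_point, lo, hi = odds_ratio_ci(1, 1, 1, 1)
        assert or_point == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)

    def test_haldane_correction_value(self):
        or_point, lo, hi = odds_ratio_ci(5, 0, 5, 5)
        assert or_point == pytest.approx((5.5 * 5.5) / (0.5 * 5.5))
        assert or_point == pytest.approx(11.0)

    def test_no_correction_returns_open_interval(self):
        or_point, lo, hi = odds_ratio_ci(5, 0, 5, 5, correction=None)
        assert math.isinf(or_point) and lo == 0.0 and math.isinf(hi)

    @pytest.mark.parametrize("table", [(25, 4, 35, 24), (3, 9, 7, 2), (12, 8, 6, 14)])
    def test_group_swap_inverts_or(self, table):
        a, b, c, d = table
        or1 = odds_ratio_ci(a, b, c, d)[0]
        or2 = odds_ratio_ci(c, d, a, b)[0]
        assert or1 * or2 == pytest.approx(1.0)
        # simultaneous row+column swap leaves OR unchanged
        or3 = odds_ratio_ci(d, c, b, a)[0]
        assert or3 == pytest.approx(or1)

    def test_exact_conditional_interval(self):
        or_point, lo, hi = odds_ratio_ci(25, 4, 35, 24, method="exact")
        assert round(or_point, 3) == 4.286
        assert 0 < lo < hi
        # exact conditional interval is wider than Woolf on this table
        _, wlo, whi = odds_ratio_ci(25, 4, 35, 24, method="woolf")
        assert lo < wlo and hi > whi

    def test_woolf_coverage_at_null(self, rng):
        """95% Woolf interval covers OR=1 in 93-97% of 29/59 null tables."""
        cover = 0
        m = 1000
        for _ in range(m):
            a = int(rng.binomial(29, 0.3))
            c = int(rng.binomial(59, 0.3))
            _, lo, hi = odds_ratio_ci(a, 29 - a, c, 59 - c)
            cover += lo <= 1.0 <= hi
        assert 0.93 <= cover / m <= 0.97


class TestLineageChiSquare:
    def test_proportional_tables_give_zero(self):
        stat, df, p = lineage_chi_square({"H": (5, 10), "L3": (10, 20), "M": (15, 30)})
        assert stat == pytest.approx(0.0)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        stat, df, p = lineage_chi_square([(20, 10), (10, 20)])
        assert stat == pytest.approx(6.667, abs=5e-4)
        assert df == 1
        assert p == pytest.approx(0.0098, abs=5e-4)

    def test_zero_total_rows_dropped(self):
        with pytest.warns(UserWarning, match="zero-total"):
            stat, df, p = lineage_chi_square({"H": (5, 10), "L3": (10, 20), "X": (0, 0)})
        assert df == 1

    def test_single_surviving_category_raises(self):
        with pytest.raises(DegenerateTableError):
            lineage_chi_square({"H": (5, 10), "X": (0, 0)})


class TestTFromSummary:
    def test_identical_summaries(self):
        res = t_from_summary(10, 2, 20, 10, 2, 20)
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_age_comparison_from_rounded_summaries(self):
        """Printed rounded means/SDs give t ~ -0.97 with df=86 (the study's
        unrounded data gave -1.035; rounding alone explains the gap)."""
        res = t_from_summary(27.7, 4.2, 29, 28.6, 4.0, 59)
        assert res.df == 86
        assert res.t == pytest.approx(-0.976, abs=0.01)
        assert 0.25 < res.p_value < 0.40
        assert res.cohens_d == pytest.approx(0.219447, abs=1e-6)

    def test_paired_closed_form(self):
        res = t_from_summary(1.0, 1.0, 16, kind="paired")
        assert res.t == pytest.approx(4.0)
        assert res.df == 15

    def test_nonpositive_sd_raises(self):
        with pytest.raises(ValueError):
            t_from_summary(1, 0, 10, 2, 1, 10)


class TestCohensD:
    def test_printed_effect_size(self):
        assert cohens_d_summary(27.7, 4.2, 28.6, 4.0) == pytest.approx(
            0.219447, abs=5e-7
        )

    def test_equal_means_zero(self):
        assert cohens_d_summary(5, 1, 5, 2) == 0.0

    def test_unit_case(self):
        assert cohens_d_summary(0, 1, 1, 1) == pytest.approx(1.0)

    def test_pooled_df_weighted_variant(self):
        d = cohens_d_summary(27.7, 4.2, 28.6, 4.0, method="pooled_df_weighted",
                             n1=29, n2=59)
        pooled_sd = math.sqrt((28 * 4.2**2 + 58 * 4.0**2) / 86)
        assert d == pytest.approx(0.9 / pooled_sd)

    def test_nonpositive_sd_raises(self):
        with pytest.raises(ValueError):
            cohens_d_summary(1, -1, 2, 1)


def test_multiple_testing_helpers():
    p = [0.001, 0.01, 0.04, 0.5]
    bf = bonferroni(p)
    assert bf == pytest.approx([0.004, 0.04, 0.16, 1.0])
    bh = benjamini_hochberg(p)
    assert np.all(np.diff(bh[np.argsort(p)]) >= -1e-12)
    assert np.all(bh >= np.asarray(p) - 1e-12)
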