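"""Association battery: HWE, 2x2 tests vs brute-force oracles, tallies."""

import math

import numpy as np
import pytest
from scipy import stats

from cdsite import (
    CompositeMarker,
    allelic_test,
    bonferroni_threshold,
    carrier_test,
    composite_indicator,
    hwe_test,
    odds_ratio_ci,
    raf_to_allele_counts,
    run_comparisons,
    tally_significant,
)
from cdsite.association import _test_2x2

from conftest import make_cohort


def pearson_chi2_oracle(a, b, c, d):
    """Textbook Pearson chi-square for a 2x2 table, no continuity correction."""
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return stats.chi2.sf(stat, df=1)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


class TestHwe:
    def test_exact_proportions_give_chi2_zero(self):
        chi2, p = hwe_test(25, 50, 25)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_monomorphic_convention(self):
        assert hwe_test(100, 0, 0) == (0.0, 1.0)
        assert hwe_test(0, 0, 77) == (0.0, 1.0)

    def test_known_deviation(self):
        chi2, p = hwe_test(30, 60, 10)
        assert chi2 == pytest.approx(6.25)
        assert p == pytest.approx(stats.chi2.sf(6.25, 1), rel=1e-12)
        assert p == pytest.approx(0.0124, abs=2e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


class TestOddsRatioCI:
    def test_null_table(self):
        or_, lo, hi = odds_ratio_ci(50, 50, 50, 50)
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_woolf_interval(self):
        or_, lo, hi = odds_ratio_ci(100, 100, 50, 150)
        assert or_ == pytest.approx(3.0)
        se = math.sqrt(1 / 100 + 1 / 100 + 1 / 50 + 1 / 150)
        assert lo == pytest.approx(math.exp(math.log(3) - 1.96 * se), rel=1e-3)
        assert hi == pytest.approx(math.exp(math.log(3) + 1.96 * se), rel=1e-3)
        assert (lo, hi) == pytest.approx((1.97, 4.58), abs=0.01)

    def test_zero_cell_haldane_anscombe(self):
        or_, lo, hi = odds_ratio_ci(10, 90, 0, 100)
        assert or_ == pytest.approx((10.5 * 100.5) / (90.5 * 0.5), rel=1e-12)
        assert lo <= or_ <= hi

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_ci(0, 0, 5, 5)


class TestAllelicTest:
    def test_identical_distributions_null(self):
        d = np.array([0, 1, 2, 1, 0, 1])
        res = allelic_test(d, d.copy())
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_printed_raf_reconstruction(self):
        # risk-allele counts rebuilt from the published rs2066844
        # frequencies (0.09 in 708 cases, 0.04 in 537 controls)
        a = raf_to_allele_counts(0.09, 708)
        c = raf_to_allele_counts(0.04, 537)
        or_, _, _ = odds_ratio_ci(a, 2 * 708 - a, c, 2 * 537 - c)
        assert or_ == pytest.approx(2.36, abs=0.02)

    def test_small_arms_trigger_fisher(self):
        case = np.array([2, 2, 1, 1, 1])
        ref = np.array([0, 0, 0, 0, 1])
        res = allelic_test(case, ref)
        assert res.test_used == "fisher"

    def test_monomorphic_both_arms_untestable(self):
        res = allelic_test(np.zeros(10), np.zeros(10))
        assert res.untestable
        assert res.p_value == 1.0 and res.odds_ratio == 1.0

    def test_missing_dropped_complete_case(self):
        case = np.array([2, 2, np.nan, 0])
        ref = np.array([0, np.nan, 0, 1])
        res = allelic_test(case, ref)
        assert res.a + res.b == 2 * 3
        assert res.c + res.d == 2 * 3


class TestCarrierTest:
    def test_carrier_coding(self):
        res = carrier_test(np.array([2, 1, 0, 0]), np.array([1, 0, 0, 0]))
        assert (res.a, res.b, res.c, res.d) == (2, 2, 1, 3)

    def test_known_or(self):
        case = np.array([1] * 60 + [0] * 40)
        ref = np.array([1] * 40 + [0] * 60)
        res = carrier_test(case, ref)
        assert res.odds_ratio == pytest.approx(2.25)

    def test_all_carriers_untestable(self):
        res = carrier_test(np.ones(20), np.full(20, 2.0))
        assert res.untestable


class TestCompositeIndicator:
    def _cohort(self, panel, rows):
        dosage = np.full((len(rows), len(panel)), 0.0)
        for i, vals in enumerate(rows):
            for snp, v in vals.items():
                dosage[i, panel.index_of(snp)] = v
        return make_cohort(panel, dosage, [("control", "none")] * len(rows))

    def test_any_risk_genotype(self, panel):
        c = self._cohort(panel, [
            {"rs2066844": 0, "rs2066845": 0, "rs2066847": 1},
            {"rs2066844": 0, "rs2066845": 0, "rs2066847": 0},
            {"rs2066844": 2, "rs2066845": 0, "rs2066847": 0},
        ])
        ind = composite_indicator(c)
        assert list(ind) == [1.0, 0.0, 1.0]

    def test_partial_missing_optimistic_zero(self, panel):
        c = self._cohort(panel, [{"rs2066844": np.nan, "rs2066845": 0, "rs2066847": 0}])
        assert composite_indicator(c)[0] == 0.0
        assert np.isnan(composite_indicator(c, missing_policy="strict")[0])

    def test_all_missing_is_missing(self, panel):
        c = self._cohort(
            panel,
            [{"rs2066844": np.nan, "rs2066845": np.nan, "rs2066847": np.nan}],
        )
        assert np.isnan(composite_indicator(c)[0])

    def test_empty_members_rejected(self, panel, small_cohort):
        with pytest.raises(ValueError):
            composite_indicator(small_cohort, ())


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 19, 0.05 / 19), (0.05, 1, 0.05), (0.05, 29, 0.05 / 29)],
    )
    def test_threshold(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_printed_threshold_two_significant_figures(self):
        assert round(bonferroni_threshold(0.05, 19), 4) == 0.0026


class TestRunComparisons:
    def test_missing_site_skipped_with_warning(self, panel, caplog):
        labels = [("control", "none")] * 10 + [("CD", "L1")] * 10 + [("CD", "L3")] * 10
        rng = np.random.default_rng(0)
        cohort = make_cohort(panel, rng.integers(0, 3, (30, 29)), labels)
        with caplog.at_level("WARNING"):
            table = run_comparisons(cohort)
        comps = set(r.comparison for r in table.results)
        assert "L2_vs_ctrl" not in comps and "L1_vs_L2" not in comps
        assert {"CD_vs_ctrl", "L1_vs_ctrl", "L3_vs_ctrl", "L3_vs_L1"} <= comps

    def test_shape_one_marker_all_comparisons(self, panel, small_cohort):
        table = run_comparisons(small_cohort, models=("allelic",))
        df = table.to_frame()
        one = df[df["marker_id"] == "rs7517847"]
        assert len(one) == 7

    def test_invariant_to_subject_order(self, panel):
        rng = np.random.default_rng(2)
        labels = (
            [("control", "none")] * 30
            + [("CD", "L1")] * 20
            + [("CD", "L2")] * 20
            + [("CD", "L3")] * 20
        )
        dosage = rng.integers(0, 3, (90, 29)).astype(float)
        cohort = make_cohort(panel, dosage, labels)
        perm = rng.permutation(90)
        shuffled = make_cohort(panel, dosage[perm], [labels[i] for i in perm])
        df1 = run_comparisons(cohort).to_frame()
        df2 = run_comparisons(shuffled).to_frame()
        for col in ("a", "b", "c", "d"):
            np.testing.assert_array_equal(df1[col], df2[col])
        np.testing.assert_allclose(df1["p_value"], df2["p_value"])

    def test_composite_included_under_carrier_model(self, panel, small_cohort):
        table = run_comparisons(
            small_cohort, composites=(CompositeMarker("NOD2_any"),)
        )
        df = table.to_frame()
        comp = df[df["marker_id"] == "NOD2_any"]
        assert set(comp["model"]) == {"carrier"}
        assert comp["composite"].all()


class TestOracles:
    def test_chi2_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            a, b, c, d = rng.integers(5, 80, size=4)
            p, used = _test_2x2(a, b, c, d)
            expected = np.outer([a + b, c + d], [a + c, b + d]) / (a + b + c + d)
            if used == "chi2":
                assert p == pytest.approx(pearson_chi2_oracle(a, b, c, d), rel=1e-10)

    def test_fisher_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 200:
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p, used = _test_2x2(a, b, c, d)
            if used != "fisher":
                continue
            assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-8)
            checked += 1


class TestTallies:
    @pytest.mark.parametrize(
        "comparison,include,expected",
        [
            ("L1_vs_ctrl", True, 16),
            ("L2_vs_ctrl", False, 7),
            ("L3_vs_ctrl", True, 14),
            ("L1_vs_L2", False, 5),
            ("L3_vs_L2", False, 3),
            ("L3_vs_L1", False, 2),
        ],
    )
    def test_printed_site_tallies(self, table3, comparison, include, expected):
        assert tally_significant(table3, comparison, 0.05, include) == expected

    def test_case_control_tally_23_of_29(self, table2):
        assert tally_significant(table2, "CD_vs_ctrl", 0.05) == 23

    def test_bonferroni_survivors_match_stars(self, table2):
        thresh = bonferroni_threshold(0.05, 19)
        n = tally_significant(table2, "CD_vs_ctrl", thresh)
        assert n == int(table2.rows["bonferroni_flag"].sum()) == 10

    def test_monotone_in_alpha(self, table3):
        alphas = [1e-6, 1e-4, 1e-2, 0.05, 0.2, 1.0 - 1e-12]
        counts = [
            tally_significant(table3, "L1_vs_ctrl", a, include_composite=True)
            for a in alphas
        ]
        assert counts == sorted(counts)

    def test_empty_table_counts_zero(self):
        from cdsite.association import AssociationTable

        assert tally_significant(AssociationTable(), "L1_vs_ctrl", 0.05) == 0

    def test_unknown_comparison_rejected(self, table3):
        with pytest.raises(ValueError):
            tally_significant(table3, "L9_vs_ctrl", 0.05)
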