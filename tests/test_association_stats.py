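import itertools
import math

import numpy as np
import pytest
from scipy import stats

from conftest import make_record
from melanoma_shields.association_stats import (
    TwoByTwo,
    association_report,
    fisher_exact_two_sided,
    logistic_univariable,
    lvi_two_by_two,
    odds_ratio_woolf,
    pearson_correlation,
    t_test_paired,
    t_test_unpaired,
)
from melanoma_shields.cohort_model import Cohort


def fisher_enumeration_oracle(a, b, c, d):
    """Sum hypergeometric point masses <= the observed one over the
    full support of tables with the observed margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


class TestOddsRatioWoolf:
    def test_published_invasion_table(self):
        # invasion in 38/45 cases vs 26/57 controls
        res = odds_ratio_woolf(TwoByTwo(38, 7, 26, 31))
        assert res.odds_ratio == pytest.approx(6.47, abs=0.005)
        assert res.ci95[0] == pytest.approx(2.48, abs=0.005)
        assert res.ci95[1] == pytest.approx(16.90, abs=0.005)

    def test_identity_table(self):
        assert odds_ratio_woolf(TwoByTwo(1, 1, 1, 1)).odds_ratio == 1.0

    def test_invariant_under_double_swap(self):
        a = odds_ratio_woolf(TwoByTwo(12, 5, 7, 20))
        b = odds_ratio_woolf(TwoByTwo(20, 7, 5, 12))
        assert a.odds_ratio == pytest.approx(b.odds_ratio)
        assert a.ci95 == pytest.approx(b.ci95)

    def test_reciprocal_under_exposure_recoding(self):
        a = odds_ratio_woolf(TwoByTwo(12, 5, 7, 20))
        b = odds_ratio_woolf(TwoByTwo(5, 12, 20, 7))
        assert b.odds_ratio == pytest.approx(1 / a.odds_ratio)
        assert b.ci95[0] == pytest.approx(1 / a.ci95[1])

    def test_ci_symmetric_on_log_scale(self):
        res = odds_ratio_woolf(TwoByTwo(9, 4, 3, 11))
        assert math.log(res.ci95[0]) + math.log(res.ci95[1]) == pytest.approx(
            2 * math.log(res.odds_ratio)
        )

    def test_zero_cell_raises_unless_haldane(self):
        with pytest.raises(ValueError, match="Haldane"):
            odds_ratio_woolf(TwoByTwo(5, 0, 3, 4))
        res = odds_ratio_woolf(TwoByTwo(5, 0, 3, 4), haldane=True)
        assert res.odds_ratio == pytest.approx((5.5 * 4.5) / (0.5 * 3.5))

    def test_matches_statsmodels_table2x2(self):
        from statsmodels.stats.contingency_tables import Table2x2

        t = Table2x2([[38, 7], [26, 31]])
        res = odds_ratio_woolf(TwoByTwo(38, 7, 26, 31))
        assert res.odds_ratio == pytest.approx(t.oddsratio)
        # statsmodels uses the exact normal quantile, we use 1.96
        assert res.ci95 == pytest.approx(tuple(t.oddsratio_confint()), rel=1e-4)


class TestFisherExact:
    def test_published_slnb_invasion_p(self):
        # 8/10 invasion-positive in the SLNB-positive arm vs 3/8
        assert fisher_exact_two_sided(TwoByTwo(8, 2, 3, 5)) == pytest.approx(
            0.145, abs=5e-4
        )

    def test_single_possible_table_gives_one(self):
        assert fisher_exact_two_sided(TwoByTwo(1, 0, 0, 1)) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_for_all_small_tables(self):
        checked = 0
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if not 1 <= a + b + c + d <= 12:
                continue
            if min(a + b, c + d, a + c, b + d) < 1:
                continue
            p = fisher_exact_two_sided(TwoByTwo(a, b, c, d))
            assert p == pytest.approx(
                fisher_enumeration_oracle(a, b, c, d), abs=1e-9
            ), (a, b, c, d)
            assert 0.0 < p <= 1.0
            checked += 1
        assert checked > 500

    def test_symmetric_under_group_relabelling(self):
        p1 = fisher_exact_two_sided(TwoByTwo(8, 2, 3, 5))
        p2 = fisher_exact_two_sided(TwoByTwo(3, 5, 8, 2))
        assert p1 == pytest.approx(p2)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(TwoByTwo(0, 0, 3, 5))


class TestLogisticUnivariable:
    def expand_table(self, a, b, c, d):
        x = np.array([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
        y = np.array([1.0] * (a + b) + [0.0] * (c + d))
        return x, y

    def test_binary_covariate_reproduces_cross_product_or(self):
        x, y = self.expand_table(38, 7, 26, 31)
        fit = logistic_univariable(x, y)
        assert fit.converged
        assert fit.or_per_unit == pytest.approx((38 * 31) / (7 * 26), abs=1e-6)

    def test_matches_statsmodels_fit(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        fit = logistic_univariable(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.se_slope == pytest.approx(ref.bse[1], rel=1e-4)

    def test_null_covariate_slope_near_zero(self, rng):
        x = rng.normal(size=10_000)
        y = (rng.random(10_000) < 0.4).astype(float)
        fit = logistic_univariable(x, y)
        assert fit.converged
        assert abs(fit.slope) < 0.1
        assert fit.ci95[0] < 1.0 < fit.ci95[1]

    def test_slope_recovery_over_replicates(self, rng):
        # 200 cohorts of n=500 with true slope 1.5 on a standard-normal
        # covariate: the mean estimate recovers the slope within 3%
        slopes = []
        for _ in range(200):
            x = rng.normal(size=500)
            p = 1 / (1 + np.exp(-(-0.5 + 1.5 * x)))
            y = (rng.random(500) < p).astype(float)
            slopes.append(logistic_univariable(x, y).slope)
        assert np.mean(slopes) == pytest.approx(1.5, rel=0.03)

    def test_perfect_separation_flagged_without_estimates(self):
        x = np.array([0.0, 1.0, 2.0, 5.0, 6.0, 7.0])
        y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        fit = logistic_univariable(x, y)
        assert not fit.converged
        assert math.isnan(fit.slope)
        assert fit.message != ""

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            logistic_univariable([1.0, 1.0, 1.0], [0.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            logistic_univariable([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


class TestTTests:
    def test_identical_groups_null(self):
        t, df, p = t_test_unpaired([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 4

    def test_hand_computed_student_t(self):
        x1, x2 = [1.0, 2.0, 3.0], [4.0, 6.0, 8.0]
        # pooled s^2 = (2 + 8)/4 = 2.5, t = (2-6)/sqrt(2.5*(2/3))
        expected_t = (2.0 - 6.0) / math.sqrt(2.5 * (2 / 3))
        t, df, p = t_test_unpaired(x1, x2)
        assert t == pytest.approx(expected_t)
        assert df == 4
        assert p == pytest.approx(2 * stats.t.sf(abs(expected_t), 4))

    def test_welch_option_changes_df(self):
        x1 = [1.0, 2.0, 3.0, 4.0]
        x2 = [10.0, 30.0, 50.0]
        _, df_student, _ = t_test_unpaired(x1, x2)
        _, df_welch, _ = t_test_unpaired(x1, x2, equal_variance=False)
        assert df_student == 5
        assert df_welch < df_student

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            t_test_unpaired([2.0, 2.0], [2.0, 2.0])

    def test_paired_identity_null(self):
        x = [1.0, 2.0, 3.0]
        t, df, p = t_test_paired(x, x)
        assert (t, p) == (0.0, 1.0)
        assert df == 2

    def test_paired_constant_shift_degenerate(self):
        with pytest.raises(ValueError):
            t_test_paired([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_paired_hand_computed_four_pairs(self):
        x = [5.0, 7.0, 6.0, 9.0]
        y = [4.0, 5.0, 6.0, 5.0]
        # diffs {1,2,0,4}: mean 1.75, sd sqrt(8.75/3)
        expected_t = 1.75 / (math.sqrt(8.75 / 3) / 2.0)
        t, df, p = t_test_paired(x, y)
        assert t == pytest.approx(expected_t)
        assert df == 3
        assert p == pytest.approx(2 * stats.t.sf(expected_t, 3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            t_test_paired([1.0, 2.0], [1.0])


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 4.0, 8.0]
        r, r2, _ = pearson_correlation(x, x)
        assert (r, r2) == (pytest.approx(1.0), pytest.approx(1.0))
        r, r2, _ = pearson_correlation(x, [-v for v in x])
        assert r == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_hotspot_attenuation_yields_half_shared_variance(self, large_cohort):
        # hot-spot LVD = 0.8 * LVD + noise, with the default noise SD
        # chosen so the shared variance fraction is ~0.5
        _, cohort = large_cohort
        total = np.array([r.lvd_total for r in cohort.records[:10_000]])
        hot = np.array([r.lvd_hotspot for r in cohort.records[:10_000]])
        _, r2, p = pearson_correlation(total, hot)
        assert r2 == pytest.approx(0.5, abs=0.05)
        assert p < 1e-10


class TestAssociationReport:
    def test_toy_cohort_hand_checkable(self):
        records = [
            make_record("M1", lvd_total=10.0, lvi=True, breslow_mm=2.0),
            make_record("M2", lvd_total=12.0, lvi=True, breslow_mm=3.0),
            make_record("M3", lvd_total=9.0, lvi=False, breslow_mm=2.0),
            make_record("M4", lvd_total=11.0, lvi=True, breslow_mm=1.0),
            make_record("N1", "non_metastatic", lvd_total=5.0, lvi=False, breslow_mm=1.0),
            make_record("N2", "non_metastatic", lvd_total=7.0, lvi=True, breslow_mm=2.0),
            make_record("N3", "non_metastatic", lvd_total=6.0, lvi=False, breslow_mm=1.5),
            make_record("N4", "non_metastatic", lvd_total=4.0, lvi=False, breslow_mm=2.5),
        ]
        report = association_report(Cohort(records))
        assert report.loc["lvd_total_mm2", "case_mean"] == pytest.approx(10.5)
        assert report.loc["lvd_total_mm2", "control_mean"] == pytest.approx(5.5)
        # LVI 3/4 cases vs 1/4 controls -> cross-product OR 9
        assert report.loc["lvi", "odds_ratio"] == pytest.approx((3 * 3) / (1 * 1))
        assert report.loc["breslow_mm", "case_mean"] == pytest.approx(2.0)
        assert set(report.index) == {
            "lvd_total_mm2",
            "lvi",
            "breslow_mm",
            "log10_shields_index",
        }

    def test_lvi_or_converges_to_generator_odds(self, large_cohort):
        cfg, cohort = large_cohort
        report = association_report(cohort)
        p1, p0 = cfg.metastatic.lvi_prob, cfg.non_metastatic.lvi_prob
        expected = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert report.loc["lvi", "odds_ratio"] == pytest.approx(expected, rel=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            association_report(Cohort([make_record("A")]))

    def test_lvi_table_counts(self, toy_cohort):
        t = lvi_two_by_two(toy_cohort)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)
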